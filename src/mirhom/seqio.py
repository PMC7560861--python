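"""FASTA ingest and non-redundant reference preparation.

Candidate transcripts (EST/TSA contigs) and reference mature miRNAs are
normalised to an internal DNA alphabet (U→T, uppercase) so that both can be
compared directly by the homology scanner.  Reports that re-emit mature
sequences convert back to the RNA alphabet.

Reference redundancy removal mirrors CD-HIT-EST at a 100% identity
threshold: exact duplicates and exact substrings of a longer retained
sequence are collapsed onto the longest representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


class Source(str, Enum):
    """Provenance tag of a candidate transcript."""

    EST = "EST"
    TSA = "TSA"
    OTHER = "OTHER"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty body, duplicate id, bad alphabet)."""


def normalize_seq(raw: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet (U→T)."""
    return raw.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Convert an internal DNA-alphabet sequence to RNA (T→U, lowercase-safe)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in the internal DNA alphabet."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class TranscriptRecord:
    """One candidate sequence (EST or TSA contig)."""

    id: str
    source: Source
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        self.seq = normalize_seq(self.seq)
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FastaFormatError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# family is the numeric core of a miRBase-style name: "gma-miR482d-3p" -> "482".
def parse_family(ref_id: str) -> str:
    """Extract the miRNA family from a miRBase-style identifier.

    Falls back to the full id when no ``miR<digits>`` core can be found, so
    the parse never fails.
    """
    import re

    m = re.search(r"miR-?(\d+)", ref_id, flags=re.IGNORECASE)
    return m.group(1) if m else ref_id


@dataclass
class ReferenceMature:
    """A reference mature miRNA (miRBase-style), 18–26 nt."""

    id: str
    seq: str
    family: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reference id must be non-empty")
        self.seq = normalize_seq(self.seq)
        if not 18 <= len(self.seq) <= 26:
            raise ValueError(
                f"reference {self.id!r}: mature length {len(self.seq)} outside [18, 26]"
            )
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FastaFormatError(
                f"reference {self.id!r}: invalid characters {sorted(bad)}"
            )
        if not self.family:
            self.family = parse_family(self.id)

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(
    path: str | Path,
    source: Source = Source.OTHER,
    max_n_fraction: float = 0.10,
) -> list[TranscriptRecord]:
    """Read a FASTA file into :class:`TranscriptRecord` objects.

    Ids are the first whitespace-delimited token of each header.  Records
    with more than ``max_n_fraction`` ambiguous (N) bases are dropped with a
    logged warning.  Duplicate ids and empty entries are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        body = str(entry.seq)
        if not rid:
            raise FastaFormatError(f"{path}: entry with empty header")
        if not body:
            raise FastaFormatError(f"{path}: entry {rid!r} has an empty sequence")
        if rid in seen:
            raise FastaFormatError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        rec = TranscriptRecord(id=rid, source=source, seq=body)
        if rec.seq.count("N") > max_n_fraction * len(rec.seq):
            log.warning("dropping %s: >%.0f%% ambiguous bases", rid, 100 * max_n_fraction)
            continue
        records.append(rec)
    return records


def read_reference_fasta(path: str | Path) -> list[ReferenceMature]:
    """Read a mature-miRNA reference FASTA into :class:`ReferenceMature` records."""
    return [
        ReferenceMature(id=t.id, seq=t.seq)
        for t in read_fasta(path, Source.OTHER, max_n_fraction=0.0)
    ]


def write_fasta(
    records: Iterable[TranscriptRecord | ReferenceMature],
    path: str | Path,
    rna: bool = False,
    width: int = 70,
) -> None:
    """Write records as FASTA, wrapping bodies at ``width`` columns.

    With ``rna=True`` sequences are emitted in the RNA alphabet (T→U), the
    convention used for mature-miRNA reports.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            seq = to_rna(rec.seq) if rna else rec.seq
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def cluster_redundant(refs: Sequence[ReferenceMature]) -> list[ReferenceMature]:
    """Collapse exact duplicates and contained substrings onto the longest
    representative (CD-HIT-EST at 100% identity semantics).

    Deterministic: among equal sequences the lexicographically smallest id is
    retained; output order follows first appearance of each representative.
    Idempotent by construction.
    """
    # sort candidates by (-length, id) so a longer sequence is always
    # considered before anything it could contain
    order = sorted(refs, key=lambda r: (-len(r.seq), r.id))
    kept: list[ReferenceMature] = []
    for ref in order:
        container = None
        for k in kept:
            if ref.seq in k.seq:
                container = k
                break
        if container is None:
            kept.append(ref)
    kept_ids = {r.id for r in kept}
    return [r for r in refs if r.id in kept_ids]
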