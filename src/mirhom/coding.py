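"""Coding-potential filter.

Transcripts with protein-coding evidence are excluded before structure
analysis.  Evidence is either (a) a long open reading frame — ATG-initiated,
stop-terminated, over all six frames — or (b) membership in an externally
supplied protein-search hit table (one id per line, or a blast outfmt-6-like
TSV whose first column is the transcript id).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .seqio import TranscriptRecord, revcomp

START = "ATG"
STOPS = frozenset({"TAA", "TAG", "TGA"})


class CodingEvidence(str, Enum):
    ORF = "ORF"
    EXTERNAL_HIT = "EXTERNAL_HIT"
    NONE = "NONE"


@dataclass(frozen=True)
class CodingVerdict:
    transcript_id: str
    coding: bool
    longest_orf_aa: int
    evidence: CodingEvidence


def _longest_orf_in_frame(seq: str, frame: int) -> int:
    """Longest ATG→stop ORF (aa incl. Met, excl. stop) in one forward frame."""
    best = 0
    start: int | None = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOPS:
            if start is not None:
                best = max(best, (i - start) // 3)
                start = None
        elif codon == START and start is None:
            start = i
    # an ORF still open at the end of the sequence is not stop-terminated
    return best


def longest_orf(seq: str) -> int:
    """Length (aa) of the longest ATG-initiated, stop-terminated ORF over all
    six frames (standard genetic code; ORFs running off the end don't count)."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            best = max(best, _longest_orf_in_frame(strand_seq, frame))
    return best


def classify_coding(
    t: TranscriptRecord,
    orf_threshold_aa: int = 100,
    external_hits: set[str] | None = None,
) -> CodingVerdict:
    """Classify a transcript as coding/noncoding.

    External evidence takes precedence over the ORF heuristic; the verdict
    records which evidence fired.
    """
    if orf_threshold_aa < 1:
        raise ValueError("orf_threshold_aa must be ≥ 1")
    orf_aa = longest_orf(t.seq) if len(t.seq) >= 3 else 0
    if external_hits and t.id in external_hits:
        return CodingVerdict(t.id, True, orf_aa, CodingEvidence.EXTERNAL_HIT)
    if orf_aa >= orf_threshold_aa:
        return CodingVerdict(t.id, True, orf_aa, CodingEvidence.ORF)
    return CodingVerdict(t.id, False, orf_aa, CodingEvidence.NONE)


def read_external_hits(path: str | Path) -> set[str]:
    """Read an external protein-hit table: plain ids or tab-separated rows
    (first column used)."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.add(line.split("\t")[0].split()[0])
    return ids


def filter_noncoding(
    transcripts: Iterable[TranscriptRecord],
    orf_threshold_aa: int = 100,
    external_hits: set[str] | None = None,
) -> tuple[list[TranscriptRecord], list[CodingVerdict]]:
    """Split transcripts into the surviving noncoding set plus all verdicts."""
    verdicts = [classify_coding(t, orf_threshold_aa, external_hits) for t in transcripts]
    coding_ids = {v.transcript_id for v in verdicts if v.coding}
    return [t for t in transcripts if t.id not in coding_ids], verdicts
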