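"""Seeded, ungapped homology scan of reference mature miRNAs on transcripts.

The scan reproduces the decision rule of a short-word blastn screen followed
by stringent re-filtering: a hit is any position on either strand where the
*entire* reference aligns without gaps with at most ``max_mismatches``
substitutions, anchored by at least one exact word of length ``word_size``
inside the alignment.  No alignment statistics (e-values) are computed —
the surviving-hit definition is fully determined by the mismatch/length
filters.

Coordinates are 0-based half-open on the transcript forward strand; reports
print 1-based inclusive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import ReferenceMature, TranscriptRecord, revcomp


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the homology scan (word size 7, ≤2 mismatches,
    full-length ungapped alignment of references ≥18 nt)."""

    word_size: int = 7
    max_mismatches: int = 2
    min_align_len: int = 18

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be ≥ 4")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be ≥ 0")
        if self.min_align_len < self.word_size:
            raise ValueError("min_align_len must be ≥ word_size")


@dataclass(frozen=True)
class HomologyHit:
    """A located reference-mature match on a transcript.

    ``matched_seq`` holds the transcript bases of the aligned window read
    5′→3′ on the hit strand — i.e. the mature-miRNA candidate itself.
    """

    transcript_id: str
    ref_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    matched_seq: str
    mismatches: int

    @property
    def align_len(self) -> int:
        return self.end - self.start


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit once ``limit`` is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _has_seed(a: str, b: str, word: int) -> bool:
    """True if an exact run of ≥ ``word`` matching bases exists in the alignment."""
    run = 0
    for x, y in zip(a, b):
        if x == y:
            run += 1
            if run >= word:
                return True
        else:
            run = 0
    return False


def _word_index(seq: str, word: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - word + 1):
        index[seq[i : i + word]].append(i)
    return index


def scan_transcript(
    t: TranscriptRecord, ref: ReferenceMature, cfg: ScanConfig = ScanConfig()
) -> list[HomologyHit]:
    """Locate all full-length ungapped matches of ``ref`` on both strands of ``t``.

    Seed-and-verify: exact ``word_size``-mers of the reference are looked up
    in a transcript word index; every implied alignment offset is verified
    for the mismatch cap.  A transcript shorter than the reference yields no
    hits; alignments overhanging transcript ends do not exist.
    """
    if len(ref.seq) < cfg.min_align_len:
        raise ValueError(
            f"reference {ref.id!r} shorter than min_align_len {cfg.min_align_len}"
        )
    m = len(ref.seq)
    n = len(t.seq)
    if n < m:
        return []
    index = _word_index(t.seq, cfg.word_size)
    hits: list[HomologyHit] = []
    for strand in "+-":
        query = ref.seq if strand == "+" else revcomp(ref.seq)
        offsets: set[int] = set()
        for qpos in range(m - cfg.word_size + 1):
            for tpos in index.get(query[qpos : qpos + cfg.word_size], ()):
                off = tpos - qpos
                if 0 <= off <= n - m:
                    offsets.add(off)
        for off in sorted(offsets):
            window = t.seq[off : off + m]
            mm = _count_mismatches(window, query, cfg.max_mismatches)
            if mm > cfg.max_mismatches:
                continue
            # the seed is guaranteed by construction, but mismatch placement
            # of *other* seeds can imply offsets without their own exact word
            if not _has_seed(window, query, cfg.word_size):
                continue
            matched = window if strand == "+" else revcomp(window)
            hits.append(
                HomologyHit(
                    transcript_id=t.id,
                    ref_id=ref.id,
                    start=off,
                    end=off + m,
                    strand=strand,
                    matched_seq=matched,
                    mismatches=mm,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_all(
    transcripts: Sequence[TranscriptRecord],
    refs: Sequence[ReferenceMature],
    cfg: ScanConfig = ScanConfig(),
) -> list[HomologyHit]:
    """Scan every transcript against every reference; stable ordering
    (transcript input order, then reference input order, then coordinate)."""
    out: list[HomologyHit] = []
    for t in transcripts:
        for ref in refs:
            out.extend(scan_transcript(t, ref, cfg))
    return out


def _overlap_ge_half(a: HomologyHit, b: HomologyHit) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov >= 0.5 * min(a.align_len, b.align_len)


def dedupe_loci(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Collapse hits overlapping ≥50% (of the shorter interval) on the same
    transcript and strand onto a single winner: fewest mismatches, then
    longer alignment, then lexicographically smallest ref_id.

    Greedy non-maximum suppression: winners are accepted best-first and
    suppress everything they overlap.
    """
    hits = list(hits)
    order = sorted(
        hits, key=lambda h: (h.mismatches, -h.align_len, h.ref_id, h.start, h.strand)
    )
    accepted: list[HomologyHit] = []
    for h in order:
        if any(
            a.transcript_id == h.transcript_id
            and a.strand == h.strand
            and _overlap_ge_half(a, h)
            for a in accepted
        ):
            continue
        accepted.append(h)
    accepted_set = set(id(a) for a in accepted)
    return [h for h in hits if id(h) in accepted_set]


def hits_to_rows(hits: Iterable[HomologyHit]) -> list[dict]:
    """Rows for the TSV hit table; coordinates printed 1-based inclusive."""
    return [
        {
            "transcript_id": h.transcript_id,
            "ref_id": h.ref_id,
            "start1": h.start + 1,
            "end1": h.end,
            "strand": h.strand,
            "mismatches": h.mismatches,
            "matched_seq": h.matched_seq,
        }
        for h in hits
    ]
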