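"""Seeded ungapped homology scan: planted matches, oracle equivalence,
strand symmetry and locus dedup."""

import numpy as np
import pytest

from conftest import make_ref, random_seq
from mirhom.scan import HomologyHit, ScanConfig, dedupe_loci, scan_all, scan_transcript
from mirhom.seqio import ReferenceMature, Source, TranscriptRecord, revcomp


def _plant(rng, ref_seq, offset, length=200, strand="+"):
    bg = random_seq(rng, length)
    ins = ref_seq if strand == "+" else revcomp(ref_seq)
    seq = bg[:offset] + ins + bg[offset + len(ins):]
    return TranscriptRecord("t", Source.TSA, seq)


def _exhaustive_scan(t, ref, cfg):
    """Independent sliding-window oracle: every offset on both strands,
    mismatch count plus exact-seed check."""
    out = set()
    m = len(ref.seq)
    for strand in "+-":
        q = ref.seq if strand == "+" else revcomp(ref.seq)
        for off in range(len(t.seq) - m + 1):
            w = t.seq[off : off + m]
            mm = sum(a != b for a, b in zip(w, q))
            if mm > cfg.max_mismatches:
                continue
            run = best = 0
            for a, b in zip(w, q):
                run = run + 1 if a == b else 0
                best = max(best, run)
            if best >= cfg.word_size:
                out.add((t.id, ref.id, off, off + m, strand, mm))
    return out


def test_planted_exact_match(rng):
    ref = make_ref(random_seq(rng, 21))
    t = _plant(rng, ref.seq, 50)
    hits = scan_transcript(t, ref)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.strand, h.mismatches) == (50, 71, "+", 0)
    assert h.matched_seq == ref.seq


def test_planted_reverse_complement(rng):
    ref = make_ref(random_seq(rng, 21))
    t = _plant(rng, ref.seq, 50, strand="-")
    hits = scan_transcript(t, ref)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].matched_seq == ref.seq


def test_three_substitutions_never_hit(rng):
    ref = make_ref(random_seq(rng, 21))
    mutated = list(ref.seq)
    for p in (3, 10, 17):  # kills every 7-mer seed and exceeds the mismatch cap
        mutated[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[p]]
    t = _plant(rng, "".join(mutated), 50)
    assert scan_transcript(t, ref) == []


def test_transcript_shorter_than_reference(rng):
    ref = make_ref(random_seq(rng, 21))
    t = TranscriptRecord("short", Source.TSA, "ACGTACGTAC")
    assert scan_transcript(t, ref) == []


def test_reference_below_min_length_rejected():
    ref = ReferenceMature("r", "ACGTACGTACGTACGTAC")  # 18 nt, valid record
    t = TranscriptRecord("t", Source.TSA, "ACGT" * 30)
    with pytest.raises(ValueError):
        scan_transcript(t, ref, ScanConfig(min_align_len=20))


def test_oracle_equivalence_many_random_instances(rng):
    """Scanner output equals the exhaustive sliding-window oracle."""
    refs = [make_ref(random_seq(rng, int(rng.integers(18, 25))), f"r{i}") for i in range(10)]
    cfg = ScanConfig()
    for i in range(50):
        n = int(rng.integers(50, 1000))
        t = TranscriptRecord(f"t{i}", Source.TSA, random_seq(rng, n))
        if rng.random() < 0.7:  # plant a (possibly mutated) copy to get signal
            ref = refs[int(rng.integers(len(refs)))]
            seq = list(ref.seq)
            for p in rng.choice(len(seq), size=int(rng.integers(0, 4)), replace=False):
                seq[p] = "ACGT"[int(rng.integers(4))]
            ins = "".join(seq) if rng.random() < 0.5 else revcomp("".join(seq))
            off = int(rng.integers(0, n - len(ins) + 1)) if n > len(ins) else 0
            t = TranscriptRecord(
                f"t{i}", Source.TSA, t.seq[:off] + ins + t.seq[off + len(ins):]
            )
        for ref in refs:
            got = {
                (h.transcript_id, h.ref_id, h.start, h.end, h.strand, h.mismatches)
                for h in scan_transcript(t, ref, cfg)
            }
            assert got == _exhaustive_scan(t, ref, cfg)


def test_strand_symmetry(rng):
    ref = make_ref(random_seq(rng, 21))
    t = _plant(rng, ref.seq, 80, length=250)
    fwd = scan_transcript(t, ref)
    rc = TranscriptRecord(t.id, t.source, revcomp(t.seq))
    mirrored = scan_transcript(rc, ref)
    n = len(t.seq)
    assert {(n - h.end, n - h.start, h.strand) for h in fwd} == {
        (h.start, h.end, {"+": "-", "-": "+"}[h.strand]) for h in mirrored
    }


def test_mismatch_monotonicity(rng):
    refs = [make_ref(random_seq(rng, 21), f"r{i}") for i in range(3)]
    ts = []
    for i in range(10):
        ref = refs[i % 3]
        seq = list(ref.seq)
        for p in rng.choice(21, size=i % 3, replace=False):
            seq[p] = "ACGT"[int(rng.integers(4))]
        ts.append(_plant(rng, "".join(seq), 30, length=120))
    for mm_lo, mm_hi in [(0, 1), (1, 2), (2, 3)]:
        lo = {
            (h.transcript_id, h.ref_id, h.start, h.strand)
            for h in scan_all(ts, refs, ScanConfig(max_mismatches=mm_lo))
        }
        hi = {
            (h.transcript_id, h.ref_id, h.start, h.strand)
            for h in scan_all(ts, refs, ScanConfig(max_mismatches=mm_hi))
        }
        assert lo <= hi


# --- locus dedup ------------------------------------------------------------


def _hit(tid="t", rid="r", start=0, end=21, strand="+", mm=0):
    return HomologyHit(tid, rid, start, end, strand, "A" * (end - start), mm)


def test_dedupe_keeps_fewest_mismatches():
    a = _hit(rid="ra", mm=0)
    b = _hit(rid="rb", mm=2)
    assert dedupe_loci([b, a]) == [a]


def test_dedupe_keeps_nonoverlapping():
    a = _hit(start=0, end=21)
    b = _hit(start=100, end=121)
    assert dedupe_loci([a, b]) == [a, b]


def test_dedupe_random_sets_satisfy_clustering_contract(rng):
    """Survivors are mutually <50%-overlapping; every suppressed hit
    overlaps a survivor with better-or-equal priority."""

    def overlap_half(a, b):
        ov = min(a.end, b.end) - max(a.start, b.start)
        return ov > 0 and ov >= 0.5 * min(a.align_len, b.align_len)

    def prio(h):
        return (h.mismatches, -h.align_len, h.ref_id)

    for trial in range(30):
        hits = [
            _hit(
                tid=f"t{int(rng.integers(3))}",
                rid=f"r{int(rng.integers(5))}",
                start=(s := int(rng.integers(0, 100))),
                end=s + int(rng.integers(18, 25)),
                strand="+-"[int(rng.integers(2))],
                mm=int(rng.integers(0, 3)),
            )
            for _ in range(int(rng.integers(2, 25)))
        ]
        kept = dedupe_loci(hits)
        assert set(map(id, kept)) <= set(map(id, hits))
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a.transcript_id == b.transcript_id and a.strand == b.strand:
                    assert not overlap_half(a, b)
        kept_ids = set(map(id, kept))
        for h in hits:
            if id(h) not in kept_ids:
                assert any(
                    k.transcript_id == h.transcript_id
                    and k.strand == h.strand
                    and overlap_half(k, h)
                    and prio(k) <= prio(h)
                    for k in kept
                )
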