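"""Synthetic transcript corpora with planted miRNA precursors and decoys.

Every discovery stage is testable without downloads: a corpus consists of
random background transcripts, transcripts carrying a planted stem-loop
precursor built from a known reference mature (with a controlled number of
substitutions), coding decoys carrying a long ORF, and dinucleotide-shuffled
hairpin decoys (same composition, destroyed stem).  A truth table records
what was planted where.

Design notes on detectability.  Plants are meant to be *recoverable by
construction* so that end-to-end sensitivity is a property, not a coin
flip: mature substitutions are placed so that at least one exact 7-nt word
survives (the seed the scanner requires); synthetic reference matures are
drawn with a fixed G+C count so planted stems always exceed the default
folding-energy screen; and backgrounds of transcripts labelled noncoding
are rejection-sampled against the ORF filter so truth labels hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .coding import longest_orf
from .seqio import ReferenceMature, Source, TranscriptRecord, revcomp, write_fasta

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


class DecoyKind(str, Enum):
    NONE = "NONE"
    CODING = "CODING"
    SHUFFLED_HAIRPIN = "SHUFFLED_HAIRPIN"


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    n_transcripts: int = 30
    length_range: tuple[int, int] = (150, 400)
    gc_fraction: float = 0.5
    n_planted: int = 10
    plant_mutations: int = 2  # per-plant substitutions drawn uniformly in [0, this]
    loop_len: int = 8
    arm: str = "random"  # "5p" | "3p" | "random"
    n_coding_decoys: int = 3
    n_shuffled_decoys: int = 3
    orf_guard_aa: int = 100  # noncoding transcripts resampled below this ORF length

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.n_planted + self.n_coding_decoys + self.n_shuffled_decoys > self.n_transcripts:
            raise ValueError("plants + decoys exceed n_transcripts")
        if self.arm not in ("5p", "3p", "random"):
            raise ValueError("arm must be 5p, 3p or random")


@dataclass(frozen=True)
class TruthRecord:
    transcript_id: str
    planted: bool
    ref_id: str = ""
    mature_start: int = -1  # forward-strand start of the planted mature
    strand: str = ""
    mutations: int = 0
    decoy_kind: DecoyKind = DecoyKind.NONE


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_reference_set(
    rng: np.random.Generator,
    n_refs: int = 10,
    length: int = 21,
    gc_fraction: float = 0.5,
) -> list[ReferenceMature]:
    """Synthetic mature references with an exact G+C count.

    Fixing the composition (rather than sampling it) keeps the thermodynamic
    stability of planted stems uniform across references.
    """
    n_gc = int(round(length * gc_fraction))
    refs: list[ReferenceMature] = []
    seen: set[str] = set()
    while len(refs) < n_refs:
        gc_part = rng.choice(list("GC"), size=n_gc)
        at_part = rng.choice(list("AT"), size=length - n_gc)
        seq = np.concatenate([gc_part, at_part])
        rng.shuffle(seq)
        s = "".join(seq)
        if s in seen:
            continue
        seen.add(s)
        refs.append(ReferenceMature(id=f"ref-miR{9000 + len(refs)}", seq=s))
    return refs


def _mutate_preserving_seed(
    mature: str, mutations: int, rng: np.random.Generator, word: int = 7
) -> str:
    """Substitute ``mutations`` bases; for ≤2 substitutions re-draw positions
    until an exact ``word``-nt run against the original survives."""
    if mutations == 0:
        return mature
    n = len(mature)
    for _ in range(200):
        pos = rng.choice(n, size=min(mutations, n), replace=False)
        out = list(mature)
        for p in pos:
            out[p] = rng.choice([b for b in "ACGT" if b != mature[p]])
        cand = "".join(out)
        if mutations > 2:
            return cand
        run = best = 0
        for a, b in zip(cand, mature):
            run = run + 1 if a == b else 0
            best = max(best, run)
        if best >= word:
            return cand
    return cand  # pragma: no cover - unreachable for realistic lengths


def make_precursor(
    ref: ReferenceMature,
    loop_len: int = 8,
    arm: str = "5p",
    mutations: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[str, int]:
    """Build a planted stem-loop precursor: mature + loop + star (reverse
    complement) with a 2-nt overhang trimmed from the star side, mirrored
    for the 3p arm.  Returns (precursor sequence, mature offset).

    The trimmed star bases are the partners of the mature 3′-terminal bases,
    so the mature sits entirely within one arm.  The loop is drawn over
    {A, C} only, which cannot pair internally, guaranteeing a single
    stem-loop under the bundled test energy model.  Substitutions are
    applied to the mature copy only; the star stays complementary to the
    original reference.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mature = _mutate_preserving_seed(ref.seq, mutations, rng)
    loop = "".join(rng.choice(list("AC"), size=loop_len))
    star_full = revcomp(ref.seq)
    if arm == "5p":
        seq = mature + loop + star_full[:-2]
        offset = 0
    elif arm == "3p":
        seq = star_full[2:] + loop + mature
        offset = len(star_full) - 2 + loop_len
    else:
        raise ValueError("arm must be 5p or 3p")
    return seq, offset


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 1000) -> str:
    """Altschul–Erickson dinucleotide shuffle: preserves mono- and
    dinucleotide counts exactly (first and last base fixed).

    Edge-permutation with Eulerian-walk verification and retry; sequences of
    length < 3 are returned unchanged.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    total = len(seq) - 1
    for _ in range(max_tries):
        pools = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        walk = [seq[0]]
        cur = seq[0]
        ok = True
        for _ in range(total):
            pool = pools.get(cur)
            if not pool:
                ok = False
                break
            cur = pool.pop()
            walk.append(cur)
        if ok:
            return "".join(walk)
    return seq  # pragma: no cover - retry exhaustion is vanishingly rare


def _coding_insert(rng: np.random.Generator, n_codons: int = 150) -> str:
    """An ATG-initiated, stop-terminated ORF of ``n_codons`` sense codons."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _embed(
    rng: np.random.Generator, insert: str, length: int, gc: float
) -> tuple[str, int]:
    """Place ``insert`` at a uniform interior position of a random background."""
    length = max(length, len(insert) + 20)
    pos = int(rng.integers(10, length - len(insert) - 10 + 1))
    bg = _random_seq(rng, length - len(insert), gc)
    return bg[:pos] + insert + bg[pos:], pos


def _noncoding_embed(
    rng: np.random.Generator, insert: str, length: int, gc: float, guard_aa: int
) -> tuple[str, int]:
    for _ in range(100):
        seq, pos = _embed(rng, insert, length, gc)
        if longest_orf(seq) < guard_aa:
            return seq, pos
    raise RuntimeError("could not draw an ORF-free background")  # pragma: no cover


def make_corpus(
    cfg: SynthConfig, refs: list[ReferenceMature]
) -> tuple[list[TranscriptRecord], list[TruthRecord]]:
    """Generate a corpus and its truth table, fully reproducible from the seed."""
    if not refs:
        raise ValueError("reference set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    transcripts: list[TranscriptRecord] = []
    truth: list[TruthRecord] = []
    n_background = cfg.n_transcripts - cfg.n_planted - cfg.n_coding_decoys - cfg.n_shuffled_decoys

    def tid(i: int) -> str:
        return f"syn{cfg.seed}_{i:04d}"

    i = 0
    for k in range(cfg.n_planted):
        ref = refs[k % len(refs)]
        muts = int(rng.integers(0, cfg.plant_mutations + 1))
        arm = cfg.arm if cfg.arm != "random" else ("5p" if rng.random() < 0.5 else "3p")
        prec, off = make_precursor(ref, cfg.loop_len, arm, muts, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = prec if strand == "+" else revcomp(prec)
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq, pos = _noncoding_embed(rng, insert, length, cfg.gc_fraction, cfg.orf_guard_aa)
        if strand == "+":
            mstart = pos + off
        else:
            mstart = pos + len(prec) - off - len(ref.seq)
        transcripts.append(TranscriptRecord(tid(i), Source.TSA, seq))
        truth.append(TruthRecord(tid(i), True, ref.id, mstart, strand, muts, DecoyKind.NONE))
        i += 1
    for _ in range(cfg.n_coding_decoys):
        orf = _coding_insert(rng)
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq, _pos = _embed(rng, orf, length, cfg.gc_fraction)
        transcripts.append(TranscriptRecord(tid(i), Source.TSA, seq))
        truth.append(TruthRecord(tid(i), False, decoy_kind=DecoyKind.CODING))
        i += 1
    for k in range(cfg.n_shuffled_decoys):
        ref = refs[k % len(refs)]
        prec, _off = make_precursor(ref, cfg.loop_len, "5p", 0, rng)
        shuffled = dinucleotide_shuffle(prec, rng)
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq, _pos = _noncoding_embed(rng, shuffled, length, cfg.gc_fraction, cfg.orf_guard_aa)
        transcripts.append(TranscriptRecord(tid(i), Source.TSA, seq))
        truth.append(TruthRecord(tid(i), False, decoy_kind=DecoyKind.SHUFFLED_HAIRPIN))
        i += 1
    for _ in range(n_background):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq, _pos = _noncoding_embed(rng, "", length, cfg.gc_fraction, cfg.orf_guard_aa)
        transcripts.append(TranscriptRecord(tid(i), Source.TSA, seq))
        truth.append(TruthRecord(tid(i), False))
        i += 1
    return transcripts, truth


def write_corpus(
    out_dir: str | Path,
    cfg: SynthConfig,
    refs: list[ReferenceMature],
    transcripts: list[TranscriptRecord],
    truth: list[TruthRecord],
) -> None:
    """Write transcripts.fa, refs.fa and truth.tsv (seed embedded in the
    truth header and in every synthetic id)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(transcripts, out / "transcripts.fa")
    write_fasta(refs, out / "refs.fa")
    with (out / "truth.tsv").open("w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        fh.write("transcript_id\tplanted\tref_id\tmature_start\tstrand\tmutations\tdecoy_kind\n")
        for t in truth:
            fh.write(
                f"{t.transcript_id}\t{int(t.planted)}\t{t.ref_id}\t{t.mature_start}"
                f"\t{t.strand}\t{t.mutations}\t{t.decoy_kind.value}\n"
            )
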