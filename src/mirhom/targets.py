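"""Complementarity-based miRNA target prediction (plant-style expectation
scoring).

The scoring follows the Allen-style scheme popularised by plant target
servers: per-position penalties of 1.0 for a mismatch, 0.5 for a G:U wobble
and 2.0 for an indel, doubled within the seed region (miRNA positions
2–13, 1-based from the 5′ end).  The cumulative penalty is the *expectation*
of a site; sites above the cap are rejected.  Non-complementarity anywhere
in the central window (positions 9–11) marks the site as translational
inhibition rather than cleavage.  Only ungapped scoring is active: the
constraint applied downstream is "≤ 4 mismatches without gap".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .seqio import TranscriptRecord, normalize_seq, to_rna

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # miRNA G : target U and vice versa


class Mode(str, Enum):
    CLEAVAGE = "CLEAVAGE"
    TRANSLATIONAL_INHIBITION = "TRANSLATIONAL_INHIBITION"


class PairState(str, Enum):
    WC = "WC"
    GU = "GU"
    MISMATCH = "MISMATCH"


@dataclass(frozen=True)
class Penalties:
    mismatch: float = 1.0
    gu: float = 0.5
    indel: float = 2.0
    seed_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if min(self.mismatch, self.gu, self.indel, self.seed_multiplier) < 0:
            raise ValueError("penalties must be ≥ 0")


@dataclass(frozen=True)
class TargetConfig:
    max_expectation: float = 3.0
    central_window: tuple[int, int] = (9, 11)  # 1-based from miRNA 5' end
    seed_range: tuple[int, int] = (2, 13)
    max_mismatches_ungapped: int = 4
    multiplicity: int = 2  # max sites kept per (miRNA, target)
    max_hits_per_mirna: int = 10
    penalties: Penalties = field(default_factory=Penalties)

    def __post_init__(self) -> None:
        if self.max_expectation < 0:
            raise ValueError("max_expectation must be ≥ 0")


@dataclass(frozen=True)
class DuplexScore:
    expectation: float
    n_mismatch: int
    n_gu: int
    states: tuple[PairState, ...]  # indexed by miRNA position − 1


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    target_id: str
    target_start: int  # 0-based half-open on the target
    target_end: int
    expectation: float
    n_mismatch: int
    n_gu: int
    mode: Mode
    alignment: str  # 3 lines: miRNA 3'→5', match line, target 5'→3'


def score_duplex(
    mirna: str, site: str, penalties: Penalties = Penalties(),
    seed_range: tuple[int, int] = (2, 13),
) -> DuplexScore:
    """Score an ungapped antiparallel miRNA:site duplex.

    miRNA position p (1-based from its 5′ end) faces site base
    ``site[len − p]`` (site given 5′→3′).  Watson–Crick pairs cost 0, G:U
    wobbles and mismatches their penalty, doubled inside the seed.
    """
    mirna = normalize_seq(mirna)
    site = normalize_seq(site)
    if len(mirna) != len(site):
        raise ValueError("ungapped scoring requires equal lengths")
    n = len(mirna)
    states: list[PairState] = []
    expectation = 0.0
    n_mm = n_gu = 0
    for p in range(1, n + 1):
        a, b = mirna[p - 1], site[n - p]
        if (a, b) in _WC:
            states.append(PairState.WC)
            continue
        mult = penalties.seed_multiplier if seed_range[0] <= p <= seed_range[1] else 1.0
        if (a, b) in _GU:
            states.append(PairState.GU)
            expectation += penalties.gu * mult
            n_gu += 1
        else:
            states.append(PairState.MISMATCH)
            expectation += penalties.mismatch * mult
            n_mm += 1
    return DuplexScore(expectation, n_mm, n_gu, tuple(states))


def _mode_of(score: DuplexScore, central: tuple[int, int]) -> Mode:
    lo, hi = central
    for p in range(lo, hi + 1):
        if p <= len(score.states) and score.states[p - 1] is not PairState.WC:
            return Mode.TRANSLATIONAL_INHIBITION
    return Mode.CLEAVAGE


_MATCH_CHAR = {PairState.WC: "|", PairState.GU: "o", PairState.MISMATCH: " "}


def _alignment_str(mirna: str, site: str, score: DuplexScore) -> str:
    """3-line duplex rendering: miRNA 3′→5′ over the site 5′→3′."""
    n = len(mirna)
    top = to_rna(mirna)[::-1]
    match = "".join(_MATCH_CHAR[score.states[n - 1 - c]] for c in range(n))
    bottom = to_rna(site)
    return f"miRNA  3' {top} 5'\n          {match}\ntarget 5' {bottom} 3'"


def find_targets(
    mirna_id: str,
    mirna_seq: str,
    targets: Sequence[TranscriptRecord],
    cfg: TargetConfig = TargetConfig(),
) -> list[TargetHit]:
    """Slide an ungapped window of the miRNA length over each target (sense
    strand) and keep admissible sites, best-expectation first.

    At most ``cfg.multiplicity`` sites per target and ``max_hits_per_mirna``
    overall, ordered by ascending expectation then coordinates.
    """
    mirna_seq = normalize_seq(mirna_seq)
    m = len(mirna_seq)
    raw: list[TargetHit] = []
    for t in targets:
        per_target: list[TargetHit] = []
        for off in range(0, len(t.seq) - m + 1):
            site = t.seq[off : off + m]
            sc = score_duplex(mirna_seq, site, cfg.penalties, cfg.seed_range)
            if sc.expectation > cfg.max_expectation or sc.n_mismatch > cfg.max_mismatches_ungapped:
                continue
            per_target.append(
                TargetHit(
                    mirna_id=mirna_id,
                    target_id=t.id,
                    target_start=off,
                    target_end=off + m,
                    expectation=sc.expectation,
                    n_mismatch=sc.n_mismatch,
                    n_gu=sc.n_gu,
                    mode=_mode_of(sc, cfg.central_window),
                    alignment=_alignment_str(mirna_seq, site, sc),
                )
            )
        per_target.sort(key=lambda h: (h.expectation, h.target_start))
        raw.extend(per_target[: cfg.multiplicity])
    raw.sort(key=lambda h: (h.expectation, h.target_id, h.target_start))
    return raw[: cfg.max_hits_per_mirna]


def find_all_targets(
    mirnas: Iterable[tuple[str, str]],
    targets: Sequence[TranscriptRecord],
    cfg: TargetConfig = TargetConfig(),
) -> list[TargetHit]:
    """Run :func:`find_targets` for each (id, sequence) miRNA pair."""
    out: list[TargetHit] = []
    for mid, seq in mirnas:
        out.extend(find_targets(mid, seq, targets, cfg))
    return out


def filter_by_gene_list(hits: Iterable[TargetHit], ids: set[str]) -> list[TargetHit]:
    """Keep hits whose target id is in ``ids`` (e.g. a drought-gene list),
    preserving order."""
    return [h for h in hits if h.target_id in ids]
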