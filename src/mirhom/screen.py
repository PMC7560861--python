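"""Hairpin validation and precursor statistics.

Candidate structures are screened against five criteria used for conserved
plant miRNA precursors: (i) ≤ 2 substitutions between candidate mature and
reference, (ii) a proper single stem-loop, (iii) the mature entirely within
one arm, (iv) < 6 mismatches between mature and its star sequence, and
(v) strongly negative MFE and MFEI.  The per-precursor statistics follow
the standard conventions:

    AMFE = (MFE / LP) × 100        (kcal/mol per 100 nt)
    MFEI = AMFE / GC%              (dimensionless, printed as magnitude)

with LP the precursor length and base composition reported in the RNA
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .fold import FoldBackend, FoldResult, PrecursorCandidate, fold as fold_candidate
from .seqio import to_rna


class FailReason(str, Enum):
    NO_HAIRPIN = "NO_HAIRPIN"
    MATURE_IN_LOOP = "MATURE_IN_LOOP"
    STAR_MM = "STAR_MM"
    SUBS = "SUBS"
    MFEI_LOW = "MFEI_LOW"
    MFE_HIGH = "MFE_HIGH"


@dataclass(frozen=True)
class ScreenThresholds:
    """Screening cut-offs.  MFE/MFEI defaults quantify "high negative MFE
    and MFEI": |MFEI| ≥ 0.5 brackets the accepted precursor range
    (0.57–1.03) and MFE ≤ −18 kcal/mol excludes marginal stems."""

    max_substitutions: int = 2
    max_star_mismatches: int = 5
    min_abs_mfei: float = 0.5
    max_mfe: float = -18.0
    #: terminal breathing allowance: up to this many mature positions may sit
    #: at the loop edge before the mature counts as localised in the loop
    loop_overlap_tolerance: int = 2


@dataclass
class Composition:
    counts: dict[str, int]  # RNA alphabet keys A, C, G, U
    au_pct: float
    gc_pct: float


@dataclass
class ArmStar:
    arm: str  # "5p" | "3p" | ""
    star_seq: str
    star_mismatches: int
    mature_in_loop: bool
    no_hairpin: bool


@dataclass
class HairpinReport:
    """One Table-style record per candidate precursor."""

    candidate_id: str
    family: str
    lp: int
    lm: int
    counts: dict[str, int]
    au_pct: float
    gc_pct: float
    mfe: float
    amfe_val: float
    mfei_val: float
    arm: str
    star_seq: str
    star_mismatches: int
    substitutions_vs_ref: int
    precursor_seq: str = ""
    mature_seq: str = ""
    dotbracket: str = ""
    passed: bool = False
    fail_reasons: list[FailReason] = field(default_factory=list)

    @property
    def mfei_magnitude(self) -> float:
        return round(abs(self.mfei_val), 2)


def base_composition(seq: str) -> Composition:
    """Base counts (RNA alphabet) plus AU% and GC% to two decimals."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes in sequence: {sorted(set(seq) - set('ACGT'))}")
    n = len(seq)
    counts = {"A": seq.count("A"), "C": seq.count("C"), "G": seq.count("G"), "U": seq.count("T")}
    au = round(100.0 * (counts["A"] + counts["U"]) / n, 2)
    gc = round(100.0 * (counts["G"] + counts["C"]) / n, 2)
    return Composition(counts=counts, au_pct=au, gc_pct=gc)


def amfe(mfe: float, lp: int) -> float:
    """Adjusted MFE: energy normalised per 100 nt."""
    if lp <= 0:
        raise ValueError("precursor length must be positive")
    if mfe > 0:
        raise ValueError("MFE must be ≤ 0")
    return (mfe / lp) * 100.0


def mfei(amfe_val: float, gc_pct: float) -> float:
    """Minimal folding free energy index AMFE/GC% (negative; reports print
    the magnitude to two decimals)."""
    if gc_pct <= 0:
        raise ValueError("GC% must be positive")
    return amfe_val / gc_pct


def pairing_table(dotbracket: str) -> list[int]:
    """Partner index per position (−1 if unpaired); standard nested matching."""
    partners = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            j = stack.pop()
            partners[i], partners[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise ValueError("unbalanced structure: unmatched '('")
    return partners


def _hairpin_loops_within(partners: list[int], lo: int, hi: int) -> list[tuple[int, int]]:
    """Hairpin loops (innermost pairs) with both ends inside [lo, hi]."""
    loops = []
    for i, j in enumerate(partners):
        if j > i and lo <= i and j <= hi:
            if all(partners[k] == -1 for k in range(i + 1, j)):
                loops.append((i, j))
    return loops


def _dominant_stem(partners: list[int]) -> tuple[int, int] | None:
    """Exterior-most pair whose enclosed region holds ≥ 80% of all paired
    positions; ``None`` if no such pair exists."""
    total = sum(1 for p in partners if p >= 0)
    if total == 0:
        return None
    for i in range(len(partners)):
        j = partners[i]
        if j > i:
            inside = sum(1 for k in range(i, j + 1) if partners[k] >= 0)
            if inside >= 0.8 * total:
                return i, j
    return None


def _hairpin_loop_of(partners: list[int]) -> tuple[int, int] | None:
    """Loop interval (open positions between the innermost pair) of the
    dominant stem; ``None`` signals no-hairpin/multiloop structures."""
    stem = _dominant_stem(partners)
    if stem is None:
        return None
    loops = _hairpin_loops_within(partners, stem[0], stem[1])
    if len(loops) != 1:
        return None  # multiloop (or none) inside the dominant stem
    a, b = loops[0]
    return a + 1, b - 1


def assign_arm_and_star(
    fold: FoldResult, seq: str, mature_offset: int, mature_len: int,
    loop_tolerance: int = 2,
) -> ArmStar:
    """Locate the mature within the stem-loop and extract its star.

    The star is the sequence of pairing partners of the mature positions,
    read 5′→3′ and extended by the canonical 2-nt 3′ overhang.  Star
    mismatches count mature positions left unpaired *inside* the duplex
    (between its outermost paired positions): dangling overhang ends are
    not mature/star mismatches.  Up to ``loop_tolerance`` terminal mature
    positions may breathe into the hairpin loop before the mature counts
    as localised in the loop.
    """
    partners = pairing_table(fold.dotbracket)
    loop = _hairpin_loop_of(partners)
    if loop is None:
        return ArmStar("", "", mature_len, False, True)
    loop_lo, loop_hi = loop
    mature = range(mature_offset, mature_offset + mature_len)
    overlap = sum(1 for p in mature if loop_lo <= p <= loop_hi)
    in_loop = overlap > loop_tolerance
    if in_loop:
        arm = ""
    elif mature.start < loop_lo:
        arm = "5p"
    else:
        arm = "3p"
    paired = [p for p in mature if partners[p] >= 0]
    if not paired:
        return ArmStar(arm, "", mature_len, in_loop, False)
    star_mm = sum(1 for p in range(paired[0], paired[-1] + 1) if partners[p] < 0)
    partner_pos = [partners[p] for p in paired]
    star_lo, star_hi = min(partner_pos), max(partner_pos)
    # 2-nt 3' overhang: the star's 3' end is its high-coordinate end for
    # either arm (the whole precursor reads 5'→3' in increasing coordinates)
    star = seq[star_lo : min(len(seq), star_hi + 3)]
    return ArmStar(arm, to_rna(star), star_mm, in_loop, False)


def trim_precursor(
    c: PrecursorCandidate,
    fold: FoldResult,
    backend: FoldBackend,
    soft_flank: int = 5,
) -> tuple[PrecursorCandidate, FoldResult] | None:
    """Trim the excised window to the stem enclosing the mature duplex.

    Walks outward from the mature duplex along its helix, stopping where the
    stem joins a multiloop (an enclosing pair with sibling branches), then
    keeps ``soft_flank`` extra nt on each side and refolds.  Returns ``None``
    when the mature is entirely unpaired or the refold has no structure.
    """
    partners = pairing_table(fold.dotbracket)
    mature = range(c.mature_offset, c.mature_offset + c.mature_len)
    anchored = [p for p in mature if partners[p] >= 0]
    if not anchored:
        return None
    # the mature may pair partly against spurious partners elsewhere in the
    # window; the duplex is anchored on the majority partner run (clusters of
    # partner positions split at gaps > 8 nt, largest cluster wins)
    clusters: list[list[int]] = [[anchored[0]]]
    for p in anchored[1:]:
        if abs(partners[p] - partners[clusters[-1][-1]]) > 8:
            clusters.append([])
        clusters[-1].append(p)
    duplex = max(clusters, key=len)
    involved = list(mature) + [partners[p] for p in duplex]
    dlo, dhi = min(involved), max(involved)
    pairs = sorted((i, j) for i, j in enumerate(partners) if j > i)
    enclosing = [(i, j) for i, j in pairs if i <= dlo and j >= dhi]
    # extend outward along the helix (innermost enclosing pair first), but
    # stop where the stem joins a multiloop (a sibling branch appears)
    enclosing.sort(key=lambda ij: ij[0], reverse=True)
    best = (dlo, dhi)
    for i, j in enclosing:
        sibling = any(
            i < a < b < j and (b < best[0] or a > best[1]) for a, b in pairs
        )
        if sibling:
            break
        best = (i, j)
    lo = max(0, min(best[0] - soft_flank, mature.start))
    hi = min(len(c.seq), max(best[1] + 1 + soft_flank, mature.stop))
    trimmed = PrecursorCandidate(
        transcript_id=c.transcript_id,
        window_start=c.window_start,  # original transcript coords retained
        window_end=c.window_end,
        seq=c.seq[lo:hi],
        mature_offset=c.mature_offset - lo,
        mature_len=c.mature_len,
        strand=c.strand,
        ref_id=c.ref_id,
        mismatches=c.mismatches,
    )
    refolded = fold_candidate(trimmed, backend)
    if refolded is None:
        return None
    return trimmed, refolded


def screen(report: HairpinReport, thresholds: ScreenThresholds = ScreenThresholds()) -> HairpinReport:
    """Fill pass/fail flags from the computed statistics (criteria i–v)."""
    reasons: list[FailReason] = []
    if report.substitutions_vs_ref > thresholds.max_substitutions:
        reasons.append(FailReason.SUBS)
    if not report.arm and not report.dotbracket:
        reasons.append(FailReason.NO_HAIRPIN)
    elif not report.arm:
        reasons.append(FailReason.MATURE_IN_LOOP)
    elif report.star_mismatches > thresholds.max_star_mismatches:
        # the mature/star duplex criterion presupposes a mature in one arm
        reasons.append(FailReason.STAR_MM)
    if abs(report.mfei_val) < thresholds.min_abs_mfei:
        reasons.append(FailReason.MFEI_LOW)
    if report.mfe > thresholds.max_mfe:
        reasons.append(FailReason.MFE_HIGH)
    report.fail_reasons = reasons
    report.passed = not reasons
    return report


def build_report(
    c: PrecursorCandidate,
    fold: FoldResult,
    backend: FoldBackend,
    family: str = "",
    thresholds: ScreenThresholds = ScreenThresholds(),
    trim: bool = True,
) -> HairpinReport:
    """Compute the full per-candidate record: trim, refold, statistics,
    arm/star assignment and screening flags."""
    cand, fr = c, fold
    arm_info = ArmStar("", "", c.mature_len, False, True)
    if trim:
        trimmed = trim_precursor(c, fold, backend)
        if trimmed is not None:
            cand, fr = trimmed
    if fr is not None:
        arm_info = assign_arm_and_star(
            fr, cand.seq, cand.mature_offset, cand.mature_len,
            loop_tolerance=thresholds.loop_overlap_tolerance,
        )
    comp = base_composition(cand.seq)
    lp = len(cand.seq)
    amfe_val = amfe(min(fr.mfe, 0.0), lp)
    mfei_val = mfei(amfe_val, comp.gc_pct) if comp.gc_pct > 0 else 0.0
    mature = cand.seq[cand.mature_offset : cand.mature_offset + cand.mature_len]
    report = HairpinReport(
        candidate_id=cand.id,
        family=family,
        lp=lp,
        lm=cand.mature_len,
        counts=comp.counts,
        au_pct=comp.au_pct,
        gc_pct=comp.gc_pct,
        mfe=fr.mfe,
        amfe_val=amfe_val,
        mfei_val=mfei_val,
        arm=arm_info.arm,
        star_seq=arm_info.star_seq,
        star_mismatches=arm_info.star_mismatches,
        substitutions_vs_ref=cand.mismatches,
        precursor_seq=to_rna(cand.seq),
        mature_seq=to_rna(mature),
        dotbracket="" if arm_info.no_hairpin else fr.dotbracket,
    )
    return screen(report, thresholds)


def name_mirna(family: str, arm: str, existing: set[str]) -> str:
    """Deterministic species-style name: ``mun-miR<family><letter>-<arm>``,
    disambiguated by letter suffix against already assigned names."""
    if not family:
        raise ValueError("family must be non-empty")
    suffixes = [""] + [chr(c) for c in range(ord("a"), ord("z") + 1)]
    for s in suffixes:
        name = f"mun-miR{family}{s}-{arm}" if arm else f"mun-miR{family}{s}"
        if name not in existing:
            return name
    raise RuntimeError(f"exhausted suffixes for family {family}")
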