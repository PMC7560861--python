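"""Precursor statistics, arm/star assignment and the five-criterion screen."""

import pytest

from conftest import random_seq
from mirhom.fold import FoldResult, PrecursorCandidate, StackingBackend, fold
from mirhom.published import CONSISTENT_MFEI, PRECURSORS
from mirhom.screen import (
    FailReason,
    HairpinReport,
    ScreenThresholds,
    amfe,
    assign_arm_and_star,
    base_composition,
    build_report,
    mfei,
    name_mirna,
    pairing_table,
    screen,
    trim_precursor,
)
from mirhom.seqio import revcomp, to_rna


# --- composition ------------------------------------------------------------


def test_composition_of_published_precursor_counts():
    """Printed base counts of a published precursor reproduce its AU%/GC%."""
    seq = "A" * 28 + "C" * 17 + "G" * 38 + "T" * 35  # 118 nt
    comp = base_composition(seq)
    assert comp.counts == {"A": 28, "C": 17, "G": 38, "U": 35}
    assert comp.au_pct == 53.39
    assert comp.gc_pct == 46.61


def test_composition_pure_au():
    comp = base_composition("AAAA")
    assert (comp.au_pct, comp.gc_pct) == (100.0, 0.0)


def test_composition_matches_tally_oracle(rng):
    for _ in range(100):
        s = random_seq(rng, 200)
        comp = base_composition(s)
        tally = {b: s.count(b) for b in "ACGT"}
        assert comp.counts == {"A": tally["A"], "C": tally["C"], "G": tally["G"], "U": tally["T"]}
        assert abs(comp.au_pct + comp.gc_pct - 100.0) <= 0.01


def test_composition_rejects_ambiguity():
    with pytest.raises(ValueError):
        base_composition("ACGTN")


# --- energy statistics ------------------------------------------------------


@pytest.mark.parametrize("mfe,lp,expected", [(-42.0, 120, -35.0), (-50.0, 100, -50.0)])
def test_amfe_examples(mfe, lp, expected):
    assert amfe(mfe, lp) == pytest.approx(expected)


def test_amfe_random_matches_arithmetic(rng):
    for _ in range(100):
        m = -float(rng.uniform(1, 80))
        lp = int(rng.integers(50, 200))
        assert amfe(m, lp) == pytest.approx(m / lp * 100)
    with pytest.raises(ValueError):
        amfe(-10.0, 0)


@pytest.mark.parametrize(
    "amfe_val,gc,expected",
    [(-35.61, 40.76, 0.87), (-26.77, 46.61, 0.57), (-50.0, 50.0, 1.0)],
)
def test_mfei_published_magnitudes(amfe_val, gc, expected):
    assert round(abs(mfei(amfe_val, gc)), 2) == expected


def test_mfei_consistent_published_rows():
    """For every internally consistent published row, |AMFE|/GC% reproduces
    the printed MFEI at two decimals."""
    for row in PRECURSORS:
        if row.tsa_id in CONSISTENT_MFEI:
            assert round(abs(mfei(row.amfe, row.gc_pct)), 2) == row.mfei


def test_mfei_zero_gc_is_error():
    with pytest.raises(ValueError):
        mfei(-30.0, 0.0)


# --- pairing table ----------------------------------------------------------


def _pairing_oracle(db):
    """Independent recursive-descent matcher."""
    partners = [-1] * len(db)

    def parse(i):
        while i < len(db):
            if db[i] == ".":
                i += 1
            elif db[i] == "(":
                j = parse(i + 1)
                partners[i], partners[j] = j, i
                i = j + 1
            else:
                return i
        return i

    end = parse(0)
    assert end == len(db)
    return partners


def test_pairing_table_examples():
    assert pairing_table("((..))") == [5, 4, -1, -1, 1, 0]
    assert pairing_table("....") == [-1, -1, -1, -1]


@pytest.mark.parametrize("bad", ["(()", "())", "(.x)"])
def test_pairing_table_rejects_invalid(bad):
    with pytest.raises(ValueError):
        pairing_table(bad)


def test_pairing_table_matches_oracle_on_folded_structures(rng, stacking):
    for _ in range(100):
        s = random_seq(rng, int(rng.integers(30, 120)))
        db, _ = stacking.fold(s)
        partners = pairing_table(db)
        assert partners == _pairing_oracle(db)
        for i, j in enumerate(partners):
            if j >= 0:
                assert partners[j] == i  # involution


# --- arm and star -----------------------------------------------------------

MATURE = "GGCATCGGCATTCGGCATACG"  # 21 nt


def _perfect_hairpin(mature, loop="AACAAC"):
    return mature + loop + revcomp(mature)


def test_perfect_duplex_star_is_reverse_complement():
    seq = _perfect_hairpin(MATURE)
    db = "(" * 21 + "." * 6 + ")" * 21
    arm = assign_arm_and_star(FoldResult(db, -20.0), seq, 0, len(MATURE))
    assert arm.arm == "5p"
    assert not arm.mature_in_loop
    assert arm.star_mismatches == 0
    assert arm.star_seq == to_rna(revcomp(MATURE))


def test_mature_straddling_loop_flagged(stacking):
    seq = _perfect_hairpin(MATURE)
    db, mfe = stacking.fold(seq)
    # mature window centred on the loop
    arm = assign_arm_and_star(FoldResult(db, mfe, backend="stacking"), seq, 14, 21)
    assert arm.mature_in_loop


def test_three_prime_arm_assignment(stacking):
    seq = _perfect_hairpin(MATURE)
    db, mfe = stacking.fold(seq)
    arm = assign_arm_and_star(
        FoldResult(db, mfe, backend="stacking"), seq, len(seq) - 21, 21
    )
    assert arm.arm == "3p"


def test_no_hairpin_signal():
    arm = assign_arm_and_star(FoldResult("." * 40, -1.0), "A" * 40, 5, 21)
    assert arm.no_hairpin


@pytest.mark.parametrize("k", range(8))
def test_star_mismatches_count_designed_bulges(k, stacking):
    """k interior mature positions mutated to non-pairing bases →
    star_mismatches = k."""
    mature = list(MATURE)
    star = revcomp(MATURE)
    non_pairing = {"A": "C", "C": "A", "G": "A", "T": "C"}  # breaks WC and G:U
    positions = [4 + 2 * i for i in range(k)]  # interior, spread out
    for p in positions:
        mature[p] = non_pairing[mature[p]]
    seq = "".join(mature) + "AACAAC" + star
    db, mfe = stacking.fold(seq)
    arm = assign_arm_and_star(FoldResult(db, mfe, backend="stacking"), seq, 0, len(mature))
    assert arm.star_mismatches == k


# --- trim + screen ----------------------------------------------------------


def _report(**kw):
    base = dict(
        candidate_id="c", family="482", lp=100, lm=21,
        counts={"A": 25, "C": 25, "G": 25, "U": 25},
        au_pct=50.0, gc_pct=50.0, mfe=-40.0, amfe_val=-40.0, mfei_val=-0.8,
        arm="5p", star_seq="A" * 21, star_mismatches=0,
        substitutions_vs_ref=0, dotbracket="(((...)))",
    )
    base.update(kw)
    return HairpinReport(**base)


def test_screen_perfect_report_passes():
    r = screen(_report())
    assert r.passed and r.fail_reasons == []


@pytest.mark.parametrize(
    "kw,reason",
    [
        (dict(substitutions_vs_ref=3), FailReason.SUBS),
        (dict(star_mismatches=6), FailReason.STAR_MM),
        (dict(mfei_val=-0.4), FailReason.MFEI_LOW),
        (dict(mfe=-10.0, amfe_val=-10.0), FailReason.MFE_HIGH),
        (dict(arm="", dotbracket=""), FailReason.NO_HAIRPIN),
        (dict(arm=""), FailReason.MATURE_IN_LOOP),
    ],
)
def test_screen_individual_criteria(kw, reason):
    r = screen(_report(**kw))
    assert not r.passed
    assert reason in r.fail_reasons


def test_screen_boundary_star_mismatches():
    assert screen(_report(star_mismatches=5)).passed
    assert not screen(_report(star_mismatches=6)).passed


def test_screen_monotone_in_thresholds(rng):
    """Relaxing any threshold never removes a pass."""
    tight = ScreenThresholds()
    loose = ScreenThresholds(
        max_substitutions=5, max_star_mismatches=10, min_abs_mfei=0.1, max_mfe=-1.0
    )
    for _ in range(50):
        kw = dict(
            substitutions_vs_ref=int(rng.integers(0, 5)),
            star_mismatches=int(rng.integers(0, 10)),
            mfei_val=-float(rng.uniform(0, 1.5)),
            mfe=-float(rng.uniform(5, 60)),
        )
        if screen(_report(**kw), tight).passed:
            assert screen(_report(**kw), loose).passed


def test_screen_flagset_matches_per_criterion_oracle(rng):
    """Flag sets equal the independent criterion-by-criterion oracle."""
    thr = ScreenThresholds()
    for _ in range(50):
        kw = dict(
            substitutions_vs_ref=int(rng.integers(0, 5)),
            star_mismatches=int(rng.integers(0, 10)),
            mfei_val=-float(rng.uniform(0, 1.5)),
            mfe=-float(rng.uniform(5, 60)),
        )
        shape = rng.integers(0, 3)
        if shape == 1:
            kw.update(arm="", dotbracket="")
        elif shape == 2:
            kw.update(arm="")
        r = screen(_report(**kw))
        expect = set()
        if kw["substitutions_vs_ref"] > thr.max_substitutions:
            expect.add(FailReason.SUBS)
        if shape == 1:
            expect.add(FailReason.NO_HAIRPIN)
        elif shape == 2:
            expect.add(FailReason.MATURE_IN_LOOP)
        elif kw["star_mismatches"] > thr.max_star_mismatches:
            expect.add(FailReason.STAR_MM)
        if abs(kw["mfei_val"]) < thr.min_abs_mfei:
            expect.add(FailReason.MFEI_LOW)
        if kw["mfe"] > thr.max_mfe:
            expect.add(FailReason.MFE_HIGH)
        assert set(r.fail_reasons) == expect
        assert r.passed == (not expect)


def test_trim_recovers_planted_stem(rng, stacking):
    """An excised window much larger than the hairpin trims back to it."""
    hairpin = _perfect_hairpin(MATURE)
    left, right = random_seq(rng, 60), random_seq(rng, 60)
    seq = left + hairpin + right
    cand = PrecursorCandidate("t", 0, len(seq), seq, 60, 21)
    fr = fold(cand, stacking)
    out = trim_precursor(cand, fr, stacking)
    assert out is not None
    trimmed, refolded = out
    assert len(trimmed.seq) <= len(hairpin) + 30
    mature = trimmed.seq[trimmed.mature_offset : trimmed.mature_offset + 21]
    assert mature == MATURE


def test_build_report_invariants(rng, vienna):
    """Counts sum to LP, AU%+GC% = 100 ± 0.01, MFEI = AMFE/GC% exactly."""
    hairpin = _perfect_hairpin(MATURE)
    seq = random_seq(rng, 40) + hairpin + random_seq(rng, 40)
    cand = PrecursorCandidate("t", 0, len(seq), seq, 40, 21)
    fr = fold(cand, vienna)
    r = build_report(cand, fr, vienna, family="482")
    assert sum(r.counts.values()) == r.lp
    assert abs(r.au_pct + r.gc_pct - 100.0) <= 0.01
    assert r.mfei_val == pytest.approx(r.amfe_val / r.gc_pct)


def test_name_mirna_deterministic_disambiguation():
    existing = set()
    names = []
    for _ in range(4):
        n = name_mirna("482", "3p", existing)
        existing.add(n)
        names.append(n)
    assert names == ["mun-miR482-3p", "mun-miR482a-3p", "mun-miR482b-3p", "mun-miR482c-3p"]
    assert name_mirna("2118", "", set()) == "mun-miR2118"
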