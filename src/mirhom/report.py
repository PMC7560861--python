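"""Summary tables and headline statistics of a discovery run.

Produces the three standard renditions: per-precursor characteristics
(Table-1 style), feature summary statistics (mean / sample sd / min / max),
and the run census with the miRNA frequency ("1 miRNA per N candidate
sequences", N by the ceiling rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .screen import HairpinReport
from .seqio import parse_family

log = logging.getLogger(__name__)

#: features summarised per precursor report
_FEATURES = ("LP", "AU_pct", "GC_pct", "A", "C", "G", "U", "MFE", "AMFE", "MFEI")


@dataclass(frozen=True)
class FeatureStats:
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class RunCensus:
    n_candidate_est: int
    n_candidate_tsa: int
    n_candidate_total: int
    n_precursors: int
    n_families: int
    n_mirnas: int
    frequency_denominator: int | None

    @property
    def frequency_text(self) -> str:
        if self.frequency_denominator is None:
            return ""
        return f"1 miRNA per {self.frequency_denominator}(approx) sequences"


def _stats(values: Sequence[float]) -> FeatureStats:
    if not values:
        raise ValueError("no observations")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        log.warning("single observation: sample sd reported as 0")
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return FeatureStats(mean=mean, sd=sd, min=min(values), max=max(values))


def summarize(
    reports: Sequence[HairpinReport] | None = None,
    mature_lengths: Sequence[int] | None = None,
    columns: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, FeatureStats]:
    """Feature summary statistics (mean, sample sd with the n−1 denominator,
    min, max).

    Either pass pipeline ``reports`` (plus ``mature_lengths`` for the LM
    row), or pre-extracted ``columns`` — e.g. the printed columns of a
    published table — keyed by feature name.
    """
    cols: dict[str, list[float]] = {}
    if columns is not None:
        cols.update({k: list(v) for k, v in columns.items()})
    if reports:
        cols.setdefault("LP", [float(r.lp) for r in reports])
        cols.setdefault("AU_pct", [r.au_pct for r in reports])
        cols.setdefault("GC_pct", [r.gc_pct for r in reports])
        for base in "ACGU":
            cols.setdefault(base, [float(r.counts[base]) for r in reports])
        cols.setdefault("MFE", [r.mfe for r in reports])
        cols.setdefault("AMFE", [r.amfe_val for r in reports])
        cols.setdefault("MFEI", [r.mfei_magnitude for r in reports])
    if mature_lengths:
        cols["LM"] = [float(x) for x in mature_lengths]
    if not cols:
        raise ValueError("nothing to summarise")
    return {name: _stats(vals) for name, vals in cols.items() if vals}


def census(
    n_candidate_est: int,
    n_candidate_tsa: int,
    n_precursors: int,
    n_mirnas: int,
    n_families: int,
) -> RunCensus:
    """Run census; the miRNA frequency denominator is
    ``ceil(total_candidates / n_mirnas)`` and omitted when no miRNAs were
    found."""
    if min(n_candidate_est, n_candidate_tsa, n_precursors, n_mirnas, n_families) < 0:
        raise ValueError("census counts must be ≥ 0")
    total = n_candidate_est + n_candidate_tsa
    denom = math.ceil(total / n_mirnas) if n_mirnas > 0 else None
    return RunCensus(
        n_candidate_est=n_candidate_est,
        n_candidate_tsa=n_candidate_tsa,
        n_candidate_total=total,
        n_precursors=n_precursors,
        n_families=n_families,
        n_mirnas=n_mirnas,
        frequency_denominator=denom,
    )


def family_histogram(names: Iterable[str]) -> dict[str, int]:
    """Count members per miRNA family, parsed from miRBase-style names."""
    hist: dict[str, int] = {}
    for name in names:
        fam = parse_family(name)
        hist[fam] = hist.get(fam, 0) + 1
    return hist


def reports_to_frame(reports: Sequence[HairpinReport]) -> pd.DataFrame:
    """Table-1-style DataFrame (one row per candidate, full precision)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "candidate_id": r.candidate_id,
                "family": r.family,
                "LP": r.lp,
                "LM": r.lm,
                "A": r.counts["A"],
                "C": r.counts["C"],
                "G": r.counts["G"],
                "U": r.counts["U"],
                "AU_pct": r.au_pct,
                "GC_pct": r.gc_pct,
                "MFE": r.mfe,
                "AMFE": r.amfe_val,
                "MFEI": r.mfei_val,
                "arm": r.arm,
                "star_seq": r.star_seq,
                "star_mismatches": r.star_mismatches,
                "substitutions_vs_ref": r.substitutions_vs_ref,
                "passed": r.passed,
                "fail_reasons": ",".join(fr.value for fr in r.fail_reasons),
            }
        )
    return pd.DataFrame(rows)


def render_table(reports: Sequence[HairpinReport]) -> pd.DataFrame:
    """Printed rendition: percentages and energies to 2 dp, MFEI as
    magnitude to 2 dp."""
    df = reports_to_frame(reports)
    if df.empty:
        return df
    for col in ("AU_pct", "GC_pct", "MFE", "AMFE"):
        df[col] = df[col].round(2)
    df["MFEI"] = df["MFEI"].abs().round(2)
    return df


def stats_frame(stats: Mapping[str, FeatureStats], sd_dp: int = 3) -> pd.DataFrame:
    """Summary-statistics rendition (sd to 3 dp by default)."""
    return pd.DataFrame(
        [
            {
                "Parameter": name,
                "Mean": round(s.mean, 3),
                "StdDev": round(s.sd, sd_dp),
                "Minimum": s.min,
                "Maximum": s.max,
            }
            for name, s in stats.items()
        ]
    )
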