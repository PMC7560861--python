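"""End-to-end discovery pipeline.

Stages: reference preparation → homology scan → locus dedup → coding
filter → precursor excision and folding → hairpin screen → naming →
(optional) target prediction → summary report.  Each stage's survivor count
is logged so a run prints the familiar funnel (hits → filtered hits →
noncoding → validated precursors → named miRNAs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .coding import CodingVerdict, classify_coding
from .fold import FoldBackend, PrecursorCandidate, ViennaBackend, excise_window, fold
from .report import RunCensus, census, family_histogram, render_table, reports_to_frame
from .scan import HomologyHit, ScanConfig, dedupe_loci, scan_all
from .screen import HairpinReport, ScreenThresholds, build_report, name_mirna
from .seqio import ReferenceMature, Source, TranscriptRecord, cluster_redundant, parse_family
from .targets import TargetConfig, TargetHit, find_all_targets

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure, naming the stage and the offending record."""


@dataclass(frozen=True)
class PipelineConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    orf_threshold_aa: int = 100
    flank: int = 80
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    target: TargetConfig = field(default_factory=TargetConfig)
    backend: str = "vienna"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {"scan", "orf_threshold_aa", "flank", "thresholds", "target", "backend"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "scan" in d:
            kw["scan"] = ScanConfig(**d["scan"])
        if "thresholds" in d:
            kw["thresholds"] = ScreenThresholds(**d["thresholds"])
        if "target" in d:
            kw["target"] = TargetConfig(**d["target"])
        for k in ("orf_threshold_aa", "flank", "backend"):
            if k in d:
                kw[k] = d[k]
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    nr_refs: list[ReferenceMature]
    hits: list[HomologyHit]
    deduped_hits: list[HomologyHit]
    verdicts: list[CodingVerdict]
    noncoding_ids: set[str]
    candidates: list[PrecursorCandidate]
    reports: list[HairpinReport]
    names: dict[str, str]  # candidate_id -> assigned miRNA name
    funnel: dict[str, int]
    target_hits: list[TargetHit] = field(default_factory=list)

    @property
    def passing(self) -> list[HairpinReport]:
        return [r for r in self.reports if r.passed]

    def run_census(self) -> RunCensus:
        passing = self.passing
        fams = family_histogram(self.names.values())
        tx = {r.candidate_id.split(":")[0] for r in passing}
        return census(
            n_candidate_est=self.funnel.get("input_est", 0),
            n_candidate_tsa=self.funnel.get("input_tsa", 0),
            n_precursors=len(tx),
            n_mirnas=len(passing),
            n_families=len(fams),
        )


def run_discovery(
    transcripts: Sequence[TranscriptRecord],
    refs: Sequence[ReferenceMature],
    cfg: PipelineConfig = PipelineConfig(),
    external_coding_hits: set[str] | None = None,
    backend: FoldBackend | None = None,
    with_targets: Sequence[TranscriptRecord] | None = None,
) -> DiscoveryResult:
    """Run the in-memory discovery pipeline and return all stage outputs."""
    if not transcripts:
        raise PipelineError("prep: no input sequences")
    if not refs:
        raise PipelineError("prep: no reference miRNAs")
    backend = backend if backend is not None else ViennaBackend()
    funnel: dict[str, int] = {
        "input_transcripts": len(transcripts),
        "input_est": sum(1 for t in transcripts if t.source is Source.EST),
        "input_tsa": sum(1 for t in transcripts if t.source is Source.TSA),
        "input_refs": len(refs),
    }

    nr_refs = cluster_redundant(list(refs))
    funnel["nr_refs"] = len(nr_refs)
    log.info("prep: %d references → %d non-redundant", len(refs), len(nr_refs))

    hits = scan_all(list(transcripts), nr_refs, cfg.scan)
    funnel["hits"] = len(hits)
    deduped = dedupe_loci(hits)
    funnel["hits_deduped"] = len(deduped)
    log.info("scan: %d hits, %d after locus dedup", len(hits), len(deduped))

    by_id = {t.id: t for t in transcripts}
    order = {tid: k for k, tid in enumerate(by_id)}
    hit_ids = sorted({h.transcript_id for h in deduped}, key=order.__getitem__)
    funnel["transcripts_with_hits"] = len(hit_ids)
    verdicts = [
        classify_coding(by_id[i], cfg.orf_threshold_aa, external_coding_hits)
        for i in hit_ids
    ]
    noncoding_ids = {v.transcript_id for v in verdicts if not v.coding}
    funnel["noncoding"] = len(noncoding_ids)
    log.info(
        "coding filter: %d hit transcripts → %d noncoding", len(hit_ids), len(noncoding_ids)
    )

    candidates: list[PrecursorCandidate] = []
    folded: list[tuple[PrecursorCandidate, HairpinReport]] = []
    reports: list[HairpinReport] = []
    for h in deduped:
        if h.transcript_id not in noncoding_ids:
            continue
        cand = excise_window(by_id[h.transcript_id], h, cfg.flank)
        if cand is None:
            continue
        candidates.append(cand)
        fr = fold(cand, backend)
        if fr is None:
            log.debug("fold: %s discarded (no structure)", cand.id)
            continue
        report = build_report(
            cand, fr, backend,
            family=parse_family(h.ref_id),
            thresholds=cfg.thresholds,
        )
        reports.append(report)
    funnel["candidates"] = len(candidates)
    funnel["screened"] = len(reports)
    passing = [r for r in reports if r.passed]
    funnel["passed"] = len(passing)
    log.info(
        "fold+screen: %d candidates → %d screened → %d passed",
        len(candidates), len(reports), len(passing),
    )

    names: dict[str, str] = {}
    for r in passing:
        names[r.candidate_id] = name_mirna(r.family, r.arm, set(names.values()))
    funnel["families"] = len(family_histogram(names.values()))

    result = DiscoveryResult(
        nr_refs=nr_refs,
        hits=hits,
        deduped_hits=deduped,
        verdicts=verdicts,
        noncoding_ids=noncoding_ids,
        candidates=candidates,
        reports=reports,
        names=names,
        funnel=funnel,
    )

    if with_targets is not None and passing:
        mirnas = [(names[r.candidate_id], r.mature_seq.replace("U", "T")) for r in passing]
        result.target_hits = find_all_targets(mirnas, list(with_targets), cfg.target)
        funnel["target_hits"] = len(result.target_hits)
        log.info("targets: %d hits", len(result.target_hits))
    return result


def write_run(out_dir: str | Path, result: DiscoveryResult, cfg: PipelineConfig) -> Path:
    """Write the standard run directory: stage TSVs, FASTAs and a manifest."""
    import pandas as pd

    from .scan import hits_to_rows

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(hits_to_rows(result.deduped_hits)).to_csv(out / "hits.tsv", sep="\t", index=False)
    (out / "noncoding_ids.txt").write_text("".join(f"{i}\n" for i in sorted(result.noncoding_ids)))
    reports_to_frame(result.reports).to_csv(out / "candidates.tsv", sep="\t", index=False)
    render_table(result.passing).to_csv(out / "table1.tsv", sep="\t", index=False)
    with (out / "mature.fa").open("w") as fh:
        for r in result.passing:
            fh.write(f">{result.names[r.candidate_id]}\n{r.mature_seq}\n")
    with (out / "precursors.fa").open("w") as fh:
        for r in result.passing:
            fh.write(f">{r.candidate_id}\n{r.precursor_seq}\n")
    if result.target_hits:
        pd.DataFrame(
            [
                {
                    "mirna_id": h.mirna_id,
                    "target_id": h.target_id,
                    "start1": h.target_start + 1,
                    "end1": h.target_end,
                    "expectation": h.expectation,
                    "mode": h.mode.value,
                }
                for h in result.target_hits
            ]
        ).to_csv(out / "targets.tsv", sep="\t", index=False)
    manifest = {
        "tool": "mirhom",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "funnel": result.funnel,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
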