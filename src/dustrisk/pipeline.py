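"""Full-pipeline orchestration: QC → size distribution → indices → risk.

``run_pipeline`` executes the stages in order on a loaded study bundle,
writes the long-format machine tables plus the rendered summary, and
records a manifest with input/artifact digests so identical inputs
yield identical digests.  In strict QC mode a totals-screen failure
aborts before any index is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .fractions import ValidationError
from .indices import PollutionResult, compute_pollution, index_summary
from .qaqc import (
    CrmMeasurement,
    DuplicatePair,
    median_rpd_by_analyte,
    screen_recoveries,
    totals_screen,
)
from .report import build_manifest, render_summary
from .risk import RiskResult, compute_risk
from .sizedist import aggregate_by_land_use, summarize_site
from .study import StudyBundle, load_study

log = logging.getLogger("dustrisk")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineResult:
    qc_report: pd.DataFrame | None
    size_summary: pd.DataFrame
    pollution: PollutionResult
    risk: RiskResult
    summary_text: str


def run_pipeline(bundle: StudyBundle,
                 crms: Sequence[CrmMeasurement] = (),
                 duplicates: Sequence[DuplicatePair] = (),
                 totals: pd.Series | None = None,
                 strict_qc: bool = False,
                 as_printed_ladd: bool = False) -> PipelineResult:
    """Execute all stages on an in-memory bundle."""
    # -- QC ---------------------------------------------------------------
    try:
        qc_parts = []
        if crms:
            rec = screen_recoveries(list(crms))
            rec.insert(0, "metric", "recovery")
            qc_parts.append(rec)
            for row in rec[~rec["passed"]].itertuples(index=False):
                log.warning("QC recovery fail: %s (%.1f%%) %s",
                            row.analyte, row.mean_recovery_pct, row.note)
        if duplicates:
            rpd = median_rpd_by_analyte(list(duplicates))
            rpd.insert(0, "metric", "median_rpd")
            qc_parts.append(rpd)
            for row in rpd[rpd["flagged"]].itertuples(index=False):
                log.warning("QC precision flag: %s median RPD %.1f%%",
                            row.analyte, row.median_rpd_pct)
        qc_report = pd.concat(qc_parts, ignore_index=True) if qc_parts else None
        if totals is not None:
            refused = totals_screen(totals)
            if not refused.empty:
                for row in refused.itertuples(index=False):
                    log.warning("totals screen: %s/%s total %.2f wt%% — %s",
                                row.site_id, row.fraction_label, row.total_wt_pct, row.note)
                if strict_qc:
                    raise ValidationError(
                        f"{len(refused)} (site, fraction) pairs failed the totals screen")
    except ValidationError as e:
        raise StageError("qc", e)

    # -- size distribution -------------------------------------------------
    try:
        summaries = [summarize_site(s, bundle.scheme) for s in bundle.sites]
        per_site = pd.DataFrame([{
            "site_id": s.site_id, "land_use": s.land_use,
            "yield_g_per_m2": s.yield_g_per_m2,
            "inhalable_share_pct": s.inhalable_share_pct,
            **s.percents.to_dict()} for s in summaries])
        by_class = aggregate_by_land_use(summaries).add_prefix("class_")
        size_summary = per_site
        size_summary.attrs["by_land_use"] = by_class
    except ValidationError as e:
        raise StageError("size", e)

    # -- pollution indices ---------------------------------------------------
    try:
        pollution = compute_pollution(bundle.concentrations, bundle.background,
                                      bundle.conservative_analytes)
    except ValidationError as e:
        raise StageError("indices", e)

    # -- exposure & risk -----------------------------------------------------
    try:
        risk = compute_risk(bundle, as_printed=as_printed_ladd)
        assessed = set(risk.doses.loc[risk.doses["hq"].notna(), "analyte"])
        for a in sorted(set(risk.doses["analyte"]) - assessed):
            log.info("risk: analyte %s has no assessable route (no RfD)", a)
    except ValidationError as e:
        raise StageError("risk", e)

    return PipelineResult(
        qc_report=qc_report, size_summary=size_summary,
        pollution=pollution, risk=risk,
        summary_text=render_summary(pollution, risk))


def run_from_paths(concentrations: str | Path, sites: str | Path,
                   config: str | Path, out_dir: str | Path,
                   strict_qc: bool = False,
                   as_printed_ladd: bool = False) -> Path:
    """Load, run, and write the report bundle; returns the output dir.

    Emits ``qc_report.csv`` (when QC inputs exist), ``size_summary.csv``,
    ``pollution.csv``, ``risk_doses.csv``, ``risk_carcinogenic.csv``,
    ``summary.txt`` and ``manifest.json``.
    """
    bundle = load_study(concentrations, sites, config)
    result = run_pipeline(bundle, strict_qc=strict_qc, as_printed_ladd=as_printed_ladd)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        artifacts[name] = p

    if result.qc_report is not None:
        emit("qc_report", result.qc_report)
    emit("size_summary", result.size_summary)
    emit("pollution", result.pollution.table)
    emit("pollution_by_fraction", result.pollution.by_fraction)
    emit("risk_doses", result.risk.doses)
    emit("risk_hazard", result.risk.hazard)
    emit("risk_carcinogenic", result.risk.carcinogenic)

    summary_path = out / "summary.txt"
    summary_path.write_text(result.summary_text + "\n")
    artifacts["summary"] = summary_path

    manifest = build_manifest(
        Path(config),
        inputs={"concentrations": Path(concentrations), "sites": Path(sites)},
        artifacts=artifacts, version=__version__)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return out
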