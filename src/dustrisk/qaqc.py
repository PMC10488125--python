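"""Analytical quality-control screening.

Accuracy is judged from certified reference material (CRM) recoveries
(measured/certified × 100) against a 70–120 % window; certified values
close to the detection limit can blow recoveries past 200 % without
implying a calibration problem, so those are annotated and excluded
from the accuracy judgement.  Precision is the median relative percent
difference (RPD) between analytical duplicates,

    RPD = 100 · |a − b| / ((a + b) / 2),

flagged above a configurable ceiling.  A fusion-analysis totals screen
lists (site, fraction) pairs whose major-oxide + LOI sum falls outside
98.5–101 wt% for re-analysis.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .fractions import ValidationError

#: Recovery window regarded as good accuracy, percent.
DEFAULT_RECOVERY_WINDOW = (70.0, 120.0)
#: Median-RPD precision ceiling, percent.
DEFAULT_RPD_CEILING = 10.0
#: Acceptable major-oxide + LOI total, wt%.
TOTALS_WINDOW = (98.5, 101.0)
#: certified < NEAR_LOD_FACTOR × LOD marks a measurement LOD-proximal.
NEAR_LOD_FACTOR = 10.0


@dataclass(frozen=True)
class CrmMeasurement:
    """One certified/measured pair for a reference material."""

    crm_id: str
    analyte: str
    certified_value: float
    measured_value: float
    lod: float | None = None

    @property
    def near_lod(self) -> bool:
        return self.lod is not None and self.certified_value < NEAR_LOD_FACTOR * self.lod


@dataclass(frozen=True)
class DuplicatePair:
    """One analytical duplicate observation."""

    sample_id: str
    analyte: str
    value_a: float
    value_b: float

    def __post_init__(self) -> None:
        if self.value_a < 0 or self.value_b < 0:
            raise ValidationError(
                f"duplicate {self.sample_id}/{self.analyte}: values must be >= 0")


def recovery_rate(m: CrmMeasurement) -> float:
    """Percent recovery, 100 × measured / certified."""
    if m.certified_value <= 0:
        raise ValidationError(
            f"recovery undefined for {m.crm_id}/{m.analyte}: certified value "
            f"{m.certified_value} is not positive")
    return 100.0 * m.measured_value / m.certified_value


def screen_recoveries(ms: Sequence[CrmMeasurement],
                      window: tuple[float, float] = DEFAULT_RECOVERY_WINDOW,
                      ) -> pd.DataFrame:
    """Per-analyte accuracy report over pooled CRM measurements.

    Mean recovery is an unweighted mean over all measurements of the
    analyte.  An analyte whose mean falls outside ``window`` fails;
    failures driven by LOD-proximal certificates are annotated
    ``LOD-proximal, exclude from accuracy judgement`` instead of being
    treated as genuine inaccuracy.

    Returns a frame with columns ``analyte, n, mean_recovery_pct,
    passed, note`` (empty frame for empty input).
    """
    lo, hi = window
    rows = []
    by_analyte: dict[str, list[CrmMeasurement]] = {}
    for m in ms:
        by_analyte.setdefault(m.analyte, []).append(m)
    for analyte in sorted(by_analyte):
        group = by_analyte[analyte]
        recs = [recovery_rate(m) for m in group]
        mean = sum(recs) / len(recs)
        ok = lo <= mean <= hi
        note = ""
        if not ok and any(m.near_lod for m in group):
            note = "LOD-proximal, exclude from accuracy judgement"
        rows.append({"analyte": analyte, "n": len(group),
                     "mean_recovery_pct": mean, "passed": ok, "note": note})
    return pd.DataFrame(rows, columns=["analyte", "n", "mean_recovery_pct", "passed", "note"])


def relative_percent_difference(p: DuplicatePair) -> float:
    """RPD in percent: absolute difference over the pair mean."""
    mean = 0.5 * (p.value_a + p.value_b)
    if mean <= 0:
        raise ValidationError(
            f"RPD undefined for {p.sample_id}/{p.analyte}: pair mean is zero")
    return 100.0 * abs(p.value_a - p.value_b) / mean


def median_rpd_by_analyte(ps: Sequence[DuplicatePair],
                          ceiling: float = DEFAULT_RPD_CEILING) -> pd.DataFrame:
    """Per-analyte median RPD with a precision flag above ``ceiling``.

    Median over an even number of pairs is the midpoint of the central
    order statistics.  Returns columns ``analyte, n_pairs,
    median_rpd_pct, flagged``.
    """
    by_analyte: dict[str, list[float]] = {}
    for p in ps:
        by_analyte.setdefault(p.analyte, []).append(relative_percent_difference(p))
    rows = [{"analyte": a, "n_pairs": len(v),
             "median_rpd_pct": statistics.median(v),
             "flagged": statistics.median(v) > ceiling}
            for a, v in sorted(by_analyte.items())]
    return pd.DataFrame(rows, columns=["analyte", "n_pairs", "median_rpd_pct", "flagged"])


def totals_screen(totals: pd.Series,
                  window: tuple[float, float] = TOTALS_WINDOW) -> pd.DataFrame:
    """Screen per-(site, fraction) major-oxide + LOI wt% sums.

    ``totals`` is indexed by (site_id, fraction_label).  Pairs outside
    the window are listed for re-analysis; low totals carry the
    standard annotation for unscanned components.
    """
    lo, hi = window
    rows = []
    for key, total in totals.items():
        if lo <= total <= hi:
            continue
        note = ("possible sulfidic/sulfated sulfur or unscanned Li/F"
                if total < lo else "total above closure window")
        site, frac = key if isinstance(key, tuple) else (key, "")
        rows.append({"site_id": site, "fraction_label": frac,
                     "total_wt_pct": float(total), "note": note})
    return pd.DataFrame(rows, columns=["site_id", "fraction_label", "total_wt_pct", "note"])
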