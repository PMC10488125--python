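"""Enrichment factor and geo-accumulation index with classification scales.

The enrichment factor double-normalises an element X against a
conservative reference sum E_ref (here the summed Al₂O₃ + MgO + Na₂O +
K₂O + TiO₂ + P₂O₅ concentrations):

    EF_x = (X / E_ref)_sample / (X / E_ref)_background

so any common rescaling of one layer cancels.  The geo-accumulation
index compares a concentration to 1.5× its geogenic background on a
log₂ scale:

    Igeo = log2(C / (1.5 · B))

with Müller's seven contamination classes.  Both are computed per
analyte × site × fraction, then summarised as unweighted cross-site
means per fraction with finest/coarsest ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fractions import FractionScheme, ValidationError
from .study import BackgroundReference, ConcentrationTable, StudyBundle

EF_CLASSES = (
    (2.0, "deficiency to minimal enrichment"),
    (5.0, "moderate enrichment"),
    (20.0, "significant enrichment"),
    (40.0, "very high enrichment"),
    (float("inf"), "extremely high enrichment"),
)

IGEO_LABELS = (
    "no contamination",
    "uncontaminated to moderate contamination",
    "moderate contamination",
    "moderate to heavy contamination",
    "heavy contamination",
    "heavy to extreme contamination",
    "extremely contaminated",
)


def reference_sum(concentrations: Mapping[str, float] | pd.Series,
                  conservative_set: Sequence[str]) -> float:
    """E_ref: arithmetic sum of the conservative components.

    Sample and background must be summed on the same basis (the basis
    cancels in the EF double ratio as long as it is consistent).
    """
    total = 0.0
    for name in conservative_set:
        try:
            v = float(concentrations[name])
        except (KeyError, TypeError):
            raise ValidationError(f"conservative analyte {name!r} missing from table")
        if np.isnan(v):
            raise ValidationError(f"conservative analyte {name!r} missing from table")
        total += v
    return total


def enrichment_factor(xi_sample: float, eref_sample: float,
                      xi_background: float, eref_background: float) -> float:
    """EF = (Xi/Eref)_sample / (Xi/Eref)_background."""
    for name, v in (("xi_sample", xi_sample), ("eref_sample", eref_sample),
                    ("xi_background", xi_background), ("eref_background", eref_background)):
        if v <= 0:
            raise ValidationError(f"enrichment factor undefined: {name} = {v} (must be > 0)")
    return (xi_sample / eref_sample) / (xi_background / eref_background)


def classify_enrichment(ef: float) -> str:
    """Five-level enrichment label; upper classes are left-closed."""
    if ef <= 0:
        raise ValidationError(f"EF must be positive, got {ef}")
    for upper, label in EF_CLASSES:
        if ef < upper:
            return label
    return EF_CLASSES[-1][1]


def geoaccumulation_index(cn: float, bn: float) -> float:
    """Igeo = log2(cn / (1.5 · bn)); requires positive inputs."""
    if cn <= 0 or bn <= 0:
        raise ValidationError(f"Igeo undefined for cn={cn}, bn={bn} (must be > 0)")
    return float(np.log2(cn / (1.5 * bn)))


def classify_igeo(igeo: float, four_in_heavy: bool = True) -> str:
    """Seven-level Müller contamination label.

    The published scale states both "3 < Igeo ≤ 4" and "4 ≤ Igeo < 5";
    by default 4 is assigned to heavy contamination, i.e. the classes
    partition the line as (−∞,0], (0,1], (1,2], (2,3], (3,4], (4,5),
    [5,∞).  ``four_in_heavy=False`` moves 4 to heavy-to-extreme,
    using (3,4) and [4,5) instead.
    """
    if not np.isfinite(igeo):
        raise ValidationError(f"Igeo must be finite, got {igeo}")
    if igeo <= 0:
        return IGEO_LABELS[0]
    for k in (1, 2, 3):
        if igeo <= k:
            return IGEO_LABELS[k]
    if igeo >= 5:
        return IGEO_LABELS[6]
    in_heavy = igeo <= 4.0 if four_in_heavy else igeo < 4.0
    return IGEO_LABELS[4] if in_heavy else IGEO_LABELS[5]


@dataclass(frozen=True)
class PollutionResult:
    """Long results plus per-fraction cross-site summaries.

    ``table`` has one row per (site, fraction, analyte) with EF, EF
    class, Igeo and Igeo class; ``by_fraction`` holds unweighted
    cross-site means of EF and Igeo per (fraction, analyte).
    """

    table: pd.DataFrame
    by_fraction: pd.DataFrame


def compute_pollution(concentrations: ConcentrationTable,
                      background: BackgroundReference,
                      conservative_set: Sequence[str],
                      analytes: Sequence[str] | None = None,
                      four_in_heavy: bool = True) -> PollutionResult:
    """EF and Igeo for every (site, fraction, analyte).

    ``analytes`` defaults to every analyte present in both the table
    and the background (conservative components excluded from the
    indexed set but required for E_ref).
    """
    background.require(list(conservative_set))
    eref_b = reference_sum(background.values, conservative_set)

    if analytes is None:
        analytes = [a for a in concentrations.analytes
                    if a in background.values.index and a not in conservative_set]
    else:
        background.require(list(analytes))
        missing = [a for a in analytes if a not in concentrations.analytes]
        if missing:
            raise ValidationError(f"analytes {missing} absent from concentration table")

    rows = []
    for site, frac in concentrations.pairs:
        sample = concentrations.values.loc[(site, frac)]
        eref_s = reference_sum(sample, conservative_set)
        for a in analytes:
            c = float(sample[a])
            if np.isnan(c):
                continue
            b = float(background.values[a])
            if c <= 0:
                rows.append({"site_id": site, "fraction_label": frac, "analyte": a,
                             "ef": np.nan, "ef_class": "undefined",
                             "igeo": np.nan, "igeo_class": "undefined"})
                continue
            ef = enrichment_factor(c, eref_s, b, eref_b)
            ig = geoaccumulation_index(c, b)
            rows.append({"site_id": site, "fraction_label": frac, "analyte": a,
                         "ef": ef, "ef_class": classify_enrichment(ef),
                         "igeo": ig, "igeo_class": classify_igeo(ig, four_in_heavy)})
    table = pd.DataFrame(rows)
    by_fraction = (table.groupby(["fraction_label", "analyte"])[["ef", "igeo"]]
                   .mean().reset_index())
    return PollutionResult(table=table, by_fraction=by_fraction)


def index_summary(result: PollutionResult, scheme: FractionScheme) -> pd.DataFrame:
    """Per-analyte mean EF/Igeo per fraction with finest/coarsest ratio.

    Returns a frame indexed by analyte with columns ``ef_<label>`` and
    ``igeo_<label>`` for each bin plus ``ef_fine_coarse_ratio`` =
    mean EF(finest) / mean EF(coarsest analysed bin).
    """
    finest, coarsest = scheme.labels[0], scheme.labels[-1]
    wide_ef = result.by_fraction.pivot(index="analyte", columns="fraction_label", values="ef")
    wide_ig = result.by_fraction.pivot(index="analyte", columns="fraction_label", values="igeo")
    out = pd.DataFrame(index=wide_ef.index)
    for lb in scheme.labels:
        if lb in wide_ef.columns:
            out[f"ef_{lb}"] = wide_ef[lb]
            out[f"igeo_{lb}"] = wide_ig[lb]
    if finest in wide_ef.columns and coarsest in wide_ef.columns:
        out["ef_fine_coarse_ratio"] = wide_ef[finest] / wide_ef[coarsest]
    return out


def boxplot_stats(result: PollutionResult, value: Literal["ef", "igeo"] = "ef",
                  ) -> pd.DataFrame:
    """Min/Q1/median/Q3/max of EF or Igeo per (fraction, analyte)."""
    g = result.table.groupby(["fraction_label", "analyte"])[value]
    return pd.DataFrame({
        "min": g.min(), "q1": g.quantile(0.25), "median": g.median(),
        "q3": g.quantile(0.75), "max": g.max()}).reset_index()
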