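"""Three-route exposure doses and non-carcinogenic / carcinogenic risk.

Average daily doses (mg kg⁻¹ d⁻¹) of a dust-borne element at
concentration C (mg kg⁻¹) follow the USEPA residential equations:

    ADD_ing    = C · IngR · CF · EF · ED / (BW · AT)
    ADD_inh    = C · InhR · EF · ED / (PEF · BW · AT)
    ADD_dermal = C · SA · CF · AF · ABF · EF · ED / (BW · AT)

with AT = 365 · ED days for non-carcinogenic endpoints.  Hazard
quotients HQ = ADD/RfD add across routes into the hazard index HI;
HI ≤ 1 means no significant non-carcinogenic risk.

Carcinogenic risk uses the lifetime average daily dose, age-adjusted
across childhood and adulthood with route-specific contact rates CR
(ingestion IngR·CF, inhalation InhR/PEF, dermal SA·AF·ABF·CF):

    LADD = C · EF / AT_carc · Σ_receptor CR · ED / BW

and CRI = LADD · SF, classed negligible below 10⁻⁶, tolerable in
[10⁻⁶, 10⁻⁴] and harmful above, with an optional stricter 10⁻⁵
regulatory flag.  Routes lacking an RfD or SF are skipped, never
imputed.  Every quantity is degree-1 homogeneous in concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fractions import ValidationError
from .params import (
    RECEPTORS,
    ROUTES,
    ExposureFactorSet,
    Receptor,
    ReceptorFactors,
    Route,
    ToxicityReference,
)
from .study import StudyBundle

CRI_NEGLIGIBLE = 1.0e-6
CRI_HARMFUL = 1.0e-4
CRI_STRICT_FLAG = 1.0e-5


def _receptor(f: ExposureFactorSet, receptor: str) -> ReceptorFactors:
    if receptor not in RECEPTORS:
        raise ValidationError(f"unknown receptor {receptor!r}; expected child or adult")
    return f.receptor(receptor)  # type: ignore[arg-type]


def _check_conc(c: float) -> float:
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c}")
    return float(c)


def add_ingestion(c: float, f: ExposureFactorSet, receptor: Receptor) -> float:
    """ADD via incidental dust ingestion, mg kg⁻¹ d⁻¹."""
    c = _check_conc(c)
    r = _receptor(f, receptor)
    return (c * r.ing_r * r.cf_kg_mg * r.ef_days * r.ed_years
            / (r.bw_kg * r.at_noncarc_days))


def add_inhalation(c: float, f: ExposureFactorSet, receptor: Receptor) -> float:
    """ADD via inhalation of resuspended dust, mg kg⁻¹ d⁻¹."""
    c = _check_conc(c)
    r = _receptor(f, receptor)
    return (c * r.inh_r * r.ef_days * r.ed_years
            / (f.pef * r.bw_kg * r.at_noncarc_days))


def add_dermal(c: float, f: ExposureFactorSet, receptor: Receptor) -> float:
    """ADD via dermal absorption of adhered dust, mg kg⁻¹ d⁻¹."""
    c = _check_conc(c)
    r = _receptor(f, receptor)
    return (c * r.sa_cm2 * r.cf_kg_mg * r.af_mg_cm2 * r.abf * r.ef_days * r.ed_years
            / (r.bw_kg * r.at_noncarc_days))


_ADD_FUNCS = {"ingestion": add_ingestion, "inhalation": add_inhalation, "dermal": add_dermal}


def average_daily_dose(c: float, f: ExposureFactorSet, receptor: Receptor,
                       route: Route) -> float:
    try:
        return _ADD_FUNCS[route](c, f, receptor)
    except KeyError:
        raise ValidationError(f"unknown route {route!r}; expected one of {ROUTES}")


def hazard_quotient(add: float, rfd: float | None) -> float | None:
    """HQ = ADD / RfD; ``None`` (route not assessed) when RfD is absent."""
    if rfd is None:
        return None
    if rfd <= 0:
        raise ValidationError(f"RfD must be > 0, got {rfd}")
    if add < 0:
        raise ValidationError(f"ADD must be >= 0, got {add}")
    return add / rfd


def hazard_index(hqs: Iterable[float | None]) -> float:
    """HI: sum of the available route HQ terms (absent routes skipped)."""
    terms = [h for h in hqs if h is not None]
    if not terms:
        raise ValidationError("hazard index needs at least one assessed route")
    return float(sum(terms))


def contact_rate(f: ExposureFactorSet, r: ReceptorFactors, route: Route) -> float:
    """Route-specific contact rate CR used in the lifetime dose.

    Ingestion IngR·CF (kg d⁻¹ of dust), inhalation InhR/PEF (kg d⁻¹
    equivalent via the particulate emission factor, applied exactly
    once here), dermal SA·AF·ABF·CF.
    """
    if route == "ingestion":
        return r.ing_r * r.cf_kg_mg
    if route == "inhalation":
        return r.inh_r / f.pef
    if route == "dermal":
        return r.sa_cm2 * r.af_mg_cm2 * r.abf * r.cf_kg_mg
    raise ValidationError(f"unknown route {route!r}; expected one of {ROUTES}")


def lifetime_average_daily_dose(c: float, f: ExposureFactorSet, route: Route,
                                as_printed: bool = False) -> float:
    """Age-adjusted LADD over childhood + adulthood, mg kg⁻¹ d⁻¹.

    Default form: C · EF / AT_carc · Σ_r CR_r · ED_r / BW_r, with the
    particulate emission factor applied exactly once, inside the
    inhalation contact rate.  ``as_printed=True`` reproduces the
    typeset variant that sums CR + ED/BW and divides every route by
    PEF globally — retained for sensitivity analysis only.
    """
    c = _check_conc(c)
    receptors = (f.child, f.adult)
    if as_printed:
        s = sum(contact_rate(f, r, route) + r.ed_years / r.bw_kg for r in receptors)
        return c * f.child.ef_days / (f.at_carc_days * f.pef) * s
    s = sum(contact_rate(f, r, route) * r.ed_years / r.bw_kg for r in receptors)
    return c * f.child.ef_days / f.at_carc_days * s


def classify_cri(cri: float) -> str:
    """Negligible / tolerable / harmful against the 10⁻⁶–10⁻⁴ band."""
    if cri < 0:
        raise ValidationError(f"CRI must be >= 0, got {cri}")
    if cri < CRI_NEGLIGIBLE:
        return "negligible"
    if cri <= CRI_HARMFUL:
        return "tolerable"
    return "harmful"


def carcinogenic_risk(ladd: float, sf: float | None) -> tuple[float, str, bool] | None:
    """CRI = LADD × SF with class label and the stricter 10⁻⁵ flag.

    Returns ``(cri, class, above_strict_threshold)``; ``None`` when the
    route has no slope factor (not assessed).
    """
    if sf is None:
        return None
    if sf <= 0:
        raise ValidationError(f"slope factor must be > 0, got {sf}")
    if ladd < 0:
        raise ValidationError(f"LADD must be >= 0, got {ladd}")
    cri = ladd * sf
    return cri, classify_cri(cri), cri > CRI_STRICT_FLAG


def contribution_shares(components: pd.Series) -> pd.Series:
    """Percent share of each component in the total; shares sum to 100."""
    total = float(components.sum())
    if total <= 0:
        raise ValidationError("contribution shares undefined: total is zero")
    return 100.0 * components / total


@dataclass(frozen=True)
class RiskResult:
    """Full dose/risk output of one study.

    ``doses`` — one row per (site, fraction, receptor, analyte, route)
    with ADD and HQ (HQ is NaN where the route has no RfD);
    ``hazard`` — per (site, fraction, receptor, analyte): ∑ADD, HI and
    per-route availability; ``carcinogenic`` — per (site, fraction,
    analyte, route): LADD, CRI, class, strict flag; ``hi_totals`` —
    per (site, fraction, receptor): HI summed over analytes with
    per-analyte contribution shares.
    """

    doses: pd.DataFrame
    hazard: pd.DataFrame
    carcinogenic: pd.DataFrame
    hi_totals: pd.DataFrame

    def hi_shares(self, receptor: Receptor = "child") -> pd.Series:
        """Mean per-analyte percent contribution to total HI."""
        sub = self.hazard[self.hazard["receptor"] == receptor]
        per_analyte = sub.groupby("analyte")["hi"].sum()
        return contribution_shares(per_analyte).sort_values(ascending=False)

    def cri_shares(self) -> pd.Series:
        """Per-analyte percent contribution to summed CRI."""
        per_analyte = self.carcinogenic.groupby("analyte")["cri"].sum()
        return contribution_shares(per_analyte).sort_values(ascending=False)


def compute_risk(bundle: StudyBundle, analytes: Sequence[str] | None = None,
                 as_printed: bool = False) -> RiskResult:
    """Run the full dose/risk model over a study bundle.

    ``analytes`` defaults to every analyte with at least one RfD or SF
    entry that is present in the concentration table.
    """
    tox = bundle.toxicity
    conc = bundle.concentrations
    f = bundle.exposure
    if analytes is None:
        analytes = [a for a in tox.analytes if a in conc.analytes]

    dose_rows, hazard_rows, carc_rows = [], [], []
    for site, frac in conc.pairs:
        sample = conc.values.loc[(site, frac)]
        for a in analytes:
            c = float(sample.get(a, np.nan))
            if np.isnan(c):
                continue
            # non-carcinogenic, per receptor
            for receptor in RECEPTORS:
                hqs = []
                total_add = 0.0
                for route in ROUTES:
                    add = average_daily_dose(c, f, receptor, route)
                    total_add += add
                    hq = hazard_quotient(add, tox.rfd_for(a, route))
                    hqs.append(hq)
                    dose_rows.append({
                        "site_id": site, "fraction_label": frac, "receptor": receptor,
                        "analyte": a, "route": route, "add": add,
                        "hq": np.nan if hq is None else hq})
                if any(h is not None for h in hqs):
                    hazard_rows.append({
                        "site_id": site, "fraction_label": frac, "receptor": receptor,
                        "analyte": a, "sum_add": total_add, "hi": hazard_index(hqs),
                        "n_routes_assessed": sum(h is not None for h in hqs)})
            # carcinogenic, receptor-integrated
            if a in tox.carcinogens:
                for route in ROUTES:
                    sf = tox.sf_for(a, route)
                    if sf is None:
                        continue
                    ladd = lifetime_average_daily_dose(c, f, route, as_printed=as_printed)
                    cri, label, strict = carcinogenic_risk(ladd, sf)
                    carc_rows.append({
                        "site_id": site, "fraction_label": frac, "analyte": a,
                        "route": route, "ladd": ladd, "cri": cri,
                        "cri_class": label, "above_1e5": strict})

    doses = pd.DataFrame(dose_rows)
    hazard = pd.DataFrame(hazard_rows)
    carcinogenic = pd.DataFrame(
        carc_rows, columns=["site_id", "fraction_label", "analyte", "route",
                            "ladd", "cri", "cri_class", "above_1e5"])

    hi_rows = []
    if not hazard.empty:
        for (site, frac, receptor), grp in hazard.groupby(
                ["site_id", "fraction_label", "receptor"]):
            total = grp["hi"].sum()
            shares = contribution_shares(grp.set_index("analyte")["hi"])
            hi_rows.append({
                "site_id": site, "fraction_label": frac, "receptor": receptor,
                "total_hi": total,
                "top_analyte": shares.idxmax(), "top_share_pct": shares.max()})
    hi_totals = pd.DataFrame(hi_rows, columns=["site_id", "fraction_label", "receptor",
                                               "total_hi", "top_analyte", "top_share_pct"])
    return RiskResult(doses=doses, hazard=hazard, carcinogenic=carcinogenic,
                      hi_totals=hi_totals)
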