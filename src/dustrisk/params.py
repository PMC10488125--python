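"""Receptor exposure factors and route-specific toxicity references.

The exposure model follows the USEPA residential dust scenario with two
receptor groups, children and adults, exposed by ingestion, inhalation
and dermal contact.  Defaults are the study values: short exposure
frequency (27 d y⁻¹, outdoor contact in a Mediterranean urban setting),
child/adult ingestion rates of 200/100 mg d⁻¹, and a particulate
emission factor of 1.36 × 10⁹ m³ kg⁻¹ linking dust concentration to an
equivalent air concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import pandas as pd

from .fractions import ValidationError

Route = Literal["ingestion", "inhalation", "dermal"]
ROUTES: tuple[Route, ...] = ("ingestion", "inhalation", "dermal")

Receptor = Literal["child", "adult"]
RECEPTORS: tuple[Receptor, ...] = ("child", "adult")


@dataclass(frozen=True)
class ReceptorFactors:
    """Exposure factors for one receptor group.

    Units: ``ing_r`` mg d⁻¹; ``inh_r`` m³ d⁻¹; ``ef_days`` d y⁻¹;
    ``ed_years`` y; ``bw_kg`` kg; ``sa_cm2`` cm²; ``af_mg_cm2`` mg cm⁻²;
    ``abf`` dimensionless dermal absorption fraction; ``cf_kg_mg``
    kg mg⁻¹ mass conversion.
    """

    ing_r: float
    inh_r: float
    ef_days: float
    ed_years: float
    bw_kg: float
    sa_cm2: float
    af_mg_cm2: float
    abf: float = 0.001
    cf_kg_mg: float = 1.0e-6

    def __post_init__(self) -> None:
        for name in ("ing_r", "inh_r", "ef_days", "ed_years", "bw_kg", "sa_cm2",
                     "af_mg_cm2", "cf_kg_mg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not (0.0 < self.abf <= 1.0):
            raise ValidationError(f"abf must lie in (0, 1], got {self.abf}")

    @property
    def at_noncarc_days(self) -> float:
        """Non-carcinogenic averaging time: 365 × ED days."""
        return 365.0 * self.ed_years


@dataclass(frozen=True)
class ExposureFactorSet:
    """Child and adult exposure factors plus shared parameters.

    ``pef`` is the particulate emission factor (m³ kg⁻¹); ``at_carc_days``
    the carcinogenic (lifetime) averaging time, default 70 y × 365 d.
    """

    child: ReceptorFactors = field(default_factory=lambda: ReceptorFactors(
        ing_r=200.0, inh_r=7.63, ef_days=27.0, ed_years=6.0, bw_kg=15.0,
        sa_cm2=1600.0, af_mg_cm2=0.2))
    adult: ReceptorFactors = field(default_factory=lambda: ReceptorFactors(
        ing_r=100.0, inh_r=12.8, ef_days=27.0, ed_years=24.0, bw_kg=70.0,
        sa_cm2=4350.0, af_mg_cm2=0.7))
    pef: float = 1.36e9
    at_carc_days: float = 70.0 * 365.0

    def __post_init__(self) -> None:
        if self.pef <= 0 or self.at_carc_days <= 0:
            raise ValidationError("pef and at_carc_days must be strictly positive")

    def receptor(self, receptor: Receptor) -> ReceptorFactors:
        try:
            return getattr(self, receptor)
        except AttributeError:
            raise ValidationError(f"unknown receptor {receptor!r}; expected child or adult")

    def with_overrides(self, overrides: Mapping[str, Mapping[str, float]]) -> "ExposureFactorSet":
        """New set with per-receptor/shared fields replaced from a nested mapping."""
        kw: dict = {}
        for key, val in overrides.items():
            if key in ("child", "adult"):
                kw[key] = replace(self.receptor(key), **dict(val))
            elif key in ("pef", "at_carc_days"):
                kw[key] = float(val)  # type: ignore[arg-type]
            else:
                raise ValidationError(f"unknown exposure-factor group {key!r}")
        return replace(self, **kw)


#: Table of defaults used throughout the study.
DEFAULT_EXPOSURE = ExposureFactorSet()


@dataclass(frozen=True)
class ToxicityReference:
    """Per-analyte, per-route RfD and SF with allowed absences.

    ``rfd`` maps analyte → route → reference dose (mg kg⁻¹ d⁻¹); ``sf``
    maps analyte → route → cancer slope factor ((mg kg⁻¹ d⁻¹)⁻¹).  A
    route missing from the mapping is *not assessed*: it contributes no
    HQ or CRI term.  ``carcinogens`` lists analytes assessed for cancer
    risk.
    """

    rfd: Mapping[str, Mapping[Route, float]]
    sf: Mapping[str, Mapping[Route, float]]
    carcinogens: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for table, label in ((self.rfd, "RfD"), (self.sf, "SF")):
            for analyte, routes in table.items():
                for route, value in routes.items():
                    if route not in ROUTES:
                        raise ValidationError(f"unknown route {route!r} for {analyte} {label}")
                    if value <= 0:
                        raise ValidationError(
                            f"{label} for {analyte}/{route} must be > 0, got {value}")

    def rfd_for(self, analyte: str, route: Route) -> float | None:
        return self.rfd.get(analyte, {}).get(route)

    def sf_for(self, analyte: str, route: Route) -> float | None:
        return self.sf.get(analyte, {}).get(route)

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.rfd) | set(self.sf)))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ToxicityReference":
        """Build from a long table with columns analyte, route, rfd, sf.

        Empty cells mean the value is unavailable for that route.  An
        optional boolean ``carcinogen`` column flags cancer-risk
        analytes; otherwise any analyte with an SF is flagged.
        """
        required = {"analyte", "route"}
        if not required.issubset(df.columns):
            raise ValidationError(f"toxicity table needs columns {sorted(required)}")
        rfd: dict[str, dict[str, float]] = {}
        sf: dict[str, dict[str, float]] = {}
        carc: set[str] = set()
        for row in df.itertuples(index=False):
            analyte, route = str(row.analyte), str(row.route)
            if getattr(row, "rfd", None) is not None and pd.notna(getattr(row, "rfd", None)):
                rfd.setdefault(analyte, {})[route] = float(row.rfd)
            if getattr(row, "sf", None) is not None and pd.notna(getattr(row, "sf", None)):
                sf.setdefault(analyte, {})[route] = float(row.sf)
                carc.add(analyte)
            if getattr(row, "carcinogen", False) in (True, "true", "True", 1):
                carc.add(analyte)
        return cls(rfd=rfd, sf=sf, carcinogens=frozenset(carc))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for analyte in self.analytes:
            for route in ROUTES:
                r, s = self.rfd_for(analyte, route), self.sf_for(analyte, route)
                if r is None and s is None:
                    continue
                rows.append({"analyte": analyte, "route": route, "rfd": r, "sf": s,
                             "carcinogen": analyte in self.carcinogens})
        return pd.DataFrame(rows, columns=["analyte", "route", "rfd", "sf", "carcinogen"])
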