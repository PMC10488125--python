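"""Study containers and delimited-table / config I/O.

A *study bundle* ties together everything one sieved road-dust campaign
produces: site records (area swept, mass per sieve bin, land use), the
concentration table on a common mg kg⁻¹ element basis, the geogenic
background reference, and the exposure/toxicity parameter tables used
downstream.

External formats are plain delimited text:

* concentrations — long format with columns
  ``site_id, fraction_label, analyte, value, unit, below_lod``;
* sites — ``site_id, land_use, area_swept_m2, total_mass_g`` plus one
  mass column per fraction label and ``gt_800`` for the oversize bin;
* background — ``analyte, value, unit``;
* toxicity — ``analyte, route, rfd, sf[, carcinogen]``;
* config — YAML holding the fraction scheme, file paths, the below-LOD
  substitution rule and exposure-factor overrides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .analytes import (
    AnalyteDescriptor,
    CONSERVATIVE_OXIDES,
    OXIDE_STOICHIOMETRY,
    element_descriptor,
    oxide_descriptor,
    to_mg_per_kg,
)
from .fractions import FractionScheme, ValidationError
from .params import DEFAULT_EXPOSURE, ExposureFactorSet, ToxicityReference

LodRule = Literal["zero", "half", "full"]

LAND_USES = ("urban_residential", "industrial", "mixed")


@dataclass(frozen=True)
class SiteRecord:
    """One sampling site: land use, swept area and mass per sieve bin.

    ``fraction_masses`` maps every fraction label (including the
    oversize bin) to grams collected.  The bin masses may undershoot
    ``total_mass_g`` by up to ``mass_tolerance`` (sieving losses) but
    never exceed it.
    """

    site_id: str
    land_use: str
    area_swept_m2: float
    total_mass_g: float
    fraction_masses: Mapping[str, float]
    date: str = ""
    coordinates: tuple[float, float] | None = None
    mass_tolerance: float = 0.02  # relative undershoot allowed in bin sum

    def __post_init__(self) -> None:
        if self.land_use not in LAND_USES:
            raise ValidationError(
                f"site {self.site_id}: unknown land use {self.land_use!r}; "
                f"expected one of {LAND_USES}")
        if self.area_swept_m2 <= 0:
            raise ValidationError(f"site {self.site_id}: area_swept_m2 must be > 0")
        if self.total_mass_g < 0 or any(m < 0 for m in self.fraction_masses.values()):
            raise ValidationError(f"site {self.site_id}: masses must be >= 0")
        bin_sum = sum(self.fraction_masses.values())
        if bin_sum > self.total_mass_g * (1 + self.mass_tolerance):
            raise ValidationError(
                f"site {self.site_id}: fraction masses sum to {bin_sum:.1f} g, "
                f"exceeding total mass {self.total_mass_g:.1f} g")


@dataclass(frozen=True)
class ConcentrationTable:
    """Analyte × (site, fraction) concentrations, mg kg⁻¹ element basis.

    ``values`` is a wide DataFrame indexed by a (site_id, fraction_label)
    MultiIndex with one column per analyte.  ``below_lod`` is a boolean
    frame of the same shape; a flagged cell stores the substituted value
    so the original censoring is auditable.  Cells that were never
    measured are NaN and stay NaN.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series  # per-analyte detection limit, mg kg⁻¹ element basis

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.below_lod.index) or not (
            list(self.values.columns) == list(self.below_lod.columns)
        ):
            raise ValidationError("values and below_lod frames must be aligned")
        if (self.values.to_numpy() < 0).any():
            bad = self.values.stack()
            bad = bad[bad < 0].index[0]
            raise ValidationError(f"negative concentration at {bad}")

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def pairs(self) -> pd.MultiIndex:
        return self.values.index

    def loc(self, site_id: str, fraction_label: str) -> pd.Series:
        return self.values.loc[(site_id, fraction_label)]


@dataclass(frozen=True)
class BackgroundReference:
    """Geogenic background concentrations B_n, mg kg⁻¹ element basis."""

    values: pd.Series
    source_label: str = "background"

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            bad = self.values[self.values <= 0].index[0]
            raise ValidationError(
                f"background value for {bad!r} must be > 0 for EF/Igeo")

    def require(self, analytes: Sequence[str]) -> None:
        missing = [a for a in analytes if a not in self.values.index]
        if missing:
            raise ValidationError(
                f"background reference {self.source_label!r} is missing "
                f"analyte(s) {missing} required for EF/Igeo")


@dataclass(frozen=True)
class StudyBundle:
    """Everything one campaign needs for QC, indices and risk."""

    scheme: FractionScheme
    sites: tuple[SiteRecord, ...]
    concentrations: ConcentrationTable
    background: BackgroundReference
    exposure: ExposureFactorSet
    toxicity: ToxicityReference
    descriptors: Mapping[str, AnalyteDescriptor] = field(default_factory=dict)
    lod_rule: LodRule = "half"

    def site(self, site_id: str) -> SiteRecord:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise ValidationError(f"unknown site {site_id!r}")

    @property
    def conservative_analytes(self) -> tuple[str, ...]:
        names = [n for n, d in self.descriptors.items() if d.is_conservative_reference]
        return tuple(names) if names else tuple(CONSERVATIVE_OXIDES)


def default_descriptor(analyte: str, unit: str | None = None) -> AnalyteDescriptor:
    """Descriptor inferred from the analyte name and reported unit.

    Oxide-named analytes reported in wt% get the stoichiometric
    conversion; reported in mg kg⁻¹ they are taken as already on
    element basis (the label is kept as written).
    """
    if analyte in OXIDE_STOICHIOMETRY and unit != "mg_per_kg":
        return oxide_descriptor(analyte)
    if unit == "wt_percent":
        raise ValidationError(f"analyte {analyte!r} reported in wt% but is not a known oxide")
    return dataclasses.replace(
        element_descriptor(analyte),
        is_conservative_reference=analyte in CONSERVATIVE_OXIDES)


def substitute_lod(value: float, lod: float, rule: LodRule) -> float:
    """Value stored for a below-LOD cell under the configured rule."""
    if rule == "zero":
        return 0.0
    if rule == "half":
        return 0.5 * lod
    if rule == "full":
        return lod
    raise ValidationError(f"unknown LOD rule {rule!r}; expected zero|half|full")


def _normalise_long(df: pd.DataFrame, descriptors: Mapping[str, AnalyteDescriptor],
                    lod: Mapping[str, float], rule: LodRule) -> ConcentrationTable:
    """Long-format rows → aligned wide value/flag frames on element basis."""
    req = {"site_id", "fraction_label", "analyte", "value", "unit"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"concentration table is missing columns {sorted(missing)}")
    if "below_lod" not in df.columns:
        df = df.assign(below_lod=False)
    df = df.copy()
    df["below_lod"] = df["below_lod"].astype(bool)

    values, flags = {}, {}
    lod_elem: dict[str, float] = {}
    for row in df.to_dict("records"):
        a = str(row["analyte"])
        desc = descriptors.get(a) or default_descriptor(a, str(row["unit"]))
        if str(row["unit"]) != desc.unit:
            raise ValidationError(
                f"analyte {a!r} reported in {row['unit']!r}, expected {desc.unit!r}")
        key = (str(row["site_id"]), str(row["fraction_label"]))
        if bool(row["below_lod"]):
            # the value column of a censored row holds the detection limit
            # unless an explicit per-analyte LOD is configured
            raw_lod = lod.get(a, float(row["value"]))
            lod_mg = to_mg_per_kg(float(raw_lod), desc)
            v = substitute_lod(float("nan"), lod_mg, rule)
            lod_elem.setdefault(a, lod_mg)
        else:
            v = to_mg_per_kg(float(row["value"]), desc)
            if a in lod:
                lod_elem.setdefault(a, to_mg_per_kg(float(lod[a]), desc))
        values.setdefault(a, {})[key] = v
        flags.setdefault(a, {})[key] = bool(row["below_lod"])

    vframe = pd.DataFrame(values)
    fframe = pd.DataFrame(flags).reindex(index=vframe.index, columns=vframe.columns).fillna(False)
    vframe.index = pd.MultiIndex.from_tuples(vframe.index, names=["site_id", "fraction_label"])
    fframe.index = vframe.index
    lod_series = pd.Series(lod_elem, dtype=float).reindex(vframe.columns)
    return ConcentrationTable(values=vframe.sort_index(), below_lod=fframe.sort_index(),
                              lod=lod_series)


def read_sites(path: str | Path, scheme: FractionScheme) -> tuple[SiteRecord, ...]:
    df = pd.read_csv(path)
    req = {"site_id", "land_use", "area_swept_m2", "total_mass_g"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"site table is missing columns {sorted(missing)}")
    oversize_col = "gt_800" if scheme.oversize_label == ">800" else scheme.oversize_label
    mass_cols = list(scheme.labels) + [oversize_col]
    records = []
    for row in df.to_dict("records"):
        masses = {}
        for col in mass_cols:
            if col not in df.columns:
                raise ValidationError(f"site table is missing mass column {col!r}")
            label = scheme.oversize_label if col == oversize_col else col
            masses[label] = float(row[col])
        records.append(SiteRecord(
            site_id=str(row["site_id"]), land_use=str(row["land_use"]),
            area_swept_m2=float(row["area_swept_m2"]), total_mass_g=float(row["total_mass_g"]),
            fraction_masses=masses, date=str(row.get("date", ""))))
    return tuple(records)


def read_background(path: str | Path,
                    descriptors: Mapping[str, AnalyteDescriptor] | None = None,
                    ) -> BackgroundReference:
    df = pd.read_csv(path, float_precision="round_trip")
    req = {"analyte", "value", "unit"}
    if not req.issubset(df.columns):
        raise ValidationError(f"background table needs columns {sorted(req)}")
    vals = {}
    for row in df.to_dict("records"):
        a = str(row["analyte"])
        desc = (descriptors or {}).get(a) or default_descriptor(a, str(row["unit"]))
        vals[a] = to_mg_per_kg(float(row["value"]), desc)
    return BackgroundReference(values=pd.Series(vals, dtype=float),
                               source_label=str(Path(path).name))


def load_study(concentrations_path: str | Path, sites_path: str | Path,
               config_path: str | Path) -> StudyBundle:
    """Load and cross-validate a complete study bundle.

    The YAML config supplies the fraction scheme (``cut_points``,
    ``discard_above``), paths (relative to the config file) to the
    background and toxicity tables, the ``lod_rule``, per-analyte
    ``lod`` detection limits, and optional ``exposure`` overrides.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}

    scheme = FractionScheme(
        cut_points=tuple(cfg.get("cut_points", (800, 500, 250, 125, 45))),
        discard_above=cfg.get("discard_above"))
    rule: LodRule = cfg.get("lod_rule", "half")
    if rule not in ("zero", "half", "full"):
        raise ValidationError(f"unknown LOD rule {rule!r}")

    descriptors: dict[str, AnalyteDescriptor] = {}
    for name in cfg.get("analytes", []):
        descriptors[name] = default_descriptor(name)

    sites = read_sites(sites_path, scheme)

    conc_df = pd.read_csv(concentrations_path, float_precision="round_trip")
    missing = {"site_id", "fraction_label", "analyte", "value", "unit"} - set(conc_df.columns)
    if missing:
        raise ValidationError(f"concentration table is missing columns {sorted(missing)}")
    lod_map = {str(k): float(v) for k, v in (cfg.get("lod") or {}).items()}
    for a in conc_df["analyte"].unique():
        descriptors.setdefault(str(a), default_descriptor(
            str(a), conc_df.loc[conc_df["analyte"] == a, "unit"].iloc[0]))
    table = _normalise_long(conc_df, descriptors, lod_map, rule)

    # cross-reference validation
    known_sites = {s.site_id for s in sites}
    for site_id, label in table.pairs:
        if site_id not in known_sites:
            raise ValidationError(f"concentration table references unknown site {site_id!r}")
        scheme.validate_label(label)

    base = config_path.parent
    background = read_background(base / cfg["background_path"], descriptors)
    toxicity = ToxicityReference.from_frame(pd.read_csv(base / cfg["toxicity_path"]))

    exposure = DEFAULT_EXPOSURE
    if cfg.get("exposure"):
        exposure = exposure.with_overrides(cfg["exposure"])
    if cfg.get("at_carc_days"):
        exposure = dataclasses.replace(exposure, at_carc_days=float(cfg["at_carc_days"]))

    return StudyBundle(scheme=scheme, sites=sites, concentrations=table,
                       background=background, exposure=exposure, toxicity=toxicity,
                       descriptors=descriptors, lod_rule=rule)


def write_study(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to the delimited schemas ``load_study`` reads.

    Returns the mapping of artifact name → path.  Concentrations are
    written on element basis (unit mg_per_kg) so a round trip is
    bit-preserving without re-applying oxide conversion.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    long_rows = []
    tab = bundle.concentrations
    for (site, frac) in tab.pairs:
        for a in tab.analytes:
            v = tab.values.loc[(site, frac), a]
            if pd.isna(v):
                continue
            long_rows.append({
                "site_id": site, "fraction_label": frac, "analyte": a,
                "value": repr(float(v)), "unit": "mg_per_kg",
                "below_lod": bool(tab.below_lod.loc[(site, frac), a])})
    paths["concentrations"] = out / "concentrations.csv"
    pd.DataFrame(long_rows).to_csv(paths["concentrations"], index=False)

    site_rows = []
    oversize = bundle.scheme.oversize_label
    for s in bundle.sites:
        row = {"site_id": s.site_id, "land_use": s.land_use,
               "area_swept_m2": s.area_swept_m2, "total_mass_g": s.total_mass_g}
        for label in bundle.scheme.labels:
            row[label] = s.fraction_masses.get(label, 0.0)
        row["gt_800" if oversize == ">800" else oversize] = s.fraction_masses.get(oversize, 0.0)
        site_rows.append(row)
    paths["sites"] = out / "sites.csv"
    pd.DataFrame(site_rows).to_csv(paths["sites"], index=False)

    paths["background"] = out / "background.csv"
    pd.DataFrame({
        "analyte": bundle.background.values.index,
        "value": [repr(float(v)) for v in bundle.background.values],
        "unit": "mg_per_kg"}).to_csv(paths["background"], index=False)

    paths["toxicity"] = out / "toxicity.csv"
    bundle.toxicity.to_frame().to_csv(paths["toxicity"], index=False)

    cfg = {
        "cut_points": [float(p) for p in bundle.scheme.cut_points],
        "discard_above": float(bundle.scheme.discard_above),
        "lod_rule": bundle.lod_rule,
        "background_path": "background.csv",
        "toxicity_path": "toxicity.csv",
        "lod": {a: float(v) for a, v in bundle.concentrations.lod.dropna().items()},
    }
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False, allow_unicode=True)
    return paths
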