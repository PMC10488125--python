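"""Mass-based size-distribution descriptors and the mineral-mass fit.

Each site yields a dust mass per swept area (g m⁻²), a per-bin mass
percentage vector (the oversize bin is kept in the denominator so
percentages match how sieving campaigns report them, with a flag to
drop it), a cumulative mass curve over ascending particle size, and an
*inhalable share* — the mass percent finer than 125 µm, the size below
which particles resuspend and enter the nose and mouth.  Land-use
classes are summarised by unweighted means across their sites.

Mineral phase masses grow linearly with fraction mass; the fit is an
ordinary least-squares line on linear axes (log-log display only bends
the same line into a curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fractions import FractionScheme, ValidationError
from .study import SiteRecord

PERCENT_TOL = 1e-6


def yield_per_area(s: SiteRecord) -> float:
    """Collected dust mass per swept area, g m⁻²."""
    if s.area_swept_m2 <= 0:
        raise ValidationError(f"site {s.site_id}: swept area must be positive")
    return s.total_mass_g / s.area_swept_m2


def fraction_mass_percents(s: SiteRecord, scheme: FractionScheme,
                           include_oversize: bool = True) -> pd.Series:
    """Mass percent per bin, ascending size order.

    With ``include_oversize`` (default) the discarded coarse bin stays
    in the denominator; otherwise percentages renormalise over the
    analysed bins only.
    """
    labels = list(scheme.labels) + ([scheme.oversize_label] if include_oversize else [])
    masses = np.array([s.fraction_masses.get(lb, 0.0) for lb in labels], dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValidationError(
            f"site {s.site_id}: all fraction masses are zero, distribution undefined")
    return pd.Series(100.0 * masses / total, index=labels, name=s.site_id)


def cumulative_distribution(percents: pd.Series, scheme: FractionScheme) -> pd.Series:
    """Cumulative mass percent versus upper bin edge, ascending in size.

    ``percents`` must cover the scheme's analysed bins (oversize
    optional) and sum to 100 within tolerance.  The returned series is
    indexed by upper edge in µm and is non-decreasing, ending at 100.
    """
    if abs(percents.sum() - 100.0) > 1e-6:
        raise ValidationError(f"percents sum to {percents.sum():.8f}, expected 100")
    labels = list(scheme.labels)
    edges = list(scheme.upper_edges)
    vals = [float(percents.get(lb, 0.0)) for lb in labels]
    if scheme.oversize_label in percents.index:
        vals.append(float(percents[scheme.oversize_label]))
        edges.append(np.inf)
    return pd.Series(np.cumsum(vals), index=pd.Index(edges, name="upper_edge_um"))


@dataclass(frozen=True)
class SizeDistributionSummary:
    """Per-site descriptors derived from the sieve masses."""

    site_id: str
    land_use: str
    yield_g_per_m2: float
    percents: pd.Series            # per bin incl. oversize, ascending
    cumulative: pd.Series          # vs upper edge, µm
    inhalable_share_pct: float     # mass % finer than the inhalable cut


def inhalable_share(percents: pd.Series, scheme: FractionScheme,
                    threshold_um: float = 125.0) -> float:
    """Mass percent in bins wholly below ``threshold_um``.

    At the default 125 µm this is the sum of the two finest bins; the
    stricter 100 µm variant keeps only bins whose upper edge is ≤ 100
    (the finest sieve bin for the standard scheme).
    """
    share = 0.0
    for (lo, hi), label in zip(scheme.bounds, scheme.labels):
        if hi <= threshold_um:
            share += float(percents.get(label, 0.0))
    return share


def summarize_site(s: SiteRecord, scheme: FractionScheme,
                   inhalable_threshold_um: float = 125.0,
                   include_oversize: bool = True) -> SizeDistributionSummary:
    pct = fraction_mass_percents(s, scheme, include_oversize=include_oversize)
    return SizeDistributionSummary(
        site_id=s.site_id, land_use=s.land_use,
        yield_g_per_m2=yield_per_area(s),
        percents=pct,
        cumulative=cumulative_distribution(pct, scheme),
        inhalable_share_pct=inhalable_share(pct, scheme, inhalable_threshold_um))


def aggregate_by_land_use(summaries: Sequence[SizeDistributionSummary],
                          ) -> pd.DataFrame:
    """Unweighted per-class means of fraction percents and inhalable share.

    Returns a frame indexed by land-use class with one column per bin
    plus ``inhalable_share_pct`` and ``n_sites``.  Classes with no
    sites are simply absent.
    """
    if not summaries:
        return pd.DataFrame()
    rows = []
    for s in summaries:
        row = s.percents.to_dict()
        row["inhalable_share_pct"] = s.inhalable_share_pct
        row["land_use"] = s.land_use
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = df.groupby("land_use").mean()
    agg["n_sites"] = df.groupby("land_use").size()
    return agg


@dataclass(frozen=True)
class MineralMassTable:
    """Per-(site, fraction) mineral phase percents and fraction mass.

    ``phases`` is a wide frame (percent by phase) indexed by
    (site_id, fraction_label); ``fraction_mass_g`` aligns with it.
    """

    phases: pd.DataFrame
    fraction_mass_g: pd.Series

    def __post_init__(self) -> None:
        if (self.phases.to_numpy() < 0).any():
            raise ValidationError("mineral phase percents must be >= 0")
        sums = self.phases.sum(axis=1)
        if (sums > 100.0 + 1e-9).any():
            bad = sums[sums > 100.0 + 1e-9].index[0]
            raise ValidationError(f"phase percents at {bad} sum above 100")

    def phase_mass_g(self, phase: str) -> pd.Series:
        return self.phases[phase] / 100.0 * self.fraction_mass_g


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def mineral_mass_regression(table: MineralMassTable, phase: str) -> RegressionFit:
    """OLS fit of mineral mass (g) against fraction total mass (g).

    Fitting is on linear axes; a log-log rendering of the same line is
    purely presentational.  Requires ≥ 3 points with positive totals
    and non-degenerate mass variance.
    """
    if phase not in table.phases.columns:
        raise ValidationError(f"unknown mineral phase {phase!r}")
    x = table.fraction_mass_g.to_numpy(dtype=float)
    y = table.phase_mass_g(phase).to_numpy(dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("mineral regression needs at least 3 points with positive mass")
    if np.ptp(x) == 0:
        raise ValidationError("mineral regression undefined: fraction masses are all equal")
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2), n=int(x.size))
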