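"""Sieve fraction schemes for size-fractionated dust studies.

A study sieves bulk road dust through a stack of decreasing apertures,
producing labelled size bins.  Bins are half-open intervals ``[lower,
upper)`` in micrometres; the finest bin is ``[0, smallest aperture)``.
Material above ``discard_above`` (leaf litter, asphalt chips, debris) is
weighed but excluded from chemical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when a study input violates its schema or an invariant."""


@dataclass(frozen=True)
class FractionScheme:
    """Ordered sieve cut points defining labelled size bins.

    Parameters
    ----------
    cut_points
        Sieve apertures in µm, strictly decreasing (e.g. ``(800, 500,
        250, 125, 45)``).
    discard_above
        Aperture in µm above which material is excluded from analysis.
        Defaults to the largest cut point.
    """

    cut_points: tuple[float, ...] = (800.0, 500.0, 250.0, 125.0, 45.0)
    discard_above: float | None = None

    def __post_init__(self) -> None:
        pts = tuple(float(p) for p in self.cut_points)
        if not pts:
            raise ValidationError("FractionScheme needs at least one cut point")
        if any(p <= 0 for p in pts):
            raise ValidationError(f"cut points must be positive, got {pts}")
        if any(a <= b for a, b in zip(pts, pts[1:])):
            raise ValidationError(f"cut points must be strictly decreasing, got {pts}")
        object.__setattr__(self, "cut_points", pts)
        if self.discard_above is None:
            object.__setattr__(self, "discard_above", pts[0])

    @staticmethod
    def _fmt(x: float) -> str:
        return f"{x:g}"

    @property
    def labels(self) -> tuple[str, ...]:
        """Bin labels in ascending size order, finest first.

        For cut points (800, 500, 250, 125, 45) these are
        ``("<45", "45-125", "125-250", "250-500", "500-800")``.
        """
        asc = sorted(self.cut_points)
        out = [f"<{self._fmt(asc[0])}"]
        out += [f"{self._fmt(lo)}-{self._fmt(hi)}" for lo, hi in zip(asc, asc[1:])]
        return tuple(out)

    @property
    def oversize_label(self) -> str:
        """Label of the discarded bin above the coarsest aperture."""
        return f">{self._fmt(max(self.cut_points))}"

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        """Half-open [lower, upper) bounds in µm, ascending, finest first."""
        asc = sorted(self.cut_points)
        return tuple(zip([0.0] + asc[:-1], asc))

    @property
    def upper_edges(self) -> tuple[float, ...]:
        """Upper bin edges in µm, ascending (x-axis of cumulative curves)."""
        return tuple(sorted(self.cut_points))

    def validate_label(self, label: str) -> str:
        if label not in self.labels and label != self.oversize_label:
            raise ValidationError(
                f"unknown fraction label {label!r}; scheme defines "
                f"{list(self.labels) + [self.oversize_label]}"
            )
        return label


DEFAULT_SCHEME = FractionScheme()
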