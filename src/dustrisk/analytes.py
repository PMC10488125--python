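"""Analyte descriptors and oxide ↔ element unit conventions.

Geochemical labs report major elements as oxide weight percent (ICP-OES
fusion analyses) and trace elements in mg kg⁻¹.  Pollution indices and
exposure doses need a single basis, so every concentration is normalised
internally to mg kg⁻¹ of the *element*.  Conversion factors are the mass
fraction of the element in its stoichiometric oxide, computed from IUPAC
standard atomic weights (2021 abridged values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .fractions import ValidationError

# IUPAC 2021 standard atomic weights (abridged), g mol⁻¹.
ATOMIC_MASS: dict[str, float] = {
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "K": 39.098,
    "Ca": 40.078,
    "Ti": 47.867,
    "Mn": 54.938,
    "Fe": 55.845,
}

# oxide formula -> (element, n_element, n_oxygen)
OXIDE_STOICHIOMETRY: dict[str, tuple[str, int, int]] = {
    "SiO2": ("Si", 1, 2),
    "Al2O3": ("Al", 2, 3),
    "Fe2O3": ("Fe", 2, 3),
    "MnO": ("Mn", 1, 1),
    "MgO": ("Mg", 1, 1),
    "CaO": ("Ca", 1, 1),
    "Na2O": ("Na", 2, 1),
    "K2O": ("K", 2, 1),
    "TiO2": ("Ti", 1, 2),
    "P2O5": ("P", 2, 5),
}


def oxide_to_element_factor(oxide: str) -> float:
    """Mass fraction of the element in the oxide formula unit.

    e.g. ``oxide_to_element_factor("CaO")`` → 40.078 / 56.077 ≈ 0.7147.
    """
    try:
        el, n_el, n_o = OXIDE_STOICHIOMETRY[oxide]
    except KeyError:
        raise ValidationError(f"no stoichiometry registered for oxide {oxide!r}")
    m_el = n_el * ATOMIC_MASS[el]
    return m_el / (m_el + n_o * ATOMIC_MASS["O"])


# Conservative (low-variability, geogenic) components whose summed
# concentration normalises the enrichment factor.
CONSERVATIVE_OXIDES: tuple[str, ...] = ("Al2O3", "MgO", "Na2O", "K2O", "TiO2", "P2O5")

MAJOR_OXIDES: tuple[str, ...] = tuple(OXIDE_STOICHIOMETRY)


@dataclass(frozen=True)
class AnalyteDescriptor:
    """How one analyte is reported and converted.

    ``oxide`` form requires a conversion factor in (0, 1]; ``element``
    form must not carry one.  ``is_conservative_reference`` marks
    membership in the conservative normalising sum used by the
    enrichment factor.
    """

    name: str
    form: Literal["oxide", "element"]
    unit: Literal["wt_percent", "mg_per_kg"]
    oxide_to_element: float | None = None
    is_conservative_reference: bool = False

    def __post_init__(self) -> None:
        if self.form == "oxide":
            f = self.oxide_to_element
            if f is None or not (0.0 < f <= 1.0):
                raise ValidationError(
                    f"oxide analyte {self.name!r} needs a conversion factor in (0, 1], got {f}"
                )
        elif self.form == "element":
            if self.oxide_to_element is not None:
                raise ValidationError(
                    f"element analyte {self.name!r} must not carry an oxide factor"
                )
        else:
            raise ValidationError(f"unknown analyte form {self.form!r}")


def oxide_descriptor(oxide: str, conservative: bool | None = None) -> AnalyteDescriptor:
    """Descriptor for a major oxide reported in wt%."""
    return AnalyteDescriptor(
        name=oxide,
        form="oxide",
        unit="wt_percent",
        oxide_to_element=oxide_to_element_factor(oxide),
        is_conservative_reference=(
            oxide in CONSERVATIVE_OXIDES if conservative is None else conservative
        ),
    )


def element_descriptor(name: str) -> AnalyteDescriptor:
    """Descriptor for a trace element reported in mg kg⁻¹."""
    return AnalyteDescriptor(name=name, form="element", unit="mg_per_kg")


def convert_oxide_to_element(value_wt_percent: float, descriptor: AnalyteDescriptor) -> float:
    """Convert an oxide wt% concentration to mg kg⁻¹ of the element.

    1 wt% = 10⁴ mg kg⁻¹, scaled by the element mass fraction, so
    ``result = value × 10⁴ × factor``.  Element-form descriptors are a
    contract violation, not a silent no-op.
    """
    if descriptor.form != "oxide":
        raise ValidationError(
            f"convert_oxide_to_element called on element-form analyte {descriptor.name!r}"
        )
    if value_wt_percent < 0:
        raise ValidationError(f"negative concentration {value_wt_percent} for {descriptor.name}")
    return value_wt_percent * 1.0e4 * descriptor.oxide_to_element


def to_mg_per_kg(value: float, descriptor: AnalyteDescriptor) -> float:
    """Normalise a reported concentration to mg kg⁻¹ element basis.

    Idempotent for element-basis input: an mg kg⁻¹ element value passes
    through unchanged.
    """
    if descriptor.form == "oxide":
        return convert_oxide_to_element(value, descriptor)
    if value < 0:
        raise ValidationError(f"negative concentration {value} for {descriptor.name}")
    return float(value)
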