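"""Core isotope bookkeeping: delta notation, atom-percent excess, enrichment.

The tracer signal of a dual 13C/15N pulse-labelling experiment is carried
through three transforms:

1. delta (permil vs. an international standard) <-> heavy-atom fraction,
2. atom-percent excess (APE) = labelled minus control atom fraction, x 100,
3. enrichment concentration = APE/100 x element concentration, i.e. the mass
   of newly acquired heavy isotope per gram dry tissue,

and finally multiplied by compartment biomass to give absolute amounts.
All functions accept scalars or numpy arrays and broadcast.

Units convention used throughout the package: 13C quantities are reported in
mg (mg g-1 for concentrations), 15N quantities in ug (ug g-1), matching the
magnitudes at which the two labels are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidIsotopeValueError, InvalidSampleError

__all__ = [
    "IsotopeSystem",
    "CARBON_13",
    "NITROGEN_15",
    "SYSTEMS",
    "EnrichmentRecord",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "atom_percent_excess",
    "enrichment_concentration",
    "compartment_amount",
]

# Mass of heavy isotope per g dry mass is reported in mg g-1 for 13C and
# ug g-1 for 15N; these factors convert from g g-1.
UNIT_FACTOR = {"13C": 1e3, "15N": 1e6}
UNIT_NAME = {"13C": "mg", "15N": "ug"}


@dataclass(frozen=True)
class IsotopeSystem:
    """One of the two supported tracer systems.

    Parameters
    ----------
    heavy_label
        ``"13C"`` or ``"15N"``.
    reference_ratio
        Heavy/light isotope ratio of the international standard the delta
        scale is anchored to (VPDB for carbon, atmospheric N2 for nitrogen).
    """

    heavy_label: str
    reference_ratio: float

    def __post_init__(self) -> None:
        if self.heavy_label not in ("13C", "15N"):
            raise InvalidIsotopeValueError(
                f"unsupported isotope system {self.heavy_label!r}; "
                "expected '13C' or '15N'"
            )
        if self.reference_ratio <= 0:
            raise InvalidIsotopeValueError("reference_ratio must be positive")

    @property
    def unit_factor(self) -> float:
        return UNIT_FACTOR[self.heavy_label]

    @property
    def unit(self) -> str:
        return UNIT_NAME[self.heavy_label]


#: Canonical VPDB 13C/12C ratio.
CARBON_13 = IsotopeSystem("13C", 0.0111802)
#: Canonical atmospheric-N2 (AIR) 15N/14N ratio.
NITROGEN_15 = IsotopeSystem("15N", 0.0036765)

SYSTEMS = {"13C": CARBON_13, "15N": NITROGEN_15}


@dataclass(frozen=True)
class EnrichmentRecord:
    """Derived tracer quantities for one sample.

    ``ape`` is atom-percent excess (%), ``enrichment_conc`` the mass of newly
    acquired heavy isotope per g dry mass (mg g-1 for 13C, ug g-1 for 15N)
    and ``element_conc`` the total element concentration in mg g-1.
    """

    ape: float
    enrichment_conc: float
    element_conc: float
    unit: str = "mg/g"


def delta_to_atom_fraction(delta_permil, system: IsotopeSystem):
    """Convert delta notation (permil vs. standard) to heavy-atom fraction.

    The sample ratio is R = R_std * (delta/1000 + 1) and the heavy-atom
    fraction is R / (1 + R). Strictly increasing in delta.
    """
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta <= -1000.0):
        raise InvalidIsotopeValueError(
            "delta values must exceed -1000 permil (ratio would be <= 0)"
        )
    ratio = system.reference_ratio * (delta / 1000.0 + 1.0)
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def atom_fraction_to_delta(atom_fraction, system: IsotopeSystem):
    """Inverse of :func:`delta_to_atom_fraction`."""
    af = np.asarray(atom_fraction, dtype=float)
    if np.any((af < 0.0) | (af >= 1.0)):
        raise InvalidIsotopeValueError("atom fraction must lie in [0, 1)")
    ratio = af / (1.0 - af)
    out = (ratio / system.reference_ratio - 1.0) * 1000.0
    return out if out.ndim else float(out)


def atom_percent_excess(af_labelled, af_control):
    """Atom-percent excess: (labelled - control atom fraction) x 100.

    May be negative for samples that by chance read below the control mean;
    negative values are retained (clipping would bias means) and should be
    flagged downstream, not silently zeroed.
    """
    lab = np.asarray(af_labelled, dtype=float)
    ctl = np.asarray(af_control, dtype=float)
    for name, arr in (("af_labelled", lab), ("af_control", ctl)):
        if np.any((arr < 0.0) | (arr > 1.0)):
            raise InvalidIsotopeValueError(f"{name} must lie in [0, 1]")
    out = (lab - ctl) * 100.0
    return out if out.ndim else float(out)


def enrichment_concentration(ape, element_mass, dry_mass, unit_factor: float = 1e3):
    """Mass of newly acquired heavy isotope per g dry mass.

    enrichment = APE/100 x unit_factor x element_mass / dry_mass

    With the default ``unit_factor`` of 1000 the result is in mg per g dry
    mass (the 13C convention); pass ``1e6`` for ug per g (15N convention).
    ``element_mass`` is the total element (light + heavy) in the sample, in
    the same mass unit as ``dry_mass``.
    """
    ape_a = np.asarray(ape, dtype=float)
    em = np.asarray(element_mass, dtype=float)
    dm = np.asarray(dry_mass, dtype=float)
    if np.any(dm <= 0):
        raise InvalidSampleError("dry_mass must be positive")
    if np.any((em < 0) | (em > dm)):
        raise InvalidSampleError("element_mass must lie in [0, dry_mass]")
    out = ape_a / 100.0 * unit_factor * em / dm
    return out if out.ndim else float(out)


def compartment_amount(enrichment_conc, biomass):
    """Absolute amount of newly acquired heavy isotope in a compartment.

    amount = enrichment concentration x compartment dry biomass (g). The
    amount of a multi-compartment pool is the sum of its compartments.
    """
    bm = np.asarray(biomass, dtype=float)
    if np.any(bm < 0):
        raise InvalidSampleError("biomass must be non-negative")
    out = np.asarray(enrichment_conc, dtype=float) * bm
    return out if out.ndim else float(out)
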