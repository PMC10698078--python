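"""Per-plant heavy-isotope pool accounting.

The ectomycorrhizal (EM) pool of a plant is the sum over fungal species of
(enrichment concentration x dry biomass per root tip x number of tips), with
the tip number of a species given by its relative abundance times the total
EM tip count of the plant. Root pools add fine- and coarse-root terms; the
rhizosphere pool multiplies soil enrichment by adhering-soil dry mass.
Shares and 13C/15N transfer ratios are derived from those amounts.

Tip counts are kept real-valued internally (abundance x total tips); rounding
is applied only in reports, since rounding at small abundances would inject
bias into the summed pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InconsistentCommunityError,
    InvalidSampleError,
    UndefinedRatioError,
    UndefinedShareError,
)

__all__ = [
    "SpeciesPoolEntry",
    "PoolAmounts",
    "em_pool_amount",
    "root_pool_amount",
    "rhizosphere_amount",
    "pool_share",
    "transfer_ratio",
]


@dataclass(frozen=True)
class SpeciesPoolEntry:
    """One fungal species' contribution to a plant's EM tracer pool.

    ``enrichment_conc`` is heavy-isotope mass per g dry tip mass (mg g-1 for
    13C, ug g-1 for 15N), ``tip_biomass`` the dry mass of a single EM root
    tip in g, ``relative_abundance`` the species' share of vital mycorrhizal
    tips on this plant.
    """

    species: str
    enrichment_conc: float
    tip_biomass: float
    relative_abundance: float

    def __post_init__(self) -> None:
        if self.tip_biomass < 0:
            raise InvalidSampleError("tip_biomass must be >= 0")
        if not 0 <= self.relative_abundance <= 1:
            raise InconsistentCommunityError(
                "relative_abundance must lie in [0, 1]"
            )

    def n_tips(self, total_tips: float) -> float:
        return self.relative_abundance * total_tips


@dataclass(frozen=True)
class PoolAmounts:
    """Per-compartment tracer amounts for one plant (mg for 13C, ug for 15N)."""

    em_pool: float
    fine_root: float
    coarse_root: float
    rhizosphere: float
    unit: str

    @property
    def total_root(self) -> float:
        return self.fine_root + self.coarse_root


def em_pool_amount(entries: Sequence[SpeciesPoolEntry], total_tips: float) -> float:
    """Ectomycorrhizal tracer amount per plant.

    sum_i enrichment_i x tip_biomass_i x (relative_abundance_i x total_tips)
    """
    if total_tips <= 0:
        raise InvalidSampleError("total_tips must be positive")
    abundance_sum = sum(e.relative_abundance for e in entries)
    if abundance_sum > 1 + 1e-6:
        raise InconsistentCommunityError(
            f"relative abundances sum to {abundance_sum:.6f} > 1"
        )
    return float(
        sum(
            e.enrichment_conc * e.tip_biomass * e.n_tips(total_tips)
            for e in entries
        )
    )


def root_pool_amount(
    fine_enr: float, fine_biomass: float, coarse_enr: float, coarse_biomass: float
) -> float:
    """Tracer amount in roots: fine-root plus coarse-root term."""
    if fine_biomass < 0 or coarse_biomass < 0:
        raise InvalidSampleError("biomass must be >= 0")
    return fine_enr * fine_biomass + coarse_enr * coarse_biomass


def rhizosphere_amount(enrichment_conc_soil: float, soil_dry_mass: float) -> float:
    """Tracer amount in the rhizosphere soil adhering to fine roots."""
    if soil_dry_mass < 0:
        raise InvalidSampleError("soil_dry_mass must be >= 0")
    return enrichment_conc_soil * soil_dry_mass


def pool_share(part: float, whole: float) -> float:
    """Percentage share of one pool in another (100 x part / whole)."""
    if whole <= 0:
        raise UndefinedShareError("whole pool must be positive")
    if part < 0:
        raise InvalidSampleError("part must be >= 0")
    return 100.0 * part / whole


def transfer_ratio(amount_13c_mg: float, amount_15n_ug: float) -> float:
    """Unitless 13C/15N mass ratio of a pool.

    Inputs follow the package convention (13C in mg, 15N in ug); both are
    converted to ug before dividing.
    """
    if amount_15n_ug <= 0:
        raise UndefinedRatioError("15N amount must be positive")
    return float(amount_13c_mg * 1000.0 / amount_15n_ug)


def coarse_to_fine_ratio(total_root: float, fine_root: float) -> float:
    """Coarse-root over fine-root pool, computed as (total - fine)/fine.

    The coarse-root pool is taken as the remainder of the total root pool
    after the fine-root term, and is labelled so in reports.
    """
    if fine_root <= 0:
        raise UndefinedShareError("fine-root pool must be positive")
    return (total_root - fine_root) / fine_root
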