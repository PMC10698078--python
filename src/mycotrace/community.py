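"""Root-tip census indices and community-composition statistics.

A root-tip census classifies ~400 tips per plant as vital mycorrhizal, vital
non-mycorrhizal or dry; vital mycorrhizal tips are further assigned to fungal
morphotypes/species. From these counts the module derives colonization and
vitality rates, per-plant relative abundances, and compares community
composition between groups of plants with ANOSIM on Bray-Curtis
dissimilarities (midranks for ties, seeded label permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    DegenerateGroupError,
    InconsistentAreasError,
    InconsistentCensusError,
    UndefinedRateError,
    UndefinedSimilarityError,
)

__all__ = [
    "RootTipCensus",
    "MorphotypeTable",
    "CommunityMatrix",
    "CrossSectionAreas",
    "AnosimResult",
    "colonization_rate",
    "vitality_rate",
    "relative_abundance",
    "fungal_tissue_fraction",
    "bray_curtis_similarity",
    "bray_curtis_dissimilarity_matrix",
    "anosim",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class RootTipCensus:
    plant_id: str
    time_point: int
    n_vital_myco: int
    n_vital_nonmyco: int
    n_dry: int

    def __post_init__(self) -> None:
        for name in ("n_vital_myco", "n_vital_nonmyco", "n_dry"):
            if getattr(self, name) < 0:
                raise InconsistentCensusError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_vital_myco + self.n_vital_nonmyco + self.n_dry


@dataclass(frozen=True)
class MorphotypeTable:
    plant_id: str
    time_point: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise InconsistentCensusError("morphotype counts must be >= 0")


@dataclass(frozen=True)
class CrossSectionAreas:
    species: str
    area_fungal: float
    area_total: float

    def __post_init__(self) -> None:
        if self.area_total <= 0:
            raise InconsistentAreasError("area_total must be positive")
        if not 0 <= self.area_fungal <= self.area_total:
            raise InconsistentAreasError(
                "area_fungal must lie in [0, area_total]"
            )


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class CommunityMatrix:
    """Plants x species relative abundances.

    Rows are plants, columns named fungal species; an explicit
    ``unclassified`` column holds vital mycorrhizal tips that were not
    assigned a morphotype. Rows sum to <= 1 (+1e-9).
    """

    abundances: pd.DataFrame
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        vals = self.abundances.to_numpy(dtype=float)
        if (vals < 0).any():
            raise InconsistentCensusError("abundances must be non-negative")
        if (vals.sum(axis=1) > 1 + 1e-9).any():
            raise InconsistentCensusError("abundance rows must sum to <= 1")

    @property
    def species(self) -> list[str]:
        return [c for c in self.abundances.columns if c != UNCLASSIFIED]

    def classified(self) -> pd.DataFrame:
        """Abundance block without the unclassified remainder (ANOSIM input)."""
        return self.abundances[self.species]


def colonization_rate(census: RootTipCensus) -> float:
    """Mycorrhizal colonization rate (%).

    100 x vital mycorrhizal / (vital mycorrhizal + vital non-mycorrhizal);
    dry tips are excluded from the denominator.
    """
    vital = census.n_vital_myco + census.n_vital_nonmyco
    if vital == 0:
        raise UndefinedRateError(
            f"plant {census.plant_id}: no vital tips, colonization undefined"
        )
    return 100.0 * census.n_vital_myco / vital


def vitality_rate(census: RootTipCensus) -> float:
    """Root-tip vitality (%): vital tips over all counted tips."""
    if census.total == 0:
        raise UndefinedRateError(
            f"plant {census.plant_id}: no counted tips, vitality undefined"
        )
    return 100.0 * (census.n_vital_myco + census.n_vital_nonmyco) / census.total


def relative_abundance(
    table: MorphotypeTable, census: RootTipCensus
) -> dict[str, float]:
    """Per-species share of vital mycorrhizal tips for one plant.

    Species shares sum to <= 1; the remainder is returned under the key
    ``"unclassified"``.
    """
    if census.n_vital_myco <= 0:
        raise UndefinedRateError(
            f"plant {census.plant_id}: no vital mycorrhizal tips"
        )
    total_assigned = sum(table.counts.values())
    if total_assigned > census.n_vital_myco:
        raise InconsistentCensusError(
            f"plant {census.plant_id}: {total_assigned} morphotyped tips exceed "
            f"{census.n_vital_myco} vital mycorrhizal tips"
        )
    out = {sp: c / census.n_vital_myco for sp, c in table.counts.items()}
    out[UNCLASSIFIED] = 1.0 - total_assigned / census.n_vital_myco
    return out


def fungal_tissue_fraction(areas: CrossSectionAreas) -> float:
    """Percentage of an ectomycorrhiza cross section occupied by fungal tissue."""
    return 100.0 * areas.area_fungal / areas.area_total


def bray_curtis_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray-Curtis similarity 1 - sum|a_i - b_i| / sum(a_i + b_i).

    Symmetric, 1 for identical rows, 0 for disjoint supports. Undefined
    (raises) when both rows are all zero.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("abundance rows must have equal length")
    if (av < 0).any() or (bv < 0).any():
        raise InconsistentCensusError("abundances must be non-negative")
    denom = float((av + bv).sum())
    if denom == 0.0:
        raise UndefinedSimilarityError("both abundance rows are all zero")
    return 1.0 - float(np.abs(av - bv).sum()) / denom


def bray_curtis_dissimilarity_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Bray-Curtis similarity for a plants x species array."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - bray_curtis_similarity(rows[i], rows[j])
    return d


def _anosim_r(dism: np.ndarray, labels: np.ndarray) -> float:
    n = dism.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dism[iu])  # midranks for ties
    within = labels[iu[0]] == labels[iu[1]]
    m = n * (n - 1) / 2
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(
    matrix: CommunityMatrix,
    groups: Sequence,
    n_permutations: int = 9999,
    seed: int = 0,
    use_relative_abundance: bool = True,
) -> AnosimResult:
    """Analysis of similarities between groups of plants.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise Bray-Curtis dissimilarities ranked with midranks.
    The p-value is (1 + #{permuted R >= observed}) / (n_permutations + 1)
    under random reassignment of group labels with the given seed.

    ``use_relative_abundance=False`` rescales each classified row to sum to 1
    (the equivalent of running on raw counts renormalized over classified
    tips); the default analyses the relative abundances as stored.
    """
    labels = np.asarray(list(groups))
    data = matrix.classified().to_numpy(dtype=float)
    if labels.shape[0] != data.shape[0]:
        raise DegenerateGroupError("one group label required per plant")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise DegenerateGroupError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise DegenerateGroupError("every group needs at least two plants")
    if not use_relative_abundance:
        sums = data.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise UndefinedSimilarityError("a plant has no classified tips")
        data = data / sums

    dism = bray_curtis_dissimilarity_matrix(data)
    observed = _anosim_r(dism, labels)

    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _anosim_r(dism, perm) >= observed:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return AnosimResult(observed, p, n_permutations, seed)
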