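"""Census indices, Bray-Curtis and ANOSIM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mycotrace import (
    CommunityMatrix,
    CrossSectionAreas,
    MorphotypeTable,
    RootTipCensus,
    anosim,
    bray_curtis_similarity,
    colonization_rate,
    fungal_tissue_fraction,
    relative_abundance,
    vitality_rate,
)
from mycotrace.community import _anosim_r, bray_curtis_dissimilarity_matrix
from mycotrace.errors import (
    DegenerateGroupError,
    InconsistentAreasError,
    InconsistentCensusError,
    UndefinedRateError,
    UndefinedSimilarityError,
)


class TestCensusRates:
    @pytest.mark.parametrize(
        "myco, nonmyco, dry, expected",
        [
            (90, 10, 25, 90.0),
            (0, 50, 0, 0.0),
            (372, 28, 40, 93.0),  # 372*100/400
        ],
    )
    def test_colonization(self, myco, nonmyco, dry, expected):
        c = RootTipCensus("p", 5, myco, nonmyco, dry)
        assert colonization_rate(c) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "myco, nonmyco, dry, expected",
        [
            (100, 20, 0, 100.0),
            (0, 0, 30, 0.0),
            (372, 28, 46, 400 * 100 / 446),  # near the field mean of ~89.6%
            (372, 28, 40, 400 * 100 / 440),
        ],
    )
    def test_vitality(self, myco, nonmyco, dry, expected):
        c = RootTipCensus("p", 5, myco, nonmyco, dry)
        assert vitality_rate(c) == pytest.approx(expected)

    def test_vitality_zero_total_and_colonization_zero_vital(self):
        with pytest.raises(UndefinedRateError):
            vitality_rate(RootTipCensus("p", 5, 0, 0, 0))
        with pytest.raises(UndefinedRateError):
            colonization_rate(RootTipCensus("p", 5, 0, 0, 10))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.integers(min_value=1, max_value=500),
        hst.integers(min_value=0, max_value=500),
        hst.integers(min_value=0, max_value=500),
        hst.integers(min_value=2, max_value=9),
    )
    def test_rates_scale_invariant(self, m, nm, d, k):
        c1 = RootTipCensus("p", 5, m, nm, d)
        ck = RootTipCensus("p", 5, k * m, k * nm, k * d)
        assert colonization_rate(ck) == pytest.approx(colonization_rate(c1))
        assert vitality_rate(ck) == pytest.approx(vitality_rate(c1))


class TestRelativeAbundance:
    def test_single_species_full_cover(self):
        t = MorphotypeTable("p", 5, {"A": 100})
        c = RootTipCensus("p", 5, 100, 10, 5)
        ra = relative_abundance(t, c)
        assert ra["A"] == 1.0 and ra["unclassified"] == 0.0

    def test_proportions(self):
        ra = relative_abundance(
            MorphotypeTable("p", 5, {"A": 30, "B": 70}),
            RootTipCensus("p", 5, 100, 0, 0),
        )
        assert ra == {"A": 0.3, "B": 0.7, "unclassified": 0.0}

    def test_unclassified_remainder(self):
        ra = relative_abundance(
            MorphotypeTable("p", 5, {"A": 29, "B": 13, "C": 8}),
            RootTipCensus("p", 5, 100, 0, 0),
        )
        assert ra["A"] == pytest.approx(0.29)
        assert ra["B"] == pytest.approx(0.13)
        assert ra["C"] == pytest.approx(0.08)
        assert ra["unclassified"] == pytest.approx(0.50)

    def test_overcount_rejected(self):
        with pytest.raises(InconsistentCensusError):
            relative_abundance(
                MorphotypeTable("p", 5, {"A": 120}),
                RootTipCensus("p", 5, 100, 0, 0),
            )


class TestFungalTissue:
    @pytest.mark.parametrize(
        "fungal, total, expected", [(1000, 1000, 100.0), (500, 1000, 50.0), (253, 1000, 25.3)]
    )
    def test_fraction(self, fungal, total, expected):
        assert fungal_tissue_fraction(
            CrossSectionAreas("sp", fungal, total)
        ) == pytest.approx(expected)

    def test_inconsistent_areas(self):
        with pytest.raises(InconsistentAreasError):
            CrossSectionAreas("sp", 1100, 1000)


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        assert bray_curtis_similarity([0.2, 0.8], [0.2, 0.8]) == pytest.approx(1.0)
        assert bray_curtis_similarity([1, 0, 0], [0, 0.4, 0.6]) == pytest.approx(0.0)
        # 1 - (0.25+0.25+0.5)/2
        assert bray_curtis_similarity(
            [0.5, 0.5, 0.0], [0.25, 0.25, 0.5]
        ) == pytest.approx(0.5)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            bray_curtis_similarity([0, 0], [0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hst.lists(hst.floats(min_value=0, max_value=1), min_size=3, max_size=6),
        hst.lists(hst.floats(min_value=0, max_value=1), min_size=3, max_size=6),
    )
    def test_symmetry_and_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if sum(a) + sum(b) == 0:
            return
        s = bray_curtis_similarity(a, b)
        assert s == pytest.approx(bray_curtis_similarity(b, a))
        assert -1e-12 <= s <= 1 + 1e-12

    def test_matches_scipy_reference(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.random(5), rng.random(5)
            assert bray_curtis_similarity(a, b) == pytest.approx(
                1.0 - braycurtis(a, b), rel=1e-12
            )


def _matrix(rows, groups=None):
    df = pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(rows[0]))])
    df = df.div(df.sum(axis=1).clip(lower=1), axis=0).clip(upper=1.0)
    return CommunityMatrix(df, groups=groups)


class TestAnosim:
    def test_disjoint_groups_give_r_one(self):
        rows = [[5, 3, 0, 0], [4, 4, 0, 0], [6, 2, 0, 0],
                [0, 0, 5, 3], [0, 0, 2, 6], [0, 0, 4, 4]]
        m = _matrix(np.array(rows, dtype=float) / 10.0)
        res = anosim(m, ["a", "a", "a", "b", "b", "b"], n_permutations=99, seed=0)
        assert res.r_statistic == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_null_case_r_near_zero(self):
        rng = np.random.default_rng(12)
        rows = rng.dirichlet(np.ones(5), size=12)
        m = _matrix(rows)
        res = anosim(m, ["a", "b"] * 6, n_permutations=999, seed=5)
        assert abs(res.r_statistic) < 0.5
        assert res.p_value > 0.05

    def test_permuted_r_has_zero_mean(self):
        """Mean ANOSIM R over label permutations is ~0 (rank balance)."""
        rng = np.random.default_rng(42)
        rows = rng.dirichlet(np.ones(4), size=8)
        dism = bray_curtis_dissimilarity_matrix(rows)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        vals = []
        for _ in range(10_000):
            rng.shuffle(labels)
            vals.append(_anosim_r(dism, labels))
        assert abs(np.mean(vals)) < 0.02

    def test_sampled_p_matches_exhaustive_enumeration(self):
        """Seeded sampling agrees with full enumeration of label assignments."""
        rng = np.random.default_rng(8)
        rows = np.vstack([
            rng.dirichlet([4, 2, 1, 1], size=3),
            rng.dirichlet([1, 1, 2, 4], size=3),
        ])
        m = _matrix(rows)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        dism = bray_curtis_dissimilarity_matrix(m.classified().to_numpy())
        observed = _anosim_r(dism, labels)
        perms = [
            _anosim_r(dism, np.array(p)) >= observed - 1e-12
            for p in set(itertools.permutations(labels))
        ]
        p_exact = float(np.mean(perms))
        n_perm = 999
        res = anosim(m, labels, n_permutations=n_perm, seed=1)
        assert abs(res.p_value - p_exact) <= 2 / np.sqrt(n_perm)

    def test_degenerate_groups_rejected(self):
        rows = np.full((3, 3), 1 / 3)
        m = _matrix(rows)
        with pytest.raises(DegenerateGroupError):
            anosim(m, ["a", "a", "b"], n_permutations=9, seed=0)

    def test_matches_scikit_bio(self):
        """Independent reference: skbio's ANOSIM on the same dissimilarities."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(21)
        rows = np.vstack([
            rng.dirichlet([5, 1, 1], size=4),
            rng.dirichlet([1, 1, 5], size=4),
        ])
        m = _matrix(rows)
        labels = ["a"] * 4 + ["b"] * 4
        ours = anosim(m, labels, n_permutations=999, seed=3)
        dism = bray_curtis_dissimilarity_matrix(m.classified().to_numpy())
        ref = skbio_anosim(DistanceMatrix(dism), grouping=labels, permutations=999)
        assert ours.r_statistic == pytest.approx(ref["test statistic"], abs=1e-12)
        assert abs(ours.p_value - ref["p-value"]) <= 2 / np.sqrt(999)
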