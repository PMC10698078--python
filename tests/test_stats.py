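"""Regression, threshold, ANOVA/Tukey, Welch and correlation statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from mycotrace import (
    anova_tukey,
    compare_regression_lines,
    enrichment_above_control_test,
    fit_linear,
    pearson_correlation_test,
    test_slope_against_value as slope_vs_value,
    two_way_block_anova,
    x_intercept_threshold,
)
from mycotrace.errors import (
    DegenerateDesignError,
    DegenerateGroupError,
    ThresholdUndefinedError,
    UnbalancedDesignError,
    UndefinedCorrelationError,
)


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.residual_df == 3

    def test_constant_y(self):
        fit = fit_linear([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r == pytest.approx(0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear([2, 2, 2], [1, 2, 3])

    def test_noise_free_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(7, 30, 40)
        fit = fit_linear(x, -2.49 * x + 57.1)
        assert fit.slope == pytest.approx(-2.49, abs=1e-10)
        assert fit.intercept == pytest.approx(57.1, abs=1e-9)

    def test_parameter_recovery_13c_regression(self):
        """Mean fitted slope over 200 replicates at the 13C ~ C/N setting."""
        rng = np.random.default_rng(123)
        slopes = []
        for _ in range(200):
            x = rng.uniform(7, 30, 33)
            y = 57.1 - 2.49 * x + rng.normal(0, 5, 33)
            slopes.append(fit_linear(x, y).slope)
        assert np.mean(slopes) == pytest.approx(-2.49, abs=0.1)


class TestSlopeTest:
    def test_exact_identity_line_vs_one(self):
        x = np.arange(1.0, 7.0)
        res = slope_vs_value(x, x, 1.0)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_equal_to_fitted_slope(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 20)
        y = 1.3 * x + rng.normal(0, 1, 20)
        fitted = fit_linear(x, y).slope
        res = slope_vs_value(x, y, fitted)
        assert res.p_value == pytest.approx(1.0)

    def test_sided_p_from_t_cdf(self):
        """p equals the explicit t-CDF evaluation at (slope - ref)/se, n-2 df."""
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 40, 25)
        y = 1.23 * x + rng.normal(0, 3, 25)
        fit = fit_linear(x, y)
        t = (fit.slope - 1.0) / fit.se_slope
        res = slope_vs_value(x, y, 1.0, direction="two-sided")
        assert res.t_statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 23), rel=1e-12)
        res_g = slope_vs_value(x, y, 1.0, direction="greater")
        assert res_g.p_value == pytest.approx(sps.t.sf(t, 23), rel=1e-12)


class TestCompareRegressionLines:
    def test_identical_sets_give_zero_difference(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 8)
        y = 2 * x + rng.normal(0, 1, 8)
        res = compare_regression_lines(x, y, x, y)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_exactly_parallel_lines(self):
        x = np.arange(6.0)
        res = compare_regression_lines(x, 2 * x + 1, x, 2 * x + 5)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_interaction_ols_oracle(self):
        """Brute-force dummy-variable regression gives the same t to 1e-9."""
        import statsmodels.api as sm

        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y1 = np.array([2.1, 3.9, 6.2, 8.1, 9.8, 12.3])
        x2 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y2 = np.array([1.2, 1.9, 3.4, 3.8, 5.1, 5.6])
        res = compare_regression_lines(x1, y1, x2, y2)

        g = np.r_[np.zeros(6), np.ones(6)]
        x = np.r_[x1, x2]
        y = np.r_[y1, y2]
        design = sm.add_constant(np.column_stack([x, g, x * g]))
        ols = sm.OLS(y, design).fit()
        assert res.t_statistic == pytest.approx(-ols.tvalues[3], abs=1e-9)
        assert res.p_value == pytest.approx(ols.pvalues[3], abs=1e-9)
        assert res.df == 8


class TestThreshold:
    def test_printed_13c_fit_x_intercept(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(7, 30, 33)
        y = 57.1 - 2.49 * x  # noise-free: exact line
        thr = x_intercept_threshold(x, y, n_bootstrap=200, seed=0)
        assert thr.x_intercept == pytest.approx(57.1 / 2.49, abs=1e-9)

    def test_printed_15n_fit_x_intercept(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(7, 30, 38)
        y = 15.1 - 0.57 * x
        thr = x_intercept_threshold(x, y, n_bootstrap=200, seed=0)
        assert thr.x_intercept == pytest.approx(15.1 / 0.57, abs=1e-9)

    def test_exact_line_ci_collapses(self):
        x = np.arange(0.0, 12.0)
        thr = x_intercept_threshold(x, 10.0 - x, n_bootstrap=500, seed=3)
        assert thr.x_intercept == pytest.approx(10.0, abs=1e-9)
        assert thr.ci_low == pytest.approx(10.0, abs=1e-9)
        assert thr.ci_high == pytest.approx(10.0, abs=1e-9)

    def test_flat_line_threshold_undefined(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 30)
        y = rng.normal(5, 1, 30)  # no slope
        with pytest.raises(ThresholdUndefinedError):
            x_intercept_threshold(x, y, n_bootstrap=100, seed=0)

    def test_fieller_interval_contains_point(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(7, 30, 33)
        y = 57.1 - 2.49 * x + rng.normal(0, 5, 33)
        thr = x_intercept_threshold(x, y, seed=0, method="fieller")
        assert thr.ci_low <= thr.x_intercept <= thr.ci_high


class TestAnovaTukey:
    @staticmethod
    def groups3(seed=0):
        rng = np.random.default_rng(seed)
        return {
            "low": rng.normal(0.0, 1.0, 6),
            "mid": rng.normal(0.5, 1.0, 5),
            "high": rng.normal(5.0, 1.0, 7),
        }

    def test_null_groups_share_one_letter(self):
        rng = np.random.default_rng(11)
        groups = {g: rng.normal(10.0, 1.0, 40) for g in "abc"}
        res = anova_tukey(groups, auto_log=False)
        assert len(set(res.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self):
        res = anova_tukey(self.groups3(), auto_log=False)
        assert res.p_value < 0.01
        assert res.letters["high"] != res.letters["low"]

    def test_pairwise_matches_statsmodels_tukeyhsd(self):
        """Independent oracle: statsmodels' Tukey HSD on a balanced fixture."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(17)
        groups = {g: rng.normal(mu, 1.0, 6) for g, mu in
                  [("a", 0.0), ("b", 1.0), ("c", 3.0)]}
        res = anova_tukey(groups, auto_log=False)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [6, 6, 6])
        ref = pairwise_tukeyhsd(data, labels)
        ours = {
            tuple(sorted((r.group1, r.group2))): r.p_adj
            for r in res.pairwise.itertuples()
        }
        for row, p_ref in zip(ref.summary().data[1:], ref.pvalues):
            key = tuple(sorted((row[0], row[1])))
            assert ours[key] == pytest.approx(p_ref, abs=1e-6)

    def test_pairwise_matches_studentized_range_cdf(self):
        """Direct q-statistic evaluation reproduces each adjusted p to 1e-6."""
        groups = self.groups3(seed=23)
        res = anova_tukey(groups, auto_log=False)
        ns = {g: len(v) for g, v in groups.items()}
        means = {g: np.mean(v) for g, v in groups.items()}
        df_err = sum(ns.values()) - 3
        mse = sum(((np.asarray(v) - means[g]) ** 2).sum()
                  for g, v in groups.items()) / df_err
        for r in res.pairwise.itertuples():
            se = np.sqrt(mse / 2 * (1 / ns[r.group1] + 1 / ns[r.group2]))
            q = abs(means[r.group1] - means[r.group2]) / se
            assert r.p_adj == pytest.approx(
                sps.studentized_range.sf(q, 3, df_err), abs=1e-6
            )

    def test_letter_display_consistency(self):
        """Groups share a letter iff their adjusted p exceeds alpha."""
        for seed in range(6):
            groups = self.groups3(seed=seed)
            res = anova_tukey(groups, auto_log=False)
            for r in res.pairwise.itertuples():
                shared = set(res.letters[r.group1]) & set(res.letters[r.group2])
                if r.p_adj <= res.alpha:
                    assert not shared
                else:
                    assert shared

    def test_degenerate_group_rejected(self):
        with pytest.raises(DegenerateGroupError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_log_gate_flags_transform(self):
        rng = np.random.default_rng(3)
        groups = {g: np.exp(rng.normal(mu, 1.5, 30)) for g, mu in
                  [("a", 0.0), ("b", 2.0)]}
        res = anova_tukey(groups, auto_log=True)
        assert res.log_transformed


class TestWelch:
    def test_identical_samples_p_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert enrichment_above_control_test(x, x) == pytest.approx(0.5)

    def test_strong_shift_rejects(self):
        rng = np.random.default_rng(14)
        ctl = rng.normal(0, 1, 10)
        lab = rng.normal(10, 1, 10)
        assert enrichment_above_control_test(lab, ctl) < 1e-3

    def test_matches_hand_welch_formula(self):
        lab = np.array([3.1, 4.0, 5.2, 4.4, 6.1])
        ctl = np.array([1.0, 2.2, 1.5, 2.8, 1.9, 2.4])
        mx, my = lab.mean(), ctl.mean()
        vx, vy = lab.var(ddof=1) / lab.size, ctl.var(ddof=1) / ctl.size
        t = (mx - my) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (lab.size - 1) + vy**2 / (ctl.size - 1))
        expected = sps.t.sf(t, df)
        assert enrichment_above_control_test(lab, ctl) == pytest.approx(
            expected, rel=1e-9
        )

    def test_small_samples_rejected(self):
        with pytest.raises(DegenerateGroupError):
            enrichment_above_control_test([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_line(self):
        r, p = pearson_correlation_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation_test([1, 1, 1], [1, 2, 3])

    def test_n7_r0475_gives_p_0282(self):
        """A 7-point fixture with r = 0.475 exactly: p from t = r sqrt(5/(1-r^2))."""
        n, r_target = 7, 0.475
        x = np.arange(n, dtype=float)
        zx = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
        e = np.sin(np.arange(n))  # anything not collinear with x
        e = e - e.mean() - (e - e.mean()) @ zx * zx
        ze = e / np.sqrt((e**2).sum())
        y = r_target * zx + np.sqrt(1 - r_target**2) * ze
        r, p = pearson_correlation_test(x, y)
        assert r == pytest.approx(r_target, abs=1e-12)
        t = r_target * np.sqrt((n - 2) / (1 - r_target**2))
        assert p == pytest.approx(2 * sps.t.sf(t, n - 2), rel=1e-9)
        assert p == pytest.approx(0.282, abs=0.002)


class TestTwoWayBlockAnova:
    @staticmethod
    def balanced_fixture():
        # 3 tissues x 2 times x 2 replicates, additive effects + fixed noise
        rng = np.random.default_rng(8)
        tissues = np.repeat(["EM", "FR", "CR"], 4)
        times = np.tile(np.repeat(["d5", "d20"], 2), 3)
        effect_t = {"EM": 5.0, "FR": 2.0, "CR": 0.0}
        effect_d = {"d5": 0.0, "d20": 0.5}
        y = np.array([
            effect_t[t] + effect_d[d] + rng.normal(0, 1)
            for t, d in zip(tissues, times)
        ])
        return y, tissues, times

    def test_matches_hand_ss_decomposition(self):
        """Type-I sums of squares on a balanced design, computed by hand."""
        y, tissues, times = self.balanced_fixture()
        table = two_way_block_anova(y, tissues, times)
        grand = y.mean()
        ss_tissue = sum(
            (y[tissues == t].mean() - grand) ** 2 * (tissues == t).sum()
            for t in np.unique(tissues)
        )
        ss_time = sum(
            (y[times == d].mean() - grand) ** 2 * (times == d).sum()
            for d in np.unique(times)
        )
        assert table.loc["tissue", "sum_sq"] == pytest.approx(ss_tissue, rel=1e-9)
        assert table.loc["time", "sum_sq"] == pytest.approx(ss_time, rel=1e-9)
        ss_res = table.loc["residual", "sum_sq"]
        ms_res = ss_res / table.loc["residual", "df"]
        f_tissue = (ss_tissue / 2) / ms_res
        assert table.loc["tissue", "F"] == pytest.approx(f_tissue, rel=1e-9)

    def test_tissue_effect_detected_time_not(self):
        y, tissues, times = self.balanced_fixture()
        table = two_way_block_anova(y, tissues, times)
        assert table.loc["tissue", "PR(>F)"] < 0.01
        assert table.loc["time", "PR(>F)"] > 0.05

    def test_empty_cell_rejected(self):
        with pytest.raises(UnbalancedDesignError):
            two_way_block_anova(
                [1.0, 2.0, 3.0, 4.0],
                ["EM", "EM", "FR", "FR"],
                ["d5", "d5", "d5", "d20"],
            )
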