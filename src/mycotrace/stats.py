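"""Regression, threshold and group-comparison statistics for enrichment data.

This layer holds the inferential machinery of the pipeline:

* ordinary least-squares fits of enrichment against C/N ratio or against the
  enrichment of the attached lateral rootlet,
* t-tests of a fitted slope against a reference value (typically 1.0, the
  "no preferential allocation" line for the lateral-root coupling),
* comparison of two regression lines through the pooled interaction test,
* the C/N threshold: the x-intercept of a significant fit, with a percentile
  bootstrap (case resampling) or Fieller confidence interval,
* one-way ANOVA with Tukey-Kramer pairwise comparisons and a compact letter
  display, with an optional Shapiro-Wilk-gated log transform,
* Welch's one-sided test of labelled samples against non-labelled controls,
* Pearson correlation tests and a fixed-block two-way ANOVA (tissue + time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDesignError,
    DegenerateGroupError,
    ThresholdUndefinedError,
    UnbalancedDesignError,
    UndefinedCorrelationError,
)

__all__ = [
    "LinearFit",
    "SlopeTestResult",
    "ThresholdEstimate",
    "AnovaTukeyResult",
    "fit_linear",
    "test_slope_against_value",
    "compare_regression_lines",
    "x_intercept_threshold",
    "anova_tukey",
    "enrichment_above_control_test",
    "pearson_correlation_test",
    "two_way_block_anova",
]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r: float
    p_slope: float
    n: int

    @property
    def residual_df(self) -> int:
        return self.n - 2

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SlopeTestResult:
    slope: float
    reference_value: float
    t_statistic: float
    p_value: float
    direction: str
    df: int


@dataclass(frozen=True)
class ThresholdEstimate:
    x_intercept: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    method: str = "percentile"


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    group_means: pd.DataFrame
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    log_transformed: bool = False


def _validate_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDesignError("x and y must be 1-d of equal length")
    if x.size < 3:
        raise DegenerateDesignError("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant; slope is unidentifiable")
    return x, y


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS fit of y on x with slope/intercept standard errors.

    r is the Pearson correlation of x and y; p_slope is the two-sided
    p-value of slope = 0 from t = slope/se on n-2 df.
    """
    x, y = _validate_xy(x, y)
    if np.ptp(y) == 0:  # flat response: slope 0, correlation 0 by convention
        return LinearFit(0.0, float(y[0]), 0.0, 0.0, 0.0, 1.0, x.size)
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        r=float(res.rvalue),
        p_slope=float(res.pvalue),
        n=x.size,
    )


def _sided_p(t: float, df: int, direction: str) -> float:
    if direction == "two-sided":
        return float(2 * sps.t.sf(abs(t), df))
    if direction == "greater":
        return float(sps.t.sf(t, df))
    if direction == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown direction {direction!r}")


def test_slope_against_value(
    x, y, reference_value: float, direction: str = "two-sided"
) -> SlopeTestResult:
    """t-test of the OLS slope against a reference value.

    t = (slope - reference) / se_slope on n-2 df. The lateral-root coupling
    analysis tests against 1.0: a slope above 1 means the symbiont enriches
    more than the rootlet that feeds it.
    """
    fit = fit_linear(x, y)
    if fit.se_slope == 0:  # exact fit: t degenerates to 0 or +-inf
        diff = fit.slope - reference_value
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = (fit.slope - reference_value) / fit.se_slope
    p = _sided_p(t, fit.residual_df, direction)
    return SlopeTestResult(fit.slope, reference_value, float(t), p, direction, fit.residual_df)


def compare_regression_lines(x1, y1, x2, y2) -> SlopeTestResult:
    """Test equality of two regression slopes (pooled interaction test).

    Fits each line separately, pools the residual variance and tests
    (slope1 - slope2) on n1 + n2 - 4 df; algebraically identical to the
    interaction t of a dummy-variable regression with group-specific
    intercepts and slopes.
    """
    x1, y1 = _validate_xy(x1, y1)
    x2, y2 = _validate_xy(x2, y2)

    def _parts(x, y):
        b, a = np.polyfit(x, y, 1)
        resid = y - (a + b * x)
        sxx = float(((x - x.mean()) ** 2).sum())
        return b, float((resid**2).sum()), sxx

    b1, sse1, sxx1 = _parts(x1, y1)
    b2, sse2, sxx2 = _parts(x2, y2)
    df = x1.size + x2.size - 4
    s2 = (sse1 + sse2) / df
    se = np.sqrt(s2 * (1 / sxx1 + 1 / sxx2))
    if se == 0:  # both lines exact: equal slopes -> p = 1, else p = 0
        t = 0.0 if np.isclose(b1, b2) else np.inf
    else:
        t = (b1 - b2) / se
    p = _sided_p(float(t), df, "two-sided")
    return SlopeTestResult(float(b1 - b2), 0.0, float(t), p, "two-sided", df)


def _bootstrap_slopes(x, y, n_bootstrap, rng):
    n = x.size
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = ((xb - xm) ** 2).sum(axis=1)
    sxy = ((xb - xm) * (yb - ym)).sum(axis=1)
    ok = sxx > 0  # degenerate resamples (constant x) are dropped
    slope = sxy[ok] / sxx[ok]
    intercept = ym[ok, 0] - slope * xm[ok, 0]
    return slope, intercept


def x_intercept_threshold(
    x,
    y,
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha_slope: float = 0.05,
    method: str = "percentile",
) -> ThresholdEstimate:
    """C/N threshold: x-intercept of the fitted enrichment ~ C/N line.

    Point estimate -intercept/slope, defined only when the slope differs from
    zero at ``alpha_slope`` (the x-intercept of a flat line is meaningless).
    ``method="percentile"`` gives a case-resampling percentile bootstrap CI;
    ``method="fieller"`` the closed-form Fieller interval.
    """
    fit = fit_linear(x, y)
    if fit.p_slope > alpha_slope:
        raise ThresholdUndefinedError(
            f"slope not significant (p = {fit.p_slope:.3f} > {alpha_slope}); "
            "x-intercept threshold undefined"
        )
    point = -fit.intercept / fit.slope
    xa, ya = _validate_xy(x, y)

    if method == "percentile":
        rng = np.random.default_rng(seed)
        slope_b, int_b = _bootstrap_slopes(xa, ya, n_bootstrap, rng)
        nz = slope_b != 0
        thr = -int_b[nz] / slope_b[nz]
        lo, hi = np.percentile(thr, [2.5, 97.5])
    elif method == "fieller":
        # roots of (a + b t)^2 = t_crit^2 (var_a + 2 t cov_ab + t^2 var_b)
        n = xa.size
        tcrit = sps.t.ppf(0.975, n - 2)
        resid = ya - fit.predict(xa)
        s2 = float((resid**2).sum()) / (n - 2)
        sxx = float(((xa - xa.mean()) ** 2).sum())
        var_b = s2 / sxx
        var_a = s2 * (1 / n + xa.mean() ** 2 / sxx)
        cov_ab = -s2 * xa.mean() / sxx
        A = fit.slope**2 - tcrit**2 * var_b
        B = 2 * (fit.slope * fit.intercept - tcrit**2 * cov_ab)
        C = fit.intercept**2 - tcrit**2 * var_a
        disc = B**2 - 4 * A * C
        if A <= 0 or disc < 0:
            raise ThresholdUndefinedError(
                "Fieller interval unbounded (slope too close to zero)"
            )
        r1 = (-B - np.sqrt(disc)) / (2 * A)
        r2 = (-B + np.sqrt(disc)) / (2 * A)
        lo, hi = sorted((r1, r2))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ThresholdEstimate(float(point), float(lo), float(hi), n_bootstrap, seed, method)


def _compact_letter_display(
    names: list[str], means: dict[str, float], sig: set[tuple[str, str]]
) -> dict[str, str]:
    """Insertion/absorption compact letter display.

    Groups are ordered by descending mean (deterministic tie-break by name);
    two groups share a letter iff their pair is not in ``sig``.
    """
    order = sorted(names, key=lambda g: (-means[g], g))
    columns: list[set[str]] = [set(order)]
    for a, b in sig:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend((col - {a}, col - {b}))
            else:
                new_cols.append(col)
        # absorb columns contained in (or duplicating) another
        columns = []
        for i, c in enumerate(new_cols):
            absorbed = False
            for j, d in enumerate(new_cols):
                if i == j:
                    continue
                if c < d or (c == d and i > j):
                    absorbed = True
                    break
            if c and not absorbed:
                columns.append(c)
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def tukey_kramer_pairwise(groups: Mapping[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer adjusted pairwise p-values (unbalanced-safe).

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 (1/n_i + 1/n_j)); the adjusted p
    is the survival function of the studentized range with k groups and the
    pooled error df.
    """
    names = list(groups)
    k = len(names)
    ns = {g: len(groups[g]) for g in names}
    means = {g: float(np.mean(groups[g])) for g in names}
    df_err = sum(ns.values()) - k
    mse = sum(((np.asarray(groups[g], float) - means[g]) ** 2).sum() for g in names) / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
            q = abs(means[a] - means[b]) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_err))
            rows.append({"group1": a, "group2": b, "meandiff": means[a] - means[b],
                         "q": float(q), "p_adj": p, "reject": p <= alpha})
    return pd.DataFrame(rows)


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    auto_log: bool = True,
) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey-Kramer post hoc letters.

    When ``auto_log`` is set and a Shapiro-Wilk test of the pooled residuals
    rejects normality at p < 0.05 (and all responses are positive), all
    statistics are computed on log-transformed responses; reported group
    means stay on the original scale and the result is flagged.
    """
    if len(groups) < 2:
        raise DegenerateGroupError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise DegenerateGroupError(f"group {g!r} has fewer than 2 values")

    log_transformed = False
    resid = np.concatenate([v - v.mean() for v in arrays.values()])
    if auto_log and np.ptp(resid) > 0 and sps.shapiro(resid).pvalue < 0.05:
        if all((v > 0).all() for v in arrays.values()):
            arrays = {g: np.log(v) for g, v in arrays.items()}
            log_transformed = True

    f, p = sps.f_oneway(*arrays.values())
    pairwise = tukey_kramer_pairwise(arrays, alpha=alpha)
    means = {g: float(v.mean()) for g, v in arrays.items()}
    sig = {
        tuple(sorted((r.group1, r.group2)))
        for r in pairwise.itertuples()
        if r.p_adj <= alpha
    }
    letters = _compact_letter_display(list(arrays), means, sig)

    orig = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    gm = pd.DataFrame(
        {
            "group": list(orig),
            "n": [orig[g].size for g in orig],
            "mean": [float(orig[g].mean()) for g in orig],
            "se": [float(orig[g].std(ddof=1) / np.sqrt(orig[g].size)) for g in orig],
            "letters": [letters[g] for g in orig],
        }
    )
    return AnovaTukeyResult(float(f), float(p), gm, pairwise, letters, alpha, log_transformed)


def enrichment_above_control_test(
    labelled: Sequence[float], control: Sequence[float], direction: str = "greater"
) -> float:
    """Welch two-sample t-test of labelled values against controls.

    One-sided "greater" by default: under labelling, enrichment can only
    exceed the natural-abundance controls.
    """
    lab = np.asarray(labelled, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if lab.size < 2 or ctl.size < 2:
        raise DegenerateGroupError("both samples need n >= 2")
    res = sps.ttest_ind(lab, ctl, equal_var=False, alternative=direction)
    return float(res.pvalue)


def pearson_correlation_test(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def two_way_block_anova(
    response: Sequence[float],
    factor_tissue: Sequence,
    factor_time: Sequence,
    max_empty_cell_fraction: float = 0.0,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA, tissue + time block, no interaction.

    Approximates a "time as random factor" model for a two-level time factor:
    with only two dates a random factor is inestimable, so time enters as a
    fixed block. Returns a table with sum_sq, df, F and p per factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "tissue": np.asarray(factor_tissue).astype(str),
            "time": np.asarray(factor_time).astype(str),
        }
    )
    cells = df.groupby(["tissue", "time"], sort=True).size()
    n_tissue = df["tissue"].nunique()
    n_time = df["time"].nunique()
    if n_tissue < 2 or n_time < 2:
        raise UnbalancedDesignError("both factors need at least two levels")
    empty = n_tissue * n_time - len(cells)
    if empty / (n_tissue * n_time) > max_empty_cell_fraction:
        raise UnbalancedDesignError(
            f"{empty} empty tissue x time cells; collect the missing "
            "combinations or analyse factors separately"
        )
    model = smf.ols("y ~ C(tissue) + C(time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index={"C(tissue)": "tissue", "C(time)": "time", "Residual": "residual"})
    return table
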