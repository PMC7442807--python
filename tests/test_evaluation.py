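"""Evaluation statistics: correlation tests, Williams' dependent-correlation
test (null calibration and power), calibration slope, Box-Cox, the
medcouple-adjusted boxplot against a brute-force kernel oracle, Fisher's
exact test against enumeration, and summary t tests."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from polybench.evaluation import (adjusted_boxplot_outliers, boxcox_transform,
                                  calibration_slope, fisher_exact_2x2,
                                  partial_correlation, pcc, power_summary,
                                  ttest_from_summary, williams_test)


# ---------------------------------------------------------------------------
# correlations

def test_pcc_trivials_and_boundary(rng):
    y = rng.standard_normal(100)
    assert pcc(y, y)[0] == pytest.approx(1.0)
    assert pcc(-y, y)[0] == pytest.approx(-1.0)
    # n = 3048, r = 0.0355 sits at the alpha = 0.05 boundary
    n = 3048
    r = 0.0355
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(t, n - 2)
    assert p == pytest.approx(0.05, abs=0.003)
    with pytest.raises(ValueError):
        pcc(np.ones(10), rng.standard_normal(10))


def test_pcc_matches_scipy(rng):
    x, y = rng.standard_normal((2, 200))
    r, p = pcc(x, y)
    r2, p2 = stats.pearsonr(x, y)
    assert r == pytest.approx(r2, abs=1e-12)
    assert p == pytest.approx(p2, rel=1e-8)


def test_partial_correlation_identities(rng):
    x, y = rng.standard_normal((2, 150))
    assert partial_correlation(x, y, None) == pytest.approx(pcc(x, y))
    C = rng.standard_normal((150, 2))
    # a prediction driven by the covariates alone: the plain correlation
    # with a covariate-driven outcome is large, the partial one vanishes
    pred = C @ [1.0, -2.0] + 0.1 * rng.standard_normal(150)
    y_cov = C @ [1.0, -2.0] + 0.5 * rng.standard_normal(150)
    assert abs(pcc(pred, y_cov)[0]) > 0.8
    r, p = partial_correlation(pred, y_cov, C)
    assert abs(r) < 0.2
    # invariance to affine transforms of the covariates
    r1, p1 = partial_correlation(x, y, C)
    r2, p2 = partial_correlation(x, y, 3.0 * C + 7.0)
    assert r1 == pytest.approx(r2, abs=1e-10)


def test_partial_correlation_single_covariate_recursion(rng):
    x, y = rng.standard_normal((2, 80))
    z = rng.standard_normal(80)
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    expect = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    r, _ = partial_correlation(x, y, z)
    assert r == pytest.approx(expect, abs=1e-10)


# ---------------------------------------------------------------------------
# Williams' test

def test_williams_symmetry_and_antisymmetry():
    t0, p0 = williams_test(0.3, 0.3, 0.5, 100)
    assert t0 == 0.0 and p0 == pytest.approx(1.0)
    t1, _ = williams_test(0.4, 0.1, 0.3, 200)
    t2, _ = williams_test(0.1, 0.4, 0.3, 200)
    assert t1 == pytest.approx(-t2, abs=1e-12)


def test_williams_null_statistic_follows_t_distribution():
    """Under rho12 = rho13 the statistic is t-distributed with n-3 df."""
    rng = np.random.default_rng(77)
    n = 120
    ts = []
    for _ in range(300):
        r12, r13, r23 = _trivariate(rng, n, 0.25, 0.25, 0.4)
        ts.append(williams_test(r12, r13, r23, n)[0])
    ks = stats.kstest(ts, stats.t(n - 3).cdf)
    assert ks.pvalue > 0.01


def _trivariate(rng, n, r12, r13, r23):
    S = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
    X = rng.multivariate_normal(np.zeros(3), S, size=n)
    c = np.corrcoef(X.T)
    return c[0, 1], c[0, 2], c[1, 2]


def test_williams_power_and_type_one_error():
    rng = np.random.default_rng(404)
    rej_alt = rej_null = 0
    reps = 200
    for _ in range(reps):
        r12, r13, r23 = _trivariate(rng, 500, 0.3, 0.0, 0.5)
        rej_alt += williams_test(r12, r13, r23, 500)[1] < 0.05
        r12, r13, r23 = _trivariate(rng, 500, 0.2, 0.2, 0.3)
        rej_null += williams_test(r12, r13, r23, 500)[1] < 0.05
    assert rej_alt / reps > 0.9
    assert abs(rej_null / reps - 0.05) < 0.04


def test_williams_invalid_inputs():
    with pytest.raises(ValueError):
        williams_test(1.0, 0.2, 0.3, 50)
    with pytest.raises(ValueError):
        williams_test(0.9, -0.9, 0.9, 50)  # not positive definite
    with pytest.raises(ValueError):
        williams_test(0.1, 0.2, 0.3, 3)


# ---------------------------------------------------------------------------
# calibration slope

def test_calibration_slope_values(rng):
    y = rng.standard_normal(100)
    s, se = calibration_slope(y, y)
    assert s == pytest.approx(1.0) and se == pytest.approx(0.0, abs=1e-10)
    s2, _ = calibration_slope(y, y / 2)
    assert s2 == pytest.approx(2.0)
    with pytest.raises(ValueError):
        calibration_slope(y, np.ones(100))


def test_calibration_slope_is_one_for_insample_ols(rng):
    """Normal-equations identity: regressing y on its own OLS fit gives 1."""
    X = np.column_stack([np.ones(200), rng.standard_normal((200, 4))])
    y = X @ rng.standard_normal(5) + rng.standard_normal(200)
    fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s, _ = calibration_slope(y, fitted)
    assert s == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# power summary

def test_power_summary_arithmetic():
    res = [(0.1, 0.01)] * 17 + [(0.0, 0.5)] * 3
    s = power_summary(res)
    assert s.power == pytest.approx(0.85)
    assert s.n_reps == 20
    assert power_summary([(0.1, 0.9)] * 5, alpha=1.0).power == 1.0
    assert power_summary([(0.1, 0.9)] * 5).power == 0.0


# ---------------------------------------------------------------------------
# Box-Cox

def test_boxcox_lambda_one_is_affine(rng):
    y = rng.uniform(1, 5, 500)
    yt, lam, shift = boxcox_transform(y)
    # whatever lambda, transform is monotone; for lambda ~ 1 it is affine
    assert np.all(np.diff(yt[np.argsort(y)]) >= 0)


def test_boxcox_lognormal_lambda_near_zero(rng):
    y = np.exp(rng.standard_normal(5000))
    yt, lam, shift = boxcox_transform(y)
    assert abs(lam) < 0.1
    assert shift == 0.0


def test_boxcox_reduces_right_skew(rng):
    y = rng.gamma(2.0, 2.0, 2000)
    yt, lam, _ = boxcox_transform(y)
    assert abs(stats.skew(yt)) < abs(stats.skew(y))


def test_boxcox_shifts_zeros(rng):
    y = np.floor(rng.gamma(1.5, 3.0, 500))  # count-like scores with zeros
    assert (y == 0).any()
    yt, lam, shift = boxcox_transform(y)
    assert shift == 1.0


# ---------------------------------------------------------------------------
# adjusted boxplot / medcouple

def _medcouple_bruteforce(y):
    y = np.sort(np.asarray(y, dtype=float))
    med = np.median(y)
    lo = y[y <= med]
    hi = y[y >= med]
    vals = []
    for xi in lo:
        for xj in hi:
            if xi == med and xj == med:
                continue  # kernel defined via sign rule for ties at median
            if xj == xi:
                continue
            vals.append(((xj - med) - (med - xi)) / (xj - xi))
    return np.median(vals)


def test_medcouple_symmetric_sample_is_zero():
    y = np.concatenate([np.arange(-10, 0), np.arange(1, 11)]).astype(float)
    from statsmodels.stats.stattools import medcouple
    assert medcouple(y) == pytest.approx(0.0, abs=1e-12)


def test_medcouple_matches_bruteforce(rng):
    for _ in range(3):
        y = rng.gamma(2.0, 1.0, 200)
        from statsmodels.stats.stattools import medcouple
        assert medcouple(y) == pytest.approx(_medcouple_bruteforce(y),
                                             abs=1e-12)


def test_adjusted_boxplot_reduces_to_tukey_when_symmetric(rng):
    y = rng.standard_normal(2001)
    mask = adjusted_boxplot_outliers(y)
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    from statsmodels.stats.stattools import medcouple
    mc = medcouple(y)
    assert abs(mc) < 0.05
    tukey = (y < q1 - 1.5 * np.exp(-4 * mc) * iqr) | \
            (y > q3 + 1.5 * np.exp(3 * mc) * iqr)
    np.testing.assert_array_equal(mask, tukey)


def test_adjusted_boxplot_flags_fewer_upper_points_when_right_skewed(rng):
    y = rng.lognormal(0, 1, 1000)
    adj = adjusted_boxplot_outliers(y)
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    classical = (y < q1 - 1.5 * iqr) | (y > q3 + 1.5 * iqr)
    assert adj.sum() < classical.sum()


# ---------------------------------------------------------------------------
# Fisher exact

def _fisher_oracle(a, b, c, d):
    """Enumerate tables with fixed margins; sum P <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        return (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
                + gammaln(r2 + 1) - gammaln(c1 - x + 1)
                - gammaln(r2 - c1 + x + 1)
                - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    ps = np.exp([logp(x) for x in xs])
    obs = np.exp(logp(a))
    return float(ps[ps <= obs * (1 + 1e-7)].sum())


def test_fisher_reproduces_cohort_table_cells():
    """Previous-depression, previous-bipolar and family-bipolar history
    counts from the two cohorts give the published P values."""
    assert fisher_exact_2x2(104, 3581, 81, 2967) == pytest.approx(0.708,
                                                                  abs=5e-4)
    assert fisher_exact_2x2(9, 3676, 6, 3042) == pytest.approx(0.798,
                                                               abs=5e-4)
    assert fisher_exact_2x2(27, 3658, 26, 3022) == pytest.approx(0.583,
                                                                 abs=5e-4)


def test_fisher_identical_rows_give_one():
    assert fisher_exact_2x2(10, 90, 10, 90) == pytest.approx(1.0)


@pytest.mark.parametrize("table", list(itertools.product([0, 3, 11], repeat=4)))
def test_fisher_matches_enumeration(table):
    a, b, c, d = table
    if min(a + b, c + d, a + c, b + d) == 0:
        assert fisher_exact_2x2(a, b, c, d) == 1.0
        return
    assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
        _fisher_oracle(a, b, c, d), abs=1e-12)


def test_fisher_transpose_invariant(rng):
    for _ in range(10):
        a, b, c, d = rng.integers(0, 40, 4)
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(a, c, b, d), abs=1e-12)


# ---------------------------------------------------------------------------
# t test from summaries

def test_ttest_summary_values(rng):
    t, p = ttest_from_summary(1.0, 1.0, 100, 1.0, 1.0, 100)
    assert t == 0.0 and p == pytest.approx(1.0)
    t2, _ = ttest_from_summary(1.0, 1.0, 100, 0.0, 1.0, 100)
    assert t2 == pytest.approx(7.0711, abs=1e-3)
    # consistency with raw-sample computation
    x = rng.standard_normal(60) + 0.3
    y = rng.standard_normal(80)
    t3, p3 = ttest_from_summary(x.mean(), x.std(ddof=1), 60,
                                y.mean(), y.std(ddof=1), 80)
    t4, p4 = stats.ttest_ind(x, y, equal_var=True)
    assert t3 == pytest.approx(t4, abs=1e-10)
    assert p3 == pytest.approx(p4, abs=1e-10)
    with pytest.raises(ValueError):
        ttest_from_summary(0, 0.0, 10, 0, 1, 10)


# ---------------------------------------------------------------------------
# method-comparison report

def test_evaluation_report_reference_and_comparisons(rng):
    from polybench.evaluation import evaluation_report
    n = 400
    y = rng.standard_normal(n)
    good = y + 0.8 * rng.standard_normal(n)
    bad = 0.05 * y + rng.standard_normal(n)
    rep = evaluation_report(y, {"stmgp": good, "noise": bad})
    ref = rep[rep["method"] == "stmgp"].iloc[0]
    other = rep[rep["method"] == "noise"].iloc[0]
    assert ref["williams_t"] == 0.0 and ref["williams_p"] == 1.0
    assert ref["r"] > other["r"]
    assert other["williams_p"] < 0.05  # the gap is detectable
    with pytest.raises(KeyError):
        evaluation_report(y, {"a": good}, reference="b")
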