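"""Performance metrics and statistical comparisons for the benchmark:
predictive and partial correlations, Williams' test for dependent
correlations, calibration slope, replicate power, Box-Cox transformation,
adjusted (skewness-tilted) boxplot outlier detection, and the demographic
tests (Fisher exact, two-sample t from summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.stattools import medcouple


def evaluation_report(y, predictions: dict, C=None,
                      reference: str = "stmgp"):
    """Per-method evaluation table against one observed phenotype.

    For every method in ``predictions`` (name -> predicted vector):
    correlation (partial if covariates are given) with its P value, the
    calibration slope, and Williams' test of whether the method's
    correlation differs from the reference method's (the two correlations
    share the observed phenotype).  Returns a pandas DataFrame.
    """
    import pandas as pd
    y = np.asarray(y, dtype=np.float64)
    if reference not in predictions:
        raise KeyError(f"reference method {reference!r} not in predictions")
    n = len(y)
    ref = np.asarray(predictions[reference], dtype=np.float64)

    def corr(p):
        return partial_correlation(p, y, C) if C is not None and np.size(C) \
            else pcc(p, y)

    r_ref, _ = corr(ref)
    rows = []
    for name, pred in predictions.items():
        pred = np.asarray(pred, dtype=np.float64)
        r, p = corr(pred)
        slope, slope_se = calibration_slope(y, pred)
        if name == reference:
            w_t, w_p = 0.0, 1.0
        else:
            r_pair = float(np.corrcoef(ref, pred)[0, 1])
            w_t, w_p = williams_test(r_ref, r, r_pair, n)
        rows.append(dict(method=name, r=r, p=p, slope=slope,
                         slope_se=slope_se, williams_t=w_t, williams_p=w_p,
                         n=n))
    return pd.DataFrame(rows)


def pcc(pred, y):
    """Pearson predictive correlation with its two-sided P value from
    t = r sqrt((n-2)/(1-r^2))."""
    pred = np.asarray(pred, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if len(pred) != n or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r = float(np.corrcoef(pred, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def partial_correlation(pred, y, C):
    """Correlation of pred and y after regressing both on [1, C];
    P from t with df = n - 2 - c."""
    pred = np.asarray(pred, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if C is None or np.size(C) == 0:
        return pcc(pred, y)
    Cm = np.asarray(C, dtype=np.float64)
    if Cm.ndim == 1:
        Cm = Cm[:, None]
    X = np.column_stack([np.ones(n), Cm])
    Q, R = np.linalg.qr(X)
    if np.abs(np.diag(R)).min() < 1e-10 * max(1.0, np.abs(np.diag(R)).max()):
        raise ValueError("rank-deficient covariate matrix")
    pr = pred - Q @ (Q.T @ pred)
    yr = y - Q @ (Q.T @ y)
    if np.ptp(pr) == 0 or np.ptp(yr) == 0:
        raise ValueError("residualized vector is constant")
    r = float(np.corrcoef(pr, yr)[0, 1])
    r = max(-1.0, min(1.0, r))
    c = Cm.shape[1]
    df = n - 2 - c
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def williams_test(r12: float, r13: float, r23: float, n: int):
    """Williams' t for the difference of two dependent correlations that
    share variable 1 (H0: rho12 = rho13), df = n - 3, two-sided P."""
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must be in (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError("correlation triple is not positive definite")
    rbar = 0.5 * (r12 + r13)
    num = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23))
    den = np.sqrt(2.0 * detR * (n - 1) / (n - 3)
                  + rbar**2 * (1.0 - r23) ** 3)
    t = num / den
    return float(t), float(2.0 * stats.t.sf(abs(t), n - 3))


def calibration_slope(y, pred):
    """OLS slope (with SE) of the observed phenotype on the predictions."""
    y = np.asarray(y, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if np.ptp(pred) == 0:
        raise ValueError("constant predictions have no slope")
    n = len(y)
    x = pred - pred.mean()
    sxx = float(x @ x)
    slope = float(x @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - slope * x
    se = np.sqrt(float(resid @ resid) / max(n - 2, 1) / sxx)
    return slope, float(se)


@dataclass
class ReplicateSummary:
    """Mean/SD of the correlation across replicates and the share of
    replicates significant at alpha (the benchmark's 'power')."""

    mean_r: float
    sd_r: float
    power: float
    n_reps: int


def power_summary(results, alpha: float = 0.05) -> ReplicateSummary:
    """Summarize replicate (r, p) pairs: mean r, SD, share with p < alpha."""
    arr = np.asarray(results, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("results must be an (n_reps, 2) array of (r, p)")
    r, p = arr[:, 0], arr[:, 1]
    return ReplicateSummary(
        mean_r=float(r.mean()),
        sd_r=float(r.std(ddof=1)) if len(r) > 1 else 0.0,
        power=float((p < alpha).mean()),
        n_reps=len(r),
    )


def boxcox_transform(y):
    """Box-Cox transform with ML-estimated lambda; a +1 shift is applied
    when zeros are present.  Returns (transformed, lambda, shift)."""
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        raise ValueError("constant input")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min() if y.min() < 0 else 1.0
    yt, lam = stats.boxcox(y + shift)
    return yt, float(lam), shift


def adjusted_boxplot_outliers(y) -> np.ndarray:
    """Outlier mask from the medcouple-adjusted boxplot.

    For medcouple MC >= 0 the fences are
    [Q1 - 1.5 e^(-4 MC) IQR, Q3 + 1.5 e^(3 MC) IQR]; the exponents swap
    sign roles for MC < 0.  MC = 0 recovers the classical 1.5 IQR rule.
    """
    y = np.asarray(y, dtype=np.float64)
    if len(y) < 10:
        raise ValueError("need n >= 10 for the adjusted boxplot")
    mc = float(medcouple(y))
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    if mc >= 0:
        lo = q1 - 1.5 * np.exp(-4.0 * mc) * iqr
        hi = q3 + 1.5 * np.exp(3.0 * mc) * iqr
    else:
        lo = q1 - 1.5 * np.exp(-3.0 * mc) * iqr
        hi = q3 + 1.5 * np.exp(4.0 * mc) * iqr
    return (y < lo) | (y > hi)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for a 2x2 table (probability-mass
    convention, as in R's fisher.test)."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0  # degenerate margin
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def ttest_from_summary(m1: float, sd1: float, n1: int,
                       m2: float, sd2: float, n2: int):
    """Pooled-variance two-sample Student t from summary statistics;
    df = n1 + n2 - 2, two-sided P."""
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("need positive SDs and n >= 2 per group")
    t, p = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                      equal_var=True)
    return float(t), float(p)
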