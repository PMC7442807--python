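"""Smooth-threshold multivariate genetic prediction (STMGP).

The predictor runs in four stages on the training cohort:

1. marginal GWAS of the phenotype on each standardized variant (adjusting
   for covariates);
2. for each candidate P-value cutoff, smooth-threshold weights are formed
   from the marginal t statistics: variants with P above the cutoff are
   excluded, variants below it receive a penalty weight
   delta_j = (lambda / |t_j|)^(1+gamma) in [0, 1) that vanishes as the
   association strengthens (lambda is the |t| value sitting exactly at the
   cutoff);
3. a generalized ridge regression with per-variant penalties
   tau * delta_j/(1-delta_j) (covariates unpenalized) is fitted for every
   cutoff, and Mallows' Cp = RSS + 2 sigma^2 df selects the cutoff, with
   df the trace of the smoother matrix;
4. the selected model predicts the held-out cohort, standardizing test
   genotypes with the *training* allele frequencies.

tau defaults to N/sqrt(log N); gamma defaults to 1, matching the adaptive
lasso's conventional weighting exponent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .assoc import GwasResult, gwas_scan, _covariate_basis
from .genotype_io import GenotypeMatrix, MISSING
from .synthetic_data import standardize_dosages

_EPS_DELTA = 1e-8


def default_tau(n: int) -> float:
    """tau = N / sqrt(log N), the recommended scaling of the overall
    penalty with sample size."""
    if n < 2:
        raise ValueError("need n >= 2")
    return n / np.sqrt(np.log(n))


_TAU_PRESETS = ("auto", "N/0.1", "N/1", "N/10")


def tau_preset(n: int, name: str = "auto") -> float:
    """Named tau settings: 'auto' (N/sqrt(log N)) and the sensitivity
    alternates N/0.1, N/1, N/10."""
    if name == "auto":
        return default_tau(n)
    if name in _TAU_PRESETS:
        return n / float(name.split("/")[1])
    raise ValueError(f"unknown tau preset {name!r}; use one of {_TAU_PRESETS}")


def smooth_threshold_weights(t_stats: np.ndarray, cutoff: float,
                             gamma: float = 1.0, df: int = 100):
    """Selected set and smooth-threshold weights at a P-value cutoff.

    Returns (selected indices, delta values).  lambda is the |t| whose
    two-sided P equals the cutoff at ``df`` residual degrees of freedom;
    the selected set is {j : P_j <= cutoff}, i.e. |t_j| >= lambda, and
    delta_j = min(1 - eps, (lambda/|t_j|)^(1+gamma)).
    """
    t_stats = np.asarray(t_stats, dtype=np.float64)
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0,1]")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if t_stats.size > 1 and np.ptp(np.abs(t_stats)) == 0.0:
        raise ValueError("degenerate t statistics (zero variance)")
    lam = float(stats.t.isf(cutoff / 2.0, df))
    at = np.abs(t_stats)
    sel = np.flatnonzero(at >= lam)
    with np.errstate(divide="ignore"):
        delta = np.minimum(1.0 - _EPS_DELTA,
                           (lam / at[sel]) ** (1.0 + gamma))
    if lam == 0.0:  # cutoff = 1: everything selected, no shrinkage weight
        delta = np.zeros(sel.size)
    return sel, delta


def fit_generalized_ridge(C, X_A: np.ndarray, y: np.ndarray, tau: float,
                          delta: np.ndarray) -> np.ndarray:
    """Minimize ||y - C b - X_A beta||^2 + tau * sum_j d_j beta_j^2 with
    d_j = delta_j/(1-delta_j); the covariate block (C includes whatever
    should stay unpenalized, e.g. the intercept) is not shrunk.

    Returns the stacked coefficient vector [b, beta].
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X_A, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    if np.any(delta >= 1.0) or np.any(delta < 0.0):
        raise ValueError("delta must lie in [0, 1)")
    if X.shape[1] != delta.size:
        raise ValueError("delta must align with X_A columns")
    if C is None:
        Cm = np.empty((len(y), 0))
    else:
        Cm = np.asarray(C, dtype=np.float64)
        if Cm.ndim == 1:
            Cm = Cm[:, None]
    M = np.column_stack([Cm, X])
    G = M.T @ M
    rhs = M.T @ y
    q = Cm.shape[1]
    d = delta / (1.0 - delta)
    G[q:, q:][np.diag_indices(X.shape[1])] += tau * d
    try:
        cf = sla.cho_factor(G, lower=True)
        return sla.cho_solve(cf, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - tau>0 guards this
        raise np.linalg.LinAlgError(f"singular penalized system: {exc}")


def cp_criterion(y: np.ndarray, fitted: np.ndarray, df_model: float,
                 sigma2_hat: float) -> float:
    """Mallows' Cp-type criterion RSS + 2 * sigma2 * df."""
    y = np.asarray(y, dtype=np.float64)
    if df_model < 0 or df_model > len(y):
        raise ValueError("df_model must be in [0, n]")
    if sigma2_hat <= 0:
        raise ValueError("sigma2_hat must be positive")
    rss = float(np.sum((y - np.asarray(fitted)) ** 2))
    return rss + 2.0 * sigma2_hat * df_model


def ridge_df(XtX_proj: np.ndarray, tau: float, d: np.ndarray) -> float:
    """Trace of the SNP-block smoother: tr[(G + tau D)^-1 G] for the
    covariate-projected gram matrix G."""
    p = XtX_proj.shape[0]
    if p == 0:
        return 0.0
    A = XtX_proj + np.diag(tau * np.asarray(d))
    cf = sla.cho_factor(A, lower=True)
    Ainv = sla.cho_solve(cf, np.eye(p))
    return float(p - tau * np.sum(np.diag(Ainv) * d))


def default_cutoff_grid(m: int, n_points: int = 20) -> np.ndarray:
    """Geometric grid of candidate P cutoffs from 1/(2m) to 0.05, plus the
    Bonferroni point 0.05/m."""
    grid = np.geomspace(1.0 / (2 * m), 0.05, n_points)
    return np.unique(np.concatenate([grid, [0.05 / m]]))


@dataclass
class StmgpModel:
    """Fitted STMGP predictor."""

    tau: float
    gamma: float
    cutoff_grid: np.ndarray
    cp_path: pd.DataFrame          # cutoff, n_selected, df, rss, cp
    selected_cutoff: float
    selected: np.ndarray           # training column indices, GWAS-P order
    variant_ids: np.ndarray | None
    delta: np.ndarray
    coef_cov: np.ndarray           # intercept first, then covariates
    beta_snp: np.ndarray           # standardized scale
    sigma2_hat: float
    freq: np.ndarray               # training allele frequency of selected
    gwas: GwasResult | None = None

    def to_json_dict(self) -> dict:
        return {
            "tau": self.tau, "gamma": self.gamma,
            "selected_cutoff": self.selected_cutoff,
            "sigma2_hat": self.sigma2_hat,
            "n_selected": int(len(self.selected)),
            "coef_cov": self.coef_cov.tolist(),
            "selected": self.selected.tolist(),
            "variant_ids": (None if self.variant_ids is None
                            else list(map(str, self.variant_ids))),
            "beta_snp": self.beta_snp.tolist(),
            "freq": self.freq.tolist(),
        }

    def coefficient_table(self) -> pd.DataFrame:
        ids = (self.selected.astype(str) if self.variant_ids is None
               else self.variant_ids)
        return pd.DataFrame({"SNP": ids, "BETA_STD": self.beta_snp,
                             "DELTA": self.delta, "FREQ": self.freq})


def _as_dosages(G):
    if isinstance(G, GenotypeMatrix):
        return G.dosages, G.variants["id"].to_numpy()
    arr = np.asarray(G)
    return arr, None


def stmgp_fit(G_train, y_train, C_train=None, tau: float | str | None = None,
              gamma: float = 1.0, cutoff_grid: np.ndarray | None = None,
              max_selected: int | None = None,
              _W: np.ndarray | None = None) -> StmgpModel:
    """Fit STMGP on a training cohort.

    ``G_train`` is a GenotypeMatrix or an int8 dosage matrix.  ``_W`` is an
    optional float32 scratch buffer of shape (n, m) reused across calls.
    """
    dos, ids = _as_dosages(G_train)
    n, m = dos.shape
    y = np.asarray(y_train, dtype=np.float64)
    if len(y) != n:
        raise ValueError("phenotype and genotypes must align")
    if tau is None or tau == "auto":
        tau = default_tau(n)
    elif isinstance(tau, str):
        tau = tau_preset(n, tau)
    tau = float(tau)
    if cutoff_grid is None:
        cutoff_grid = default_cutoff_grid(m)
    cutoff_grid = np.sort(np.asarray(cutoff_grid, dtype=np.float64))

    # training-frequency standardization; monomorphic columns are left as
    # all-zero so the scan never selects them
    miss = dos == MISSING
    n_obs = n - miss.sum(axis=0)
    p = np.where(miss, 0, dos).sum(axis=0, dtype=np.int64) / np.maximum(1, 2 * n_obs)
    poly = (p > 0) & (p < 1) & (n_obs > 0)
    p_safe = np.clip(p, 1e-6, 1 - 1e-6)
    if _W is None:
        W = np.empty((n, m), dtype=np.float32)
    else:
        W = _W[:n, :m]
    standardize_dosages(dos, p_safe, out=W)
    if not poly.all():
        W[:, ~poly] = 0.0

    gwas = gwas_scan(W, y, C_train)
    pvals = np.where(poly, gwas.p, 1.0 + gwas.p)  # monomorphic: never selected
    df_t = gwas.df_resid
    # covariate-projected column sums of squares, reused for the Cp df
    A_qtw = _covariate_basis(n, C_train)
    sxx_proj = np.einsum("ij,ij->j", W, W, dtype=np.float64)
    Aq = A_qtw.T.astype(W.dtype) @ W
    sxx_proj -= np.einsum("ij,ij->j", Aq, Aq, dtype=np.float64)
    sxx_proj = np.maximum(sxx_proj, 1e-12)

    Q = _covariate_basis(n, C_train)
    q = Q.shape[1]
    if C_train is None or np.size(C_train) == 0:
        Cm = np.ones((n, 1))
    else:
        Ca = np.asarray(C_train, dtype=np.float64)
        Cm = np.column_stack([np.ones(n), Ca if Ca.ndim == 2 else Ca[:, None]])
    # covariate-only baseline for the external error-variance estimate
    y_r = y - Q @ (Q.T @ y)
    rss0 = float(y_r @ y_r)
    sigma2_hat = rss0 / (n - q)

    order = np.argsort(pvals, kind="stable")
    counts = np.searchsorted(pvals[order], cutoff_grid, side="right")
    p_max = int(counts.max())
    if max_selected is not None:
        p_max = min(p_max, max_selected)
        counts = np.minimum(counts, p_max)

    lam_grid = stats.t.isf(cutoff_grid / 2.0, df_t)
    at_sorted = np.abs(gwas.t[order[:p_max]])

    CtC = Cm.T @ Cm
    Cty = Cm.T @ y
    yty = float(y @ y)
    if p_max > 0:
        X = W[:, order[:p_max]].astype(np.float64)
        CtX = Cm.T @ X
        XtX = X.T @ X
        Xty = X.T @ y
        # covariate-projected gram for the df trace
        CtC_inv_CtX = np.linalg.solve(CtC, CtX)
        XtX_proj = XtX - CtX.T @ CtC_inv_CtX

    rows = []
    best = None
    for c_idx, cutoff in enumerate(cutoff_grid):
        pc = int(counts[c_idx])
        if pc == 0:
            theta = np.linalg.solve(CtC, Cty)
            rss = rss0
            df_model = float(q)
            cp = rss + 2.0 * sigma2_hat * df_model
            cand = (cp, cutoff, pc, theta, np.empty(0), df_model, rss)
        else:
            lam = lam_grid[c_idx]
            at = at_sorted[:pc]
            delta = np.minimum(1.0 - _EPS_DELTA,
                               (lam / at) ** (1.0 + gamma)) if lam > 0 else \
                np.zeros(pc)
            d = delta / (1.0 - delta)
            Gm = np.empty((q + pc, q + pc))
            Gm[:q, :q] = CtC
            Gm[:q, q:] = CtX[:, :pc]
            Gm[q:, :q] = CtX[:, :pc].T
            Gm[q:, q:] = XtX[:pc, :pc]
            Gm[q:, q:][np.diag_indices(pc)] += tau * d
            rhs = np.concatenate([Cty, Xty[:pc]])
            cf = sla.cho_factor(Gm, lower=True)
            theta = sla.cho_solve(cf, rhs)
            beta = theta[q:]
            rss = yty - theta @ rhs - tau * float((d * beta**2).sum())
            # unbiased Cp df: exact ridge-smoother trace plus the divergence
            # of the data-dependent smooth-threshold weights (the weights
            # delta_j are functions of y through t_j, so the estimator
            # spends extra degrees of freedom at the selection boundary;
            # per-variant orthogonal-design form
            # (1+gamma) a_j (1-a_j) / (1-delta_j) with a_j = s_j/(s_j+tau d_j))
            sxx_sel = sxx_proj[order[:pc]]
            a_orth = sxx_sel / (sxx_sel + tau * d)
            df_sel = (1.0 + gamma) * float(
                (a_orth * (1.0 - a_orth) / (1.0 - delta)).sum())
            df_model = min(float(n), q + ridge_df(XtX_proj[:pc, :pc], tau, d)
                           + df_sel)
            cp = rss + 2.0 * sigma2_hat * df_model
            cand = (cp, cutoff, pc, theta, delta, df_model, rss)
        rows.append((cutoff, pc, df_model, rss if pc else rss0, cp))
        if best is None or cand[0] < best[0] - 1e-12:
            best = cand

    cp_path = pd.DataFrame(rows, columns=["cutoff", "n_selected", "df",
                                          "rss", "cp"])
    cp, cutoff, pc, theta, delta, df_model, rss = best
    if pc == 0:
        warnings.warn("no variants selected at any cutoff; "
                      "returning covariate-only model")
    sel = order[:pc]
    return StmgpModel(
        tau=tau, gamma=gamma, cutoff_grid=cutoff_grid, cp_path=cp_path,
        selected_cutoff=float(cutoff), selected=sel,
        variant_ids=None if ids is None else ids[sel],
        delta=np.asarray(delta), coef_cov=theta[:q], beta_snp=theta[q:],
        sigma2_hat=sigma2_hat, freq=p[sel], gwas=gwas,
    )


def stmgp_predict(model: StmgpModel, G_test, C_test=None) -> np.ndarray:
    """Linear predictor on a test cohort: intercept + covariates + the
    selected standardized variants (training-frequency standardization)."""
    dos, ids = _as_dosages(G_test)
    n = dos.shape[0]
    if model.variant_ids is not None and ids is not None:
        lookup = pd.Index(ids)
        idx = lookup.get_indexer(model.variant_ids)
        if (idx < 0).any():
            missing = model.variant_ids[idx < 0]
            raise KeyError(f"test data lacks model variants: {list(missing[:5])}")
    else:
        if model.selected.size and model.selected.max() >= dos.shape[1]:
            raise KeyError("test dosage matrix lacks model variant columns")
        idx = model.selected
    mu = np.full(n, model.coef_cov[0], dtype=np.float64)
    if model.coef_cov.size > 1:
        Cm = np.asarray(C_test, dtype=np.float64)
        if Cm.ndim == 1:
            Cm = Cm[:, None]
        mu += Cm @ model.coef_cov[1:]
    if len(idx):
        p = np.clip(model.freq, 1e-6, 1 - 1e-6)
        Wt = standardize_dosages(np.ascontiguousarray(dos[:, idx]), p)
        mu += Wt @ model.beta_snp
    return mu
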