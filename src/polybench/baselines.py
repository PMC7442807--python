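"""Comparator predictors: P-value-threshold PRS, GBLUP (AI-REML + BLUP),
SBLUP-style summary-statistic ridge, and ridge regression on clumped markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .assoc import GwasResult, clump, _covariate_basis
from .evaluation import partial_correlation, pcc
from .genotype_io import GenotypeMatrix, MISSING
from .synthetic_data import standardize_dosages

DEFAULT_PRS_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


def _dosages(G):
    if isinstance(G, GenotypeMatrix):
        return G.dosages
    return np.asarray(G)


# ---------------------------------------------------------------------------
# PRS

@dataclass
class PrsModel:
    """Clumped + thresholded polygenic score with per-allele weights."""

    variants: np.ndarray         # column indices of scored variants
    cutoff: float
    betas: np.ndarray            # per-allele (dosage) scale
    variant_ids: np.ndarray | None = None
    a1: np.ndarray | None = None
    grid: pd.DataFrame = field(default_factory=pd.DataFrame)


def prs_fit(gwas: GwasResult, G, y, C=None,
            cutoff_grid=DEFAULT_PRS_GRID, r2_clump: float = 0.1,
            window_kb: float = 250.0) -> PrsModel:
    """Clump, then pick the P cutoff maximizing the training correlation of
    the score with the covariate-adjusted phenotype."""
    dos = _dosages(G)
    n, m = dos.shape
    y = np.asarray(y, dtype=np.float64)
    kept = clump(gwas, G, r2_clump=r2_clump, window_kb=window_kb)
    # per-allele scale: beta_std / sd_j so score = sum beta * dosage
    miss = dos == MISSING
    p = np.where(miss, 0, dos).sum(axis=0) / np.maximum(1, 2 * (n - miss.sum(axis=0)))
    sd = np.sqrt(2.0 * p * (1.0 - p))
    rows = []
    best = None
    X = np.where(miss, (2 * p)[None, :], dos).astype(np.float64)  # mean-imputed
    for cutoff in sorted(cutoff_grid):
        sel = kept[gwas.p[kept] <= cutoff]
        if sel.size == 0:
            rows.append((cutoff, 0, np.nan))
            continue
        w = np.where(sd[sel] > 0, gwas.beta[sel] / sd[sel], 0.0)
        score = X[:, sel] @ w
        if np.ptp(score) == 0:
            rows.append((cutoff, int(sel.size), np.nan))
            continue
        if C is None or np.size(C) == 0:
            r, _ = pcc(score, y)
        else:
            r, _ = partial_correlation(score, y, C)
        rows.append((cutoff, int(sel.size), r))
        if best is None or r > best[0]:
            best = (r, cutoff, sel, w)
    grid = pd.DataFrame(rows, columns=["cutoff", "n_variants", "train_r"])
    if best is None:
        warnings.warn("no variants scored at any cutoff; empty PRS")
        return PrsModel(np.empty(0, dtype=int), float(max(cutoff_grid)),
                        np.empty(0), grid=grid)
    _, cutoff, sel, w = best
    if isinstance(G, GenotypeMatrix):
        ids = G.variants["id"].to_numpy()[sel]
        a1 = G.variants["a1"].to_numpy()[sel]
    else:
        ids = a1 = None
    return PrsModel(sel, float(cutoff), w, variant_ids=ids, a1=a1, grid=grid)


def prs_predict(model: PrsModel, G_test) -> np.ndarray:
    """Score = sum_j beta_j * dosage_ij over the model's variants (missing
    dosages contribute the model-frequency mean, i.e. 0 after centering is
    not applied -- plain allele counting)."""
    dos = _dosages(G_test)
    if model.variants.size == 0:
        return np.zeros(dos.shape[0])
    if isinstance(G_test, GenotypeMatrix) and model.variant_ids is not None:
        lookup = pd.Index(G_test.variants["id"])
        idx = lookup.get_indexer(model.variant_ids)
        if (idx < 0).any():
            raise KeyError("test data lacks PRS variants")
        if model.a1 is not None:
            a1 = G_test.variants["a1"].to_numpy()[idx]
            if (a1 != model.a1).any():
                raise ValueError("counted-allele mismatch between model and test data")
    else:
        idx = model.variants
    X = dos[:, idx].astype(np.float64)
    X[X == MISSING] = 0.0
    return X @ model.betas


# ---------------------------------------------------------------------------
# GRM + GREML + GBLUP

def make_grm(W: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix G = W W' / M over M standardized variants."""
    W = np.asarray(W)
    m = W.shape[1]
    if m == 0:
        raise ValueError("need at least one variant")
    K = (W @ W.T) / m
    return np.asarray((K + K.T) / 2.0, dtype=np.float64)


@dataclass
class VarianceComponents:
    """REML variance components of y = Cb + g + e with g ~ N(0, sigma_g^2 K)."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_g: float
    se_e: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)


def _reml_pieces(par, s, yt, Ct):
    """Quantities for AI-REML in the GRM eigenbasis: V = sg*s + se."""
    sg, se = par
    v = sg * s + se
    vi = 1.0 / v
    CtVi = Ct * vi[:, None]
    CtViC = Ct.T @ CtVi
    CtViy = CtVi.T @ yt
    L = np.linalg.cholesky(CtViC)
    alpha = sla.cho_solve((L, True), CtViy)
    Py = vi * (yt - Ct @ alpha)
    ll = -0.5 * (np.log(v).sum() + 2.0 * np.log(np.diag(L)).sum()
                 + float(yt @ Py))
    return v, vi, Py, CtVi, CtViC, ll


def _trace_PK(k, vi, CtVi, CtViC):
    # tr(P diag(k)) = tr(V^-1 K) - tr((C'V^-1C)^-1 C'V^-1 K V^-1 C)
    t1 = float((vi * k).sum())
    # C'V^-1 K V^-1 C = (CtVi)' diag(k) (CtVi)
    inner = CtVi.T @ (CtVi * k[:, None])
    t2 = float(np.trace(np.linalg.solve(CtViC, inner)))
    return t1 - t2


def greml(y, grm: np.ndarray, C=None, max_iter: int = 200,
          tol: float = 1e-8) -> VarianceComponents:
    """Average-information REML with EM fallback for a single GRM.

    The GRM is eigendecomposed once; every iteration is then O(n).
    Variances are floored at 1e-8 times the phenotypic variance and a
    non-converged run is flagged rather than raised.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    grm = np.asarray(grm, dtype=np.float64)
    s, U = np.linalg.eigh(grm)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError("GRM must be positive semidefinite")
    s = np.clip(s, 0.0, None)
    Q = _covariate_basis(n, C)  # validates rank
    Cm = np.ones((n, 1)) if C is None or np.size(C) == 0 else \
        np.column_stack([np.ones(n), np.asarray(C, dtype=np.float64)])
    yt = U.T @ y
    Ct = U.T @ Cm
    vary = float(y.var())
    floor = 1e-8 * vary
    par = np.array([vary / 2.0, vary / 2.0])
    trace = []
    v = vi = Py = None
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v, vi, Py, CtVi, CtViC, ll = _reml_pieces(par, s, yt, Ct)
        trace.append(ll)
        kg, ke = s, np.ones(n)
        yPKPy = np.array([float(Py @ (kg * Py)), float(Py @ (ke * Py))])
        trPK = np.array([
            _trace_PK(kg, vi, CtVi, CtViC),
            _trace_PK(ke, vi, CtVi, CtViC),
        ])
        grad = 0.5 * (yPKPy - trPK)
        if abs(ll - ll_old) < tol and np.abs(grad).max() < 1e-4:
            converged = True
            break
        ll_old = ll
        # average information matrix
        PKPy = [vi * (kg * Py) - vi * (Ct @ np.linalg.solve(
                    CtViC, CtVi.T @ (kg * Py))),
                vi * (ke * Py) - vi * (Ct @ np.linalg.solve(
                    CtViC, CtVi.T @ (ke * Py)))]
        AI = np.empty((2, 2))
        for a in range(2):
            for b in range(a, 2):
                ka = kg if a == 0 else ke
                AI[a, b] = AI[b, a] = 0.5 * float((ka * Py) @ PKPy[b])
        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            step = None
        accepted = False
        if step is not None:
            cand = par + step
            if (cand > floor).all():
                ll_new = _reml_pieces(cand, s, yt, Ct)[-1]
                if ll_new >= ll - 1e-10:
                    par = cand
                    accepted = True
        if not accepted:
            # EM fallback: monotone, slower
            par = np.maximum(
                par + par**2 * (yPKPy - trPK) / n, floor)
    v, vi, Py, CtVi, CtViC, ll = _reml_pieces(par, s, yt, Ct)
    # SEs from the AI-matrix inverse at the solution
    kg, ke = s, np.ones(n)
    PKPy = [vi * (k * Py) - vi * (Ct @ np.linalg.solve(
                CtViC, CtVi.T @ (k * Py))) for k in (kg, ke)]
    AI = np.empty((2, 2))
    for a, ka in enumerate((kg, ke)):
        for b in range(a, 2):
            AI[a, b] = AI[b, a] = 0.5 * float((ka * Py) @ PKPy[b])
    try:
        cov = np.linalg.inv(AI)
        se_g, se_e = np.sqrt(np.clip(np.diag(cov), 0, None))
        sg, se_ = par
        tot = sg + se_
        gvec = np.array([se_ / tot**2, -sg / tot**2])
        se_h2 = float(np.sqrt(max(0.0, gvec @ cov @ gvec)))
    except np.linalg.LinAlgError:
        se_g = se_e = se_h2 = np.nan
    h2 = float(par[0] / par.sum())
    if not converged:
        warnings.warn("GREML did not converge; result flagged")
    return VarianceComponents(
        sigma_g2=float(par[0]), sigma_e2=float(par[1]), h2=h2,
        se_g=float(se_g), se_e=float(se_e), se_h2=se_h2,
        loglik=float(ll), converged=converged, n_iter=it,
        loglik_trace=trace,
    )


def gblup_predict(vc: VarianceComponents, K_tt: np.ndarray,
                  K_xt: np.ndarray, y_train, C_train=None,
                  C_test=None) -> np.ndarray:
    """BLUP of test genetic values plus the GLS covariate fit.

    g_test = K_xt (K_tt + (se2/sg2) I)^-1 (y - C b),
    with b the GLS estimate under V = sg2 K + se2 I.
    """
    y = np.asarray(y_train, dtype=np.float64)
    n = len(y)
    Cm = np.ones((n, 1)) if C_train is None or np.size(C_train) == 0 else \
        np.column_stack([np.ones(n), np.asarray(C_train, dtype=np.float64)])
    nt = K_xt.shape[0]
    Ct = np.ones((nt, 1)) if C_test is None or np.size(C_test) == 0 else \
        np.column_stack([np.ones(nt), np.asarray(C_test, dtype=np.float64)])
    sg, se = vc.sigma_g2, vc.sigma_e2
    if sg <= 0:
        b = np.linalg.lstsq(Cm, y, rcond=None)[0]
        return Ct @ b
    V = sg * K_tt + se * np.eye(n)
    cf = sla.cho_factor(V, lower=True)
    ViC = sla.cho_solve(cf, Cm)
    Viy = sla.cho_solve(cf, y)
    b = np.linalg.solve(Cm.T @ ViC, Cm.T @ Viy)
    r = y - Cm @ b
    A = K_tt + (se / sg) * np.eye(n)
    alpha = np.linalg.solve(A, r)
    return Ct @ b + K_xt @ alpha


# ---------------------------------------------------------------------------
# SBLUP

def sblup_coefficients(beta_marginal, ld: np.ndarray, n: int, m: int,
                       h2: float) -> np.ndarray:
    """Joint shrunken effects from marginal (standardized-scale) betas and
    an LD correlation matrix: solve (R + m(1-h2)/(n h2) I) beta = beta_m."""
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    R = np.asarray(ld, dtype=np.float64)
    lam = m * (1.0 - h2) / (n * h2)
    A = R + lam * np.eye(R.shape[0])
    return np.linalg.solve(A, np.asarray(beta_marginal, dtype=np.float64))


# ---------------------------------------------------------------------------
# ridge on clumped markers

@dataclass
class RidgeModel:
    penalty: float
    coef_cov: np.ndarray
    beta: np.ndarray
    freq: np.ndarray
    variants: np.ndarray
    gcv_path: pd.DataFrame = field(default_factory=pd.DataFrame)


def ridge_clumped(G, y, C=None, penalty="gcv",
                  penalty_grid: np.ndarray | None = None,
                  variants: np.ndarray | None = None) -> RidgeModel:
    """Standard ridge on standardized (clumped) genotypes with unpenalized
    covariates; the penalty is chosen by generalized cross-validation
    unless given explicitly."""
    dos = _dosages(G)
    if variants is None:
        variants = np.arange(dos.shape[1])
    dos = np.ascontiguousarray(dos[:, variants])
    n, m = dos.shape
    y = np.asarray(y, dtype=np.float64)
    miss = dos == MISSING
    p = np.where(miss, 0, dos).sum(axis=0) / np.maximum(1, 2 * (n - miss.sum(axis=0)))
    p = np.clip(p, 1e-6, 1 - 1e-6)
    X = standardize_dosages(dos, p)
    Q = _covariate_basis(n, C)
    q = Q.shape[1]
    Cm = np.ones((n, 1)) if C is None or np.size(C) == 0 else \
        np.column_stack([np.ones(n), np.asarray(C, dtype=np.float64)])
    # project covariates out, work in the rotated basis
    Xr = X - Q @ (Q.T @ X)
    yr = y - Q @ (Q.T @ y)
    if m <= n:
        U, sv, Vt = np.linalg.svd(Xr, full_matrices=False)
        dual = False
    else:  # dual (kernel) path: eigendecompose the n x n gram instead
        evals, U = np.linalg.eigh(Xr @ Xr.T)
        keep = evals > 1e-10 * max(1.0, evals.max())
        U, sv = U[:, keep], np.sqrt(evals[keep])
        Vt = None
        dual = True
    z = U.T @ yr
    yty = float(yr @ yr)
    if penalty == "gcv":
        if penalty_grid is None:
            base = max(sv.max() ** 2, 1.0)
            penalty_grid = np.geomspace(base * 1e-6, base * 1e3, 40)
        rows = []
        best = None
        for lam in penalty_grid:
            shrink = sv**2 / (sv**2 + lam)
            rss = yty - float((2 * shrink - shrink**2) @ z**2)
            df = q + float(shrink.sum())
            gcv = n * rss / (n - df) ** 2
            rows.append((lam, df, rss, gcv))
            if best is None or gcv < best[0]:
                best = (gcv, lam)
        lam = best[1]
        path = pd.DataFrame(rows, columns=["penalty", "df", "rss", "gcv"])
    else:
        lam = float(penalty)
        path = pd.DataFrame()
    if dual:
        beta = Xr.T @ (U @ (z / (sv**2 + lam)))
    else:
        beta = Vt.T @ (sv / (sv**2 + lam) * z)
    b = np.linalg.lstsq(Cm, y - X @ beta, rcond=None)[0]
    return RidgeModel(penalty=float(lam), coef_cov=b, beta=beta, freq=p,
                      variants=np.asarray(variants), gcv_path=path)


def ridge_predict(model: RidgeModel, G_test, C_test=None) -> np.ndarray:
    dos = _dosages(G_test)
    dos = np.ascontiguousarray(dos[:, model.variants])
    Xt = standardize_dosages(dos, model.freq)
    nt = dos.shape[0]
    Ct = np.ones((nt, 1)) if C_test is None or np.size(C_test) == 0 else \
        np.column_stack([np.ones(nt), np.asarray(C_test, dtype=np.float64)])
    return Ct @ model.coef_cov + Xt @ model.beta
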