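"""Marginal association scan, LD clumping, and GRM-based PCA with
Tracy-Widom component selection -- the shared upstream of the predictors.

The scan fits, per variant j, ordinary least squares of the phenotype on
[1, covariates, w_j] and reports the w_j coefficient on the standardized
scale.  It is computed through the Frisch-Waugh-Lovell identity so the full
variant panel never has to be residualized in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._tw import tw1_sf

_P_FLOOR = 1e-300


@dataclass
class GwasResult:
    """Per-variant marginal statistics (standardized-genotype scale)."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_used: int
    df_resid: int
    covariate_id: str = "none"

    def to_frame(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"BETA": self.beta, "SE": self.se,
                            "T": self.t, "P": self.p})
        if variants is not None:
            out.insert(0, "SNP", variants["id"].to_numpy())
            out.insert(1, "CHR", variants["chrom"].to_numpy())
            out.insert(2, "BP", variants["pos"].to_numpy())
        return out


@dataclass
class PcaResult:
    """Principal-component scores and eigenvalues of the genetic
    relationship matrix, with the count of Tracy-Widom-significant axes."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    n_significant: int

    def __post_init__(self) -> None:
        ev = self.eigenvalues
        if np.any(np.diff(ev) > 1e-8 * max(1.0, abs(ev[0]))):
            raise ValueError("eigenvalues must be nonincreasing")


def _covariate_basis(n: int, C) -> np.ndarray:
    """Orthonormal basis Q for span([1, C]); raises on collinearity."""
    if C is None or (hasattr(C, "size") and np.size(C) == 0):
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        Cm = np.asarray(C, dtype=np.float64)
        if Cm.ndim == 1:
            Cm = Cm[:, None]
        X = np.column_stack([np.ones(n), Cm])
        names = ["intercept"] + [f"c{j}" for j in range(Cm.shape[1])]
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(1.0, diag.max())
    if bad.any():
        raise ValueError(
            "collinear covariate columns: " + ", ".join(np.array(names)[bad]))
    return Q


def gwas_scan(W: np.ndarray, y: np.ndarray, C=None,
              covariate_id: str = "none") -> GwasResult:
    """Marginal least-squares scan of y on each standardized variant,
    adjusting for an intercept and optional covariates."""
    W = np.asarray(W)
    y = np.asarray(y, dtype=np.float64)
    n, m = W.shape
    if len(y) != n:
        raise ValueError("y and W rows must align")
    Q = _covariate_basis(n, C)
    q = Q.shape[1]
    df = n - q - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    y_r = y - Q @ (Q.T @ y)
    yty = float(y_r @ y_r)
    # FWL without materializing the residualized panel:
    # ||w_r||^2 = ||w||^2 - ||Q'w||^2 ;  w_r'y_r = w'y_r
    A = Q.T.astype(W.dtype) @ W            # (q, m)
    sxx = np.einsum("ij,ij->j", W, W, dtype=np.float64)
    sxx -= np.einsum("ij,ij->j", A, A, dtype=np.float64)
    sxy = W.T @ y_r.astype(W.dtype)
    sxy = sxy.astype(np.float64)
    sxx = np.maximum(sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, 0.0)
        rss = np.maximum(yty - beta * sxy, 0.0)
        se = np.sqrt(rss / df / np.where(sxx > 0, sxx, np.inf))
        # a perfect fit (rss = 0) has se = 0: report an infinite statistic
        t = np.where(se > 0, beta / se,
                     np.where(beta != 0, np.inf * np.sign(beta), 0.0))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _P_FLOOR, 1.0)
    return GwasResult(beta=beta, se=se, t=t, p=p, n_used=n, df_resid=df,
                      covariate_id=covariate_id)


def clump(gwas: GwasResult, G, r2_clump: float = 0.1,
          window_kb: float = 250.0) -> np.ndarray:
    """Greedy LD clumping: take the most significant remaining variant,
    drop all variants within the window at r^2 >= r2_clump with it.

    ``G`` is a GenotypeMatrix (positions from its variant table) or a bare
    dosage array (positions then fall back to the column index in kb units
    times zero -- i.e. everything shares one window).
    Ties in P are broken by genomic position, then column order.
    """
    if hasattr(G, "dosages"):
        d = G.dosages
        pos = G.variants["pos"].to_numpy()
        chrom = G.variants["chrom"].to_numpy()
    else:
        d = np.asarray(G)
        pos = np.zeros(d.shape[1], dtype=np.int64)
        chrom = np.zeros(d.shape[1], dtype="U1")
    m = d.shape[1]
    order = np.lexsort((np.arange(m), pos, gwas.p))
    alive = np.ones(m, dtype=bool)
    kept: list[int] = []
    window = window_kb * 1000.0
    X = d.astype(np.float32)
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = np.inf
    X /= norms
    for j in order:
        if not alive[j]:
            continue
        kept.append(int(j))
        alive[j] = False
        near = alive & (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window)
        idx = np.flatnonzero(near)
        if idx.size:
            r2 = (X[:, idx].T @ X[:, j]) ** 2
            alive[idx[r2 >= r2_clump]] = False
    return np.sort(np.array(kept, dtype=np.int64))


def pca(W: np.ndarray, n_components: int | None = None,
        alpha: float = 0.05) -> PcaResult:
    """PCA of the genetic relationship matrix K = W W'/m over all samples.

    Scores are eigenvector coordinates scaled by sqrt(eigenvalue); the
    number of Tracy-Widom-significant components is evaluated at ``alpha``.
    """
    W = np.asarray(W, dtype=np.float64)
    n, m = W.shape
    if n_components is None:
        n_components = min(n, m)
    if n_components > min(n, m):
        raise ValueError("n_components exceeds matrix rank bound")
    K = (W @ W.T) / m
    if not np.all(np.isfinite(K)):
        raise ValueError("degenerate (non-finite) genotype matrix")
    evals, evecs = np.linalg.eigh(K)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    evals_c = np.clip(evals, 0.0, None)
    scores = evecs[:, :n_components] * np.sqrt(evals_c[:n_components])
    n_sig = tracy_widom_select(evals, n, m, alpha=alpha)
    return PcaResult(scores=scores, eigenvalues=evals, n_significant=n_sig)


def tracy_widom_select(eigenvalues: np.ndarray, n_samples: int,
                       n_variants: int, alpha: float = 0.05) -> int:
    """Sequential Tracy-Widom test for the number of significant axes of
    variation (Patterson-style).

    Each leading eigenvalue is standardized using the effective marker
    count estimated from the remaining spectrum and compared with the
    TW(beta=1) law; testing stops at the first non-significant component.
    """
    ev = np.asarray(eigenvalues, dtype=np.float64)
    if np.any(np.diff(ev) > 1e-8 * max(1.0, abs(ev[0]))):
        raise ValueError("eigenvalues must be descending")
    if alpha <= 0:
        return 0
    ev = ev[ev > 1e-12]  # drop null directions (rank deficiency)
    n_sig = 0
    for i in range(len(ev) - 2):
        rest = ev[i:]
        r = len(rest)
        s1 = rest.sum()
        # effective marker count from the Wishart second moment
        # E[sum lam^2] = r (r + n + 1)/n on the mean-1 normalized spectrum
        lam = rest * (r / s1)
        s2 = (lam**2).sum()
        if s2 <= r:
            break
        n_eff = r * (r + 1) / (s2 - r)
        if n_eff <= 1:
            break
        a, b = np.sqrt(n_eff - 1), np.sqrt(r)
        mu = (a + b) ** 2 / n_eff
        sigma = (a + b) * (1.0 / a + 1.0 / b) ** (1.0 / 3.0) / n_eff
        x = (lam[0] - mu) / sigma
        if tw1_sf(x) < alpha:
            n_sig += 1
        else:
            break
    return n_sig
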