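"""Simulation of genotypes, effect sizes, covariates and heritable phenotypes.

The generator emulates a two-cohort SNP-array study: biallelic variants in
Hardy-Weinberg proportions with uniform minor-allele frequencies, a sparse
set of causal variants in approximate linkage equilibrium (pairwise
r^2 < 0.05), i.i.d. unit-variance allelic effects from a normal, Laplace or
normal-exponential-gamma (NEG) family, and an additive phenotype

    y_j = sum_i w_ij b_i + e_j,    w_ij = (x_ij - 2 p_i) / sqrt(2 p_i (1 - p_i))

whose residual variance is tied to the realized genetic variance through the
nominal heritability:  var(e) = var(g) * (1/h2 - 1).

All randomness flows from one root seed through named substreams so any
replicate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_plink

_STREAMS = {"maf": 0, "genotypes": 1, "causal": 2, "effects": 3,
            "residuals": 4, "covariates": 5}


def substream(seed: int, *key) -> np.random.Generator:
    """Independent generator for a named substream of a root seed.

    ``key`` is a sequence of small ints and/or stream names from
    ``_STREAMS`` (e.g. ``substream(seed, rep, "effects")``).
    """
    ints = tuple(_STREAMS[k] if isinstance(k, str) else int(k) for k in key)
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=int(seed), spawn_key=ints)))


@dataclass
class SimulationConfig:
    """Study conditions for one simulation scenario.

    Defaults are the benchmark's reference conditions: the two-cohort sample
    sizes (3685 training / 3048 test), a 20000-variant desk-scale marker
    panel, 100 Laplace-distributed causal variants in linkage equilibrium
    and heritability 0.10, with 20 replicates.
    """

    n_train: int = 3685
    n_test: int = 3048
    m: int = 20000
    maf_low: float = 0.01
    maf_high: float = 0.5
    k: int = 100
    effect_dist: str = "laplace"   # normal | laplace | neg
    neg_shape: float = 3.0
    h2: float = 0.10
    r2_max: float = 0.05
    n_reps: int = 20
    seed: int = 2020

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0,1)")
        if self.k > self.m:
            raise ValueError("k cannot exceed m")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.effect_dist not in ("normal", "laplace", "neg"):
            raise ValueError(f"unknown effect distribution {self.effect_dist!r}")

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


@dataclass
class EffectVector:
    """Causal variant indices and their allelic effects b_i."""

    causal: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.causal) != len(self.b):
            raise ValueError("causal indices and effects must align")


@dataclass
class SimulatedPhenotype:
    """Phenotype with its genetic and residual components."""

    y: np.ndarray
    g: np.ndarray
    e: np.ndarray
    realized_h2: float

    def __post_init__(self) -> None:
        if not np.allclose(self.y, self.g + self.e):
            raise ValueError("y must equal g + e")


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(n: int, m: int, maf_low: float = 0.01,
                       maf_high: float = 0.5, seed=0, *, rng=None,
                       maf_rng=None, out: np.ndarray | None = None,
                       chunk: int = 512) -> GenotypeMatrix:
    """HWE genotypes: per-variant MAF uniform in [maf_low, maf_high],
    dosages Binomial(2, p) per sample, no missingness.

    Two uniform-variate comparisons per genotype realize the Binomial(2, p)
    draw; generation is chunked into ``out`` (reusable across calls) to keep
    the peak allocation small.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("invalid MAF bounds")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(seed))
    if maf_rng is None:
        maf_rng = rng
    p = maf_rng.uniform(maf_low, maf_high, size=m).astype(np.float32)
    if out is None:
        out = np.empty((n, m), dtype=np.int8)
    elif out.shape != (n, m) or out.dtype != np.int8:
        raise ValueError("out must be int8 with shape (n, m)")
    buf = np.empty((min(chunk, n), m), dtype=np.float32)
    tmp = np.empty((min(chunk, n), m), dtype=np.bool_)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        b, t = buf[: hi - lo], tmp[: hi - lo]
        rng.random(out=b, dtype=np.float32)
        np.less(b, p, out=t)
        out[lo:hi] = t
        rng.random(out=b, dtype=np.float32)
        np.less(b, p, out=t)
        out[lo:hi] += t
    variants = pd.DataFrame({
        "id": [f"snp{i}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(m, dtype=np.int64) * 5000 + 1,
        "a1": "A", "a2": "G",
        "maf_true": p.astype(np.float64),
    })
    samples = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
        "sex": 0,
    })
    return GenotypeMatrix(out, variants, samples)


def standardize_dosages(dosages: np.ndarray, p: np.ndarray,
                        out: np.ndarray | None = None,
                        dtype=np.float64, chunk: int = 512) -> np.ndarray:
    """w = (x - 2p) / sqrt(2p(1-p)); missing entries contribute 0."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic variant: standardization undefined")
    n, m = dosages.shape
    if out is None:
        out = np.empty((n, m), dtype=dtype)
    center = (2.0 * p).astype(out.dtype)
    scale = np.sqrt(2.0 * p * (1.0 - p)).astype(out.dtype)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        blk = out[lo:hi]
        blk[...] = dosages[lo:hi]
        miss = dosages[lo:hi] == MISSING
        blk -= center
        blk /= scale
        blk[miss] = 0.0  # mean imputation on the standardized scale
    return out


def standardize(G: GenotypeMatrix, dtype=np.float64,
                out: np.ndarray | None = None) -> np.ndarray:
    """Standardized genotype matrix W from observed allele frequencies."""
    return standardize_dosages(G.dosages, G.allele_freq(), out=out, dtype=dtype)


# ---------------------------------------------------------------------------
# effects

def sample_effects(k: int, dist: str = "laplace", neg_shape: float | None = None,
                   seed=0, *, rng=None) -> np.ndarray:
    """i.i.d. allelic effects with mean 0 and variance 1.

    normal: N(0,1).  laplace: scale 1/sqrt(2).  neg: Laplace with a
    gamma-distributed rate -- lambda^2 ~ Gamma(shape, scale=2/(shape-1)),
    b | lambda ~ Laplace(0, 1/lambda), which pins the compound variance
    E[2/lambda^2] at exactly 1 and requires shape > 1.  Large shapes
    collapse the rate distribution and recover the Laplace family.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(seed))
    if dist == "normal":
        return rng.standard_normal(k)
    if dist == "laplace":
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=k)
    if dist == "neg":
        if neg_shape is None or neg_shape <= 1.0:
            raise ValueError("neg requires shape > 1 for finite variance")
        lam2 = rng.gamma(neg_shape, scale=2.0 / (neg_shape - 1.0), size=k)
        return rng.laplace(0.0, 1.0 / np.sqrt(lam2), size=k)
    raise ValueError(f"unknown effect distribution {dist!r}")


# ---------------------------------------------------------------------------
# causal set

def select_causal(dosages: np.ndarray, k: int, r2_max: float = 0.05,
                  seed=0, *, rng=None) -> np.ndarray:
    """Random scan accepting variants pairwise in approximate linkage
    equilibrium (squared dosage correlation < r2_max) until k are found."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(seed))
    if hasattr(dosages, "dosages"):
        dosages = dosages.dosages
    n, m = dosages.shape
    if k > m:
        raise ValueError("k cannot exceed m")
    order = rng.permutation(m)
    accepted: list[int] = []
    Z = np.empty((k, n))  # centred, unit-norm accepted columns
    for j in order:
        col = dosages[:, j].astype(np.float64)
        col -= col.mean()
        nrm = np.linalg.norm(col)
        if nrm == 0:
            continue
        col /= nrm
        if accepted:
            r2 = (Z[: len(accepted)] @ col) ** 2
            if r2.max() >= r2_max:
                continue
        Z[len(accepted)] = col
        accepted.append(int(j))
        if len(accepted) == k:
            return np.sort(np.array(accepted))
    raise RuntimeError(
        f"could not find {k} variants at pairwise r^2 < {r2_max}; "
        f"achieved {len(accepted)}")


# ---------------------------------------------------------------------------
# phenotype

def simulate_phenotype(W: np.ndarray, causal: np.ndarray, b: np.ndarray,
                       h2: float, seed=0, *, rng=None) -> SimulatedPhenotype:
    """Additive phenotype over all individuals with the residual-variance
    rule var(e) = var(g) * (1/h2 - 1), var(g) taken empirically."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0,1]")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(seed))
    g = W[:, np.asarray(causal)].astype(np.float64) @ np.asarray(b, dtype=np.float64)
    var_g = float(g.var())
    if var_g == 0.0 and h2 < 1.0:
        raise ValueError("genetic component has zero variance")
    if h2 == 1.0:
        e = np.zeros_like(g)
    else:
        e = rng.normal(0.0, np.sqrt(var_g * (1.0 / h2 - 1.0)), size=g.shape)
    y = g + e
    return SimulatedPhenotype(y=y, g=g, e=e, realized_h2=var_g / float(y.var()))


# ---------------------------------------------------------------------------
# covariates

def simulate_covariates(n: int, seed=0, *, rng=None,
                        age_range=(40, 80), sex_prob=0.65) -> pd.DataFrame:
    """Cohort-style covariates: integer age uniform in ``age_range`` and a
    Bernoulli sex indicator (1 = female)."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(seed))
    return pd.DataFrame({
        "age": rng.integers(age_range[0], age_range[1] + 1, size=n),
        "sex": (rng.random(n) < sex_prob).astype(int),
    })


def add_covariate_effects(y: np.ndarray, C: pd.DataFrame | np.ndarray,
                          coefs) -> np.ndarray:
    """y + C @ coefs (zero coefficients leave y untouched)."""
    Cm = np.asarray(C, dtype=np.float64)
    return np.asarray(y, dtype=np.float64) + Cm @ np.asarray(coefs, dtype=np.float64)


# ---------------------------------------------------------------------------
# full replicate + disk emission

@dataclass
class Replicate:
    """One simulated replicate: combined-cohort genotypes, causal truth and
    phenotype, plus the train/test split."""

    genotypes: GenotypeMatrix
    effects: EffectVector
    phenotype: SimulatedPhenotype
    n_train: int

    @property
    def train(self) -> slice:
        return slice(0, self.n_train)

    @property
    def test(self) -> slice:
        return slice(self.n_train, self.genotypes.n_samples)


def simulate_replicate(cfg: SimulationConfig, rep: int = 0, *,
                       genotype_out: np.ndarray | None = None,
                       W_scratch: np.ndarray | None = None) -> Replicate:
    """Generate one replicate of the study: genotypes for train+test jointly,
    a causal set in linkage equilibrium, effects, and the phenotype simulated
    across all individuals (then split).

    ``genotype_out`` optionally receives the dosage matrix (reusable buffer).
    """
    n = cfg.n_total
    G = simulate_genotypes(
        n, cfg.m, cfg.maf_low, cfg.maf_high,
        rng=substream(cfg.seed, rep, "genotypes"),
        maf_rng=substream(cfg.seed, rep, "maf"),
        out=genotype_out,
    )
    causal = select_causal(G.dosages, cfg.k, cfg.r2_max,
                           rng=substream(cfg.seed, rep, "causal"))
    b = sample_effects(cfg.k, cfg.effect_dist, cfg.neg_shape,
                       rng=substream(cfg.seed, rep, "effects"))
    dc = np.ascontiguousarray(G.dosages[:, causal])
    miss = dc == -1
    p = np.where(miss, 0, dc).sum(axis=0) / (2.0 * (n - miss.sum(axis=0)))
    Wc = standardize_dosages(dc, p)
    pheno = simulate_phenotype(Wc, np.arange(cfg.k), b, cfg.h2,
                               rng=substream(cfg.seed, rep, "residuals"))
    return Replicate(G, EffectVector(causal, b), pheno, cfg.n_train)


def write_dataset(rep: Replicate, outdir, prefix: str = "sim") -> dict:
    """Emit a replicate as PLINK1 triplets plus phenotype and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = outdir / prefix
    write_plink(rep.genotypes, base)
    s = rep.genotypes.samples
    pheno = pd.DataFrame({"FID": s["fid"], "IID": s["iid"],
                          "PHENO": rep.phenotype.y})
    pheno.to_csv(f"{base}.pheno.tsv", sep="\t", index=False)
    split = pd.DataFrame({"FID": s["fid"], "IID": s["iid"],
                          "SET": ["train"] * rep.n_train
                                 + ["test"] * (len(s) - rep.n_train)})
    split.to_csv(f"{base}.split.tsv", sep="\t", index=False)
    truth = pd.DataFrame({
        "id": rep.genotypes.variants["id"].iloc[rep.effects.causal].to_numpy(),
        "b": rep.effects.b,
    })
    truth["realized_h2"] = rep.phenotype.realized_h2
    truth.to_csv(f"{base}.truth.tsv", sep="\t", index=False)
    return {"bed": f"{base}.bed", "pheno": f"{base}.pheno.tsv",
            "truth": f"{base}.truth.tsv"}
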