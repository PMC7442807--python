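"""PLINK1 binary genotype I/O and cohort-style quality control.

Genotypes are held as counted-allele dosages (0/1/2) of allele1 of the
.bim record, with ``-1`` marking a missing call.  QC mirrors standard
array-cohort practice: sample call rate, variant call rate, Hardy-Weinberg
exact test, minor-allele frequency, and method-of-moments identity-by-descent
pruning of close relatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1

# 2-bit PLINK1 codes -> dosage of allele1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_ENCODE = {2: 0, MISSING: 1, 1: 2, 0: 3}

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK1 binary files."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant and sample metadata.

    Parameters
    ----------
    dosages : int8 array, shape (n_samples, n_variants)
        Counted-allele dosages in {0, 1, 2}; ``-1`` is missing.
    variants : DataFrame with columns id, chrom, pos, a1, a2
    samples : DataFrame with columns fid, iid, sex
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError("metadata rows do not match dosage shape")
        if self.dosages.size and not (
            self.dosages.min() >= MISSING and self.dosages.max() <= 2
        ):  # int8 in [-1, 2] <=> {0,1,2} or missing
            raise ValueError("dosages must be in {0,1,2} or missing (-1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency p_i of the counted allele, missing calls excluded."""
        d = self.dosages
        miss = d == MISSING
        cnt = d.shape[0] - miss.sum(axis=0)
        tot = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / (2.0 * cnt), np.nan)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - (self.dosages == MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - (self.dosages == MISSING).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """Per-variant (hom-counted, het, hom-other) counts, shape (m, 3)."""
        d = self.dosages
        return np.stack(
            [(d == 2).sum(axis=0), (d == 1).sum(axis=0), (d == 0).sum(axis=0)],
            axis=1,
        )

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            self.dosages[np.ix_(si, vi)],
            self.variants.iloc[vi].reset_index(drop=True),
            self.samples.iloc[si].reset_index(drop=True),
        )


@dataclass
class QcReport:
    """Record of removed samples/variants with reasons and before/after counts."""

    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["fid", "iid", "reason"])
    )
    removed_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )
    relatedness_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iid1", "iid2", "pi_hat"])
    )
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_variants_before: int = 0
    n_variants_after: int = 0

    def validate(self) -> None:
        assert self.n_samples_before - len(self.removed_samples) == self.n_samples_after
        assert self.n_variants_before - len(self.removed_variants) == self.n_variants_after

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        self.removed_samples.to_csv(f"{prefix}.removed_samples.tsv", sep="\t", index=False)
        self.removed_variants.to_csv(f"{prefix}.removed_variants.tsv", sep="\t", index=False)
        self.relatedness_pairs.to_csv(f"{prefix}.relatedness.tsv", sep="\t", index=False)
        summary = {
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "n_variants_before": self.n_variants_before,
            "n_variants_after": self.n_variants_after,
            "n_samples_removed": int(len(self.removed_samples)),
            "n_variants_removed": int(len(self.removed_variants)),
        }
        Path(f"{prefix}.qc.json").write_text(json.dumps(summary, indent=1))


# ---------------------------------------------------------------------------
# PLINK1 binary triplet

def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK1 .bed/.bim/.fam triplet (SNP-major) into a GenotypeMatrix."""
    prefix = Path(prefix)
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    variants = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    samples = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(samples), len(variants)
    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed}: unsupported mode byte {raw[2:3]!r} (only SNP-major 0x01)"
        )
    bpr = (n + 3) // 4  # bytes per variant row, samples padded to a byte
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bpr:
        raise PlinkFormatError(
            f"{bed}: expected {m * bpr} data bytes for {n} samples x {m} variants, "
            f"got {body.size}"
        )
    rows = body.reshape(m, bpr)
    # little-endian within each byte: sample 0 in bits 0-1
    codes = np.empty((m, bpr * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (rows >> (2 * shift)) & 0b11
    dosages = _DECODE[codes[:, :n]].T.copy()  # (n, m)
    return GenotypeMatrix(dosages, variants[["id", "chrom", "pos", "a1", "a2"]].copy(), samples[["fid", "iid", "sex"]].copy())


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK1 SNP-major .bed/.bim/.fam triplet."""
    if G.variants["id"].duplicated().any():
        dup = G.variants["id"][G.variants["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate variant id {dup!r}")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_samples, G.n_variants
    bpr = (n + 3) // 4
    codes = np.zeros((m, bpr * 4), dtype=np.uint8)  # pad bits = 0b00
    d = G.dosages.T  # (m, n)
    lut = np.zeros(4, dtype=np.uint8)
    for dos, code in _ENCODE.items():
        lut[dos % 4] = code  # -1 -> index 3
    codes[:, :n] = lut[d % 4]
    packed = np.zeros((m, bpr), dtype=np.uint8)
    for shift in range(4):
        packed |= codes[:, shift::4] << (2 * shift)
    # padding codes must read as hom-A2 (0b00 already encodes dosage 2 of A1;
    # pad columns beyond n are never decoded, any value is acceptable)
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())
    v = G.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
        "a1": v["a1"], "a2": v["a2"],
    })
    bim.to_csv(str(prefix) + ".bim", sep="\t", header=False, index=False)
    s = G.samples
    fam = pd.DataFrame({
        "fid": s["fid"], "iid": s["iid"], "pat": 0, "mat": 0,
        "sex": s.get("sex", 0), "pheno": -9,
    })
    fam.to_csv(str(prefix) + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact P (Wigginton/PLINK convention).

    Sums the probabilities of all heterozygote counts whose conditional
    probability (given allele counts) does not exceed that of the observed
    count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_Aa  # one allele's count
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    # log P(het = h | n, rare) up to a constant, h with parity of rare
    hs = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hs) // 2
    hom_c = n - hs - hom_r
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hs + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_Aa
    if obs not in hs:
        raise ValueError("heterozygote count incompatible with allele count parity")
    p_obs = probs[np.searchsorted(hs, obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filters

def variant_qc(G: GenotypeMatrix, call_min: float = 0.99, hwe_min: float = 1e-4,
               maf_min: float = 0.01):
    """Remove variants with call rate < call_min, HWE exact P < hwe_min or
    MAF < maf_min.  Returns (filtered GenotypeMatrix, QcReport)."""
    for thr in (call_min, hwe_min, maf_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must be in [0,1]")
    cr = G.variant_call_rate()
    p = G.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    counts = G.genotype_counts()
    hwe = np.array([hwe_exact_p(*c) if c.sum() > 0 else 1.0 for c in counts])
    reasons = []
    for j in range(G.n_variants):
        why = []
        if cr[j] < call_min:
            why.append("call_rate")
        if hwe[j] < hwe_min:
            why.append("hwe")
        if np.isnan(maf[j]) or maf[j] < maf_min:
            why.append("maf")
        if why:
            reasons.append((G.variants["id"].iloc[j], "+".join(why)))
    removed = pd.DataFrame(reasons, columns=["id", "reason"])
    keep = ~G.variants["id"].isin(removed["id"]).to_numpy()
    out = G.subset(variant_idx=np.flatnonzero(keep))
    report = QcReport(
        removed_variants=removed,
        n_samples_before=G.n_samples, n_samples_after=G.n_samples,
        n_variants_before=G.n_variants, n_variants_after=out.n_variants,
    )
    report.validate()
    return out, report


def sample_qc(G: GenotypeMatrix, call_min: float = 0.98):
    """Remove samples with call rate < call_min (strict, matching the
    cohort-QC convention)."""
    if not 0.0 <= call_min <= 1.0:
        raise ValueError("call_min must be in [0,1]")
    cr = G.sample_call_rate()
    bad = np.flatnonzero(cr < call_min)
    removed = pd.DataFrame({
        "fid": G.samples["fid"].iloc[bad].to_numpy(),
        "iid": G.samples["iid"].iloc[bad].to_numpy(),
        "reason": "call_rate",
    })
    keep = np.setdiff1d(np.arange(G.n_samples), bad)
    out = G.subset(sample_idx=keep)
    report = QcReport(
        removed_samples=removed,
        n_samples_before=G.n_samples, n_samples_after=out.n_samples,
        n_variants_before=G.n_variants, n_variants_after=G.n_variants,
    )
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# Identity-by-descent relatedness pruning

def ibd_estimates(G: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments PI_HAT for every sample pair.

    Observed identity-by-state counts are compared with their expectations
    given allele frequencies to estimate P(IBD=0/1/2);
    PI_HAT = P(IBD=2) + P(IBD=1)/2.  Pairwise expectations are scaled by the
    pair's shared non-missing variant fraction.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples for IBD estimation")
    d = G.dosages
    p = G.allele_freq()
    miss = d == MISSING
    n_obs = d.shape[0] - miss.sum(axis=0)
    ok = np.isfinite(p) & (p > 0) & (p < 1) & (n_obs >= 2)
    d = d[:, ok]
    # per-variant IBS-class expectations under each IBD state, using
    # without-replacement allele draws from the observed pool (unbiased for
    # the plug-in p^2 q^2 terms, which otherwise inflate for rare alleles)
    a = np.where(miss[:, ok], 0, d).sum(axis=0, dtype=np.float64)
    T = 2.0 * n_obs[ok]
    b = T - a
    den4 = T * (T - 1) * (T - 2) * (T - 3)
    e0_ibs0 = 2 * a * (a - 1) * b * (b - 1) / den4
    e0_ibs1 = 4 * (a * (a - 1) * (a - 2) * b + a * b * (b - 1) * (b - 2)) / den4
    e1_ibs1 = 2 * a * b / (T * (T - 1))
    e1_ibs2 = 1.0 - e1_ibs1
    S = {
        "e0_ibs0": e0_ibs0.sum(), "e0_ibs1": e0_ibs1.sum(),
        "e0_ibs2": (1 - e0_ibs0 - e0_ibs1).sum(),
        "e1_ibs1": e1_ibs1.sum(), "e1_ibs2": e1_ibs2.sum(),
    }
    m = d.shape[1]
    nonmiss = (d != MISSING)
    A = [np.asarray((d == g) & nonmiss, dtype=np.float32) for g in (0, 1, 2)]
    n_shared = np.asarray(nonmiss, dtype=np.float32) @ np.asarray(nonmiss, dtype=np.float32).T
    ibs2 = sum(a @ a.T for a in A)
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    ibs1 = n_shared - ibs2 - ibs0
    rows = []
    n = G.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            mp = n_shared[i, j]  # shared non-missing variant count
            if mp == 0:
                continue
            frac = mp / m
            # solve the moment equations top-down: IBS0 only under IBD=0,
            # IBS1 under IBD<=1, IBS2 certain under IBD=2
            p0 = ibs0[i, j] / (S["e0_ibs0"] * frac)
            p1 = (ibs1[i, j] - p0 * S["e0_ibs1"] * frac) / (S["e1_ibs1"] * frac)
            p2 = (ibs2[i, j] - p0 * S["e0_ibs2"] * frac
                  - p1 * S["e1_ibs2"] * frac) / mp
            # clamp to the probability simplex
            p0, p1, p2 = (max(0.0, v) for v in (p0, p1, p2))
            tot = p0 + p1 + p2
            if tot > 0:
                p0, p1, p2 = p0 / tot, p1 / tot, p2 / tot
            rows.append((i, j, p0, p1, p2, p2 + 0.5 * p1))
    return pd.DataFrame(rows, columns=["i", "j", "z0", "z1", "z2", "pi_hat"])


def ibd_prune(G: GenotypeMatrix, pihat_max: float = 0.09375):
    """Drop one member of each pair with PI_HAT > pihat_max.

    The member with the lower call rate is dropped; on ties the
    later-ordered sample goes (deterministic).
    Returns (retained sample indices, DataFrame of flagged pairs).
    """
    est = ibd_estimates(G)
    flagged = est[est["pi_hat"] > pihat_max].reset_index(drop=True)
    cr = G.sample_call_rate()
    dropped: set[int] = set()
    for _, row in flagged.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if i in dropped or j in dropped:
            continue
        dropped.add(j if cr[j] <= cr[i] else i)
    retained = np.array([k for k in range(G.n_samples) if k not in dropped])
    return retained, flagged
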