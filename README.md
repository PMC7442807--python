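# polybench

Benchmarking machinery for **smooth-threshold multivariate genetic
prediction (STMGP)** of quantitative polygenic traits, with the standard
comparators — P-value-threshold polygenic risk scores (PRS), GBLUP
(REML + BLUP), SBLUP-style summary-statistic ridge, and ridge regression on
clumped markers — evaluated on heritability-controlled simulated GWAS
phenotypes.

## Who this is for

Statistical geneticists who want to compare genomic predictors under
controlled genetic architectures: a known number *k* of causal variants in
linkage equilibrium, a chosen effect-size law (normal, Laplace, or
normal–exponential–gamma), and a fixed SNP heritability *h²*.  The package
covers the whole loop — PLINK1 genotype I/O and QC, phenotype simulation,
model fitting, and the evaluation statistics (predictive/partial
correlations, Williams' test for dependent correlations, calibration
slopes, replicate power).

## The model

Phenotypes follow the additive standardized-genotype model

```
y_j = Σᵢ w_ij b_i + e_j ,   w_ij = (x_ij − 2p_i) / sqrt(2 p_i (1 − p_i))
```

with i.i.d. unit-variance allelic effects `b_i` and residual variance tied
to the realized genetic variance, `var(e) = var(g)·(1/h² − 1)`, so the
realized heritability concentrates at the nominal *h²*.

STMGP builds its predictor in four stages on the training cohort only:

1. a marginal GWAS scan of `y` on each `w_j` (covariates adjusted);
2. for a candidate P-value cutoff, variants with `P ≤ cutoff` are kept and
   assigned a smooth-threshold weight `δ_j = (λ/|t_j|)^(1+γ) ∈ [0,1)`
   (λ = the |t| at the cutoff), so weak associations are *continuously*
   down-weighted instead of hard-thresholded;
3. generalized ridge regression with per-variant penalties
   `τ·δ_j/(1−δ_j)` (covariates unpenalized), `τ = N/√log N` by default and
   `γ = 1`, the adaptive-lasso convention;
4. Mallows' Cp — residual sum of squares plus `2σ̂²·df`, where `df` counts
   both the ridge smoother trace and the divergence of the data-dependent
   weights — picks the cutoff, and the chosen model scores the held-out
   cohort using *training* allele frequencies.

The point of the construction is resistance to overfitting: the apparent
(training) accuracy of STMGP stays close to its held-out accuracy while
dense predictors collapse out of sample.

## Worked example

```python
from polybench.synthetic_data import SimulationConfig
from polybench.pipeline import run_scenario, summarize

cfg = SimulationConfig(n_train=300, n_test=200, m=500, k=20,
                       h2=0.3, n_reps=5, seed=7)
df = run_scenario(cfg, methods=("stmgp", "prs", "gblup", "sblup", "ridge"))
print(summarize(df).to_string(index=False))
```

prints

```
        scenario method  n_reps  mean_pcc   sd_pcc  power  mean_train_pcc  mean_gap
k20_laplace_h0.3  gblup       5  0.243968 0.043134    1.0        0.847384  0.603416
k20_laplace_h0.3    prs       5  0.241687 0.044339    1.0        0.805138  0.563451
k20_laplace_h0.3  ridge       5  0.244464 0.043599    1.0        0.844323  0.599859
k20_laplace_h0.3  sblup       5  0.238286 0.039884    1.0        0.847107  0.608820
k20_laplace_h0.3  stmgp       5  0.447636 0.051636    1.0        0.538199  0.090563
```

`mean_pcc` is the mean Pearson correlation between predictions and the
held-out phenotype across replicates, `power` the share of replicates
significant at P < 0.05, and `mean_gap` the training-minus-test correlation
gap (overfitting).  STMGP nearly doubles the held-out accuracy of the dense
predictors here while its overfitting gap (0.09) is an order of magnitude
below theirs (~0.6) — the expected signature of screening plus adaptive
shrinkage under a sparse Laplace architecture.

A thin CLI wraps the same machinery:

```bash
polybench simulate --out data/ --n-train 500 --n-test 500 --m 2000 --k 100
polybench fit stmgp --bfile data/sim --pheno data/sim.pheno.tsv --out model
polybench run --config bench.yaml
```

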