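# Methods

## Scope

`polybench` implements a simulation benchmark for genomic prediction of
quantitative traits.  It has seven parts: PLINK1 genotype I/O with
cohort-style QC (`genotype_io`), a phenotype/genotype simulator
(`synthetic_data`), the shared association layer — GWAS scan, LD clumping,
GRM PCA with Tracy–Widom component selection (`assoc`) — the
smooth-threshold generalized-ridge predictor (`stmgp`), the comparator
predictors (`baselines`), the evaluation statistics (`evaluation`), and the
orchestration layer (`pipeline`).

## The simulator

Genotypes are biallelic SNPs in Hardy–Weinberg proportions: each variant
draws a minor-allele frequency uniformly on [0.01, 0.5] and each sample
draws a Binomial(2, p) dosage.  Internally the Binomial(2, p) draw is
realized as two uniform-variate comparisons, which is the same law but lets
generation stream through a small reusable buffer; the pipeline reuses one
dosage buffer and one standardization buffer across replicates, which keeps
the peak memory near the size of a single replicate.

Phenotypes follow `y = Σ w_ij b_i + e_j` on the standardized-dosage scale.
Causal variants are chosen by a random scan that accepts a variant only if
its squared dosage correlation with every already-accepted variant is
below 0.05 (approximate linkage equilibrium), computed on the combined
train+test sample.  Effects are i.i.d. with mean 0 and variance 1:

* **normal** — N(0, 1);
* **laplace** — scale 1/√2;
* **neg** (normal–exponential–gamma) — a Laplace with gamma-distributed
  rate: λ² ~ Gamma(shape θ, scale 2/(θ−1)) and b | λ ~ Laplace(0, 1/λ).
  The scale of the gamma law is pinned analytically by the unit-variance
  requirement E[2/λ²] = 1, which also forces θ > 1.  Small θ thickens the
  tails; θ → ∞ recovers the Laplace family.

The residual is normal with variance `var(g)·(1/h² − 1)`, where `var(g)` is
the *empirical* variance of the genetic score over all simulated
individuals.  This makes the realized heritability `var(g)/var(y)`
concentrate tightly at the nominal h², which the tests verify at h² = 0.10
over 20 replicates.  Phenotypes are generated across training and test
cohorts jointly and split afterwards; everything a fitted model sees is
training data only (standardization at prediction time uses training
allele frequencies).

Default conditions are the benchmark's reference study: 3685 training and
3048 test samples, a 20 000-marker panel (a desk-scale reduction of a
~615 k array panel — fewer null markers can only ease variant selection,
so full-panel accuracies act as lower bounds), k ∈ {100, 200, 500, 2000,
5000} causal SNPs, h² ∈ {0.05, 0.10}, NEG shapes {2, 3, 10}, 20 replicates.
All randomness flows from a single root seed through named substreams
(MAF / genotypes / causal set / effects / residuals, keyed by replicate),
so any replicate is reproducible in isolation.

What the generator does **not** emulate: realistic LD maps (markers are
mutually independent unless the user supplies correlated genotypes),
genotyping error and missingness patterns, ascertainment, or population
structure (available only through the explicit two-subpopulation fixtures
used in the PCA tests).  Passing benchmark cells therefore demonstrate the
estimators' statistical behaviour under the stated architecture, not
performance on any real cohort.

## STMGP

Stage 1 computes the marginal scan via the Frisch–Waugh–Lovell identity,
so the full panel is never residualized in memory.  Stage 2, at a P-value
cutoff `c`, selects A = {j : P_j ≤ c} and assigns
`δ_j = min(1−10⁻⁸, (λ/|t_j|)^(1+γ))`, λ being the |t| whose two-sided P
equals `c`.  δ is 1 at the selection boundary and falls to 0 as the
association strengthens, giving a *continuous* estimator at the boundary —
the defining property of smooth thresholding.  Stage 3 solves the blocked
normal equations of `‖y − Cb − X_A β‖² + τ Σ d_j β_j²`, `d_j = δ_j/(1−δ_j)`,
with the covariate block unpenalized; `τ = N/√log N` by default, with
N/0.1, N/1, N/10 presets for sensitivity analyses, and γ = 1.

Stage 4 selects the cutoff by a Cp-type unbiased risk estimate,
`Cp = RSS + 2σ̂²·df`.  Because the penalty weights δ_j are themselves
functions of y (through the t statistics), an unbiased df must include
their divergence, not just the ridge smoother trace.  Under an orthogonal
design the per-variant divergence has the closed form

```
df_j = a_j + (1+γ)·a_j(1−a_j)/(1−δ_j),   a_j = s_j/(s_j + τ d_j)
```

(`s_j` the covariate-projected column sum of squares).  The implementation
uses the exact trace `tr[(X_A'X_A + τD)⁻¹ X_A'X_A]` for the first part and
the orthogonal-design form for the selection part.  This term is what makes
the criterion honest on null-dominated panels: without it, denser cutoffs
always look better in-sample and the procedure drifts to the largest
cutoff; with it, the chosen cutoff lands at the held-out-error optimum
(verified directly in the tests).  The plain hat-trace df remains available
as `ridge_df`/`cp_criterion` for generic use; it is exact (df = p) in the
τ = 0 limit.  σ̂² is the residual variance of the covariate-only fit — the
only candidate estimate free of selection bias at every cutoff; it
overstates σ² by the factor 1/(1−h²), which is negligible in the low-h²
regime this benchmark targets and shades selection toward sparser models
otherwise.  Cp ties break toward the smaller cutoff.  The cutoff grid is
geometric, 20 points from 1/(2m) to 0.05, plus the 0.05/m Bonferroni point.

## Baselines

* **PRS** — greedy LD clumping (defaults r² ≥ 0.1 within 250 kb; P-value
  ties break by genomic position), then a P-value cutoff chosen from
  {5·10⁻⁸, …, 1} to maximize the training-set correlation with the
  covariate-adjusted phenotype.  Scores are per-allele: the
  standardized-scale marginal betas are divided by the dosage SD so the
  score is a plain weighted allele count.
* **GBLUP** — GRM `WW'/M`; variance components by average-information REML
  with an EM fallback whenever the AI step leaves the parameter space or
  decreases the restricted likelihood.  The GRM is eigendecomposed once, so
  each REML iteration is O(n).  SEs come from the inverse AI matrix, the
  h² SE by the delta method; variances are floored at 10⁻⁸·var(y), and
  non-convergence is flagged, not raised.  BLUP predictions
  `K_xt (K_tt + (σ²_e/σ²_g) I)⁻¹ (y − Cb̂)` are identical to ridge on W at
  penalty M·σ²_e/σ²_g (tested to 10⁻⁶).
* **SBLUP** — solves `(R + m(1−h²)/(n h²) I) β = β_marginal` on the
  standardized scale with h² supplied by REML.  At benchmark scale the
  dense LD matrix is infeasible, so the pipeline applies the solve in
  block-diagonal chunks of 2000 markers — exact for the generator's
  linkage-equilibrium panels, and analogous to the windowed-LD treatment
  summary-statistic methods use in practice.
* **Ridge on clumped markers** — SVD (or, for p > n, the dual/kernel
  eigendecomposition) of the covariate-projected design; the penalty
  minimizes GCV `n·RSS/(n − df)²` over a geometric grid unless given.

## Evaluation statistics

Predictive correlation is Pearson's r with P from `t = r√((n−2)/(1−r²))`;
the partial correlation residualizes both vectors on [1, C] and uses
df = n−2−c.  Williams' t for two dependent correlations sharing a variable
uses the determinant form with df = n−3; its null calibration and power are
verified by simulation (the statistic is t-distributed under ρ12 = ρ13).
Calibration slope is the OLS slope of observed on predicted (identically 1
in-sample for OLS-based predictions).  Power across replicates is the
share with P < 0.05.  Box–Cox uses the maximum-likelihood λ (scipy), with
a +1 shift when zeros are present, as count-type symptom scores admit 0.
The adjusted boxplot tilts the 1.5·IQR fences by `e^(−4MC)`/`e^(3MC)`
(medcouple MC ≥ 0; exponents swap for MC < 0), with the medcouple from
statsmodels, validated against the O(n²) kernel-median brute force.
Fisher's exact 2×2 test uses the probability-mass two-sided convention
(scipy, same as R), validated against full enumeration; the two-sample t
from summary statistics is the pooled-variance form.

## Genotype QC

Variant filters (applied after sample filters, each idempotent): call rate
< 0.99, Hardy–Weinberg exact-test P < 10⁻⁴ (Wigginton-style two-sided:
sum of heterozygote-count probabilities ≤ the observed count's), minor
allele frequency < 0.01.  Sample filter: call rate < 0.98, strict.
Relatedness: 3-class method-of-moments IBD (PI_HAT = P(IBD=2) + P(IBD=1)/2)
with *without-replacement* allele-pool expectations — the plug-in `p²q²`
expectations are badly biased for rare alleles — dropping the
lower-call-rate member of each pair with PI_HAT > 0.09375 (ties: the
later-ordered sample).  PI_HAT from a few thousand markers is noisy
(sd ≈ 0.02 at 5000 SNPs), so a small tail of truly unrelated pairs can
cross the threshold on sparse panels; at 20 000 markers the noise floor is
comfortably below it.  Missing dosages are excluded from frequencies,
HWE counts and call rates, and mean-imputed (to 0 on the standardized
scale) only when a model consumes the matrix.

## Tracy–Widom component selection

The TW(β=1) CDF is computed once per process from the Painlevé II
representation: the Hastings–McLeod solution is obtained as a boundary-value
problem with its asymptotics pinned at both ends (shooting from +∞ is
unstable), and the CDF cached as an 8001-point interpolation table —
reproducing the standard 5%/1% critical values 0.9793/2.0234 to ~10⁻⁵.
Each leading eigenvalue is standardized with an effective marker count
estimated from the Wishart second moment of the remaining spectrum
(`n̂ = r(r+1)/(Σλ'² − r)` on the mean-1 normalized eigenvalues) and tested
sequentially until the first non-significant component; the procedure is
slightly conservative on null panels (observed type-I ≈ 0.01 at α = 0.05).

## Problem sizes and numerical choices

The test suite runs the benchmark cells at the reference sample sizes with
the 20 000-marker desk panel (about two minutes per 20-replicate scenario);
unit and property tests use hundreds of samples and hundreds of markers.
Degenerate inputs are contracts, not surprises: monomorphic variants are
rejected at standardization and silently excluded from selection inside
the fitters; an empty selected set yields a covariate-only model with a
warning; constant vectors are rejected by the correlation statistics.
Cholesky factorizations back all penalized solves (the penalized system is
positive definite whenever τ > 0 and the covariates have full rank).

## Known limitations

No binary-trait models, no summary-statistics-only STMGP (individual-level
genotypes are required for the within-selection correlations), no BayesR,
no imputation, no realistic LD reference panels.  The selection-aware df
uses the orthogonal-design form for the weight-divergence term; under
strong inter-marker LD it is an approximation (the ridge-trace part remains
exact).  PLINK output is PLINK1 (.bed/.bim/.fam) only.
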