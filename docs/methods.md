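# Methods

## Model and estimand

MR-LOVA estimates the causal effect τ of an exposure c on an outcome y
from two-sample GWAS summary statistics, using genetic variants as
instruments. The working model is

```
c = X b + ε                exposure
y = c τ + X u + e          outcome
```

with genotype matrix X, instrument strengths b, and *direct* (horizontally
pleiotropic) SNP effects u. A variant is a valid instrument iff u_j = 0.
The key construction is the latent outcome

```
υ = y − c τ = X u + e
```

which removes the causal (vertical-pleiotropy) pathway: a GWAS of υ
exposes exactly the direct effects, so valid instruments are those whose
effect on υ is null. Since τ is unknown, a stochastic EM loop alternates
imputation of υ's GWAS with re-estimation of τ:

1. **E-step.** On the standardized scale (column-standardized genotypes,
   unit-variance traits, so a marginal effect estimate has sampling
   variance 1/n) the latent-outcome effects are imputed as
   `û_j = ĝ_j − τ b̂_j` with variance
   `var(û_j) = var(ĝ_j) + (τ² − 2 τ cov(y,c))/n_out`,
   where ĝ and b̂ are the standardized outcome and exposure effects.
2. **Selection.** `I_j = 1` iff û_j is *not* significant
   (two-sided normal p > `p_out`, default 0.05 — exclusion restriction)
   and b̂_j *is* significant (p < `p_exp`, default 5e-8 — relevance).
3. **M-step.** τ is updated by the inverse-variance-weighted slope of û
   on b̂ over the selected set,
   `Δ = Σ I_j û_j b̂_j var(û_j)⁻¹ / Σ I_j b̂_j² var(û_j)⁻¹`,
   applied additively: `τ ← τ + Δ`. Because û is residualized on the
   current τ, the truth is a fixed point of this map. Note that the
   additive update is algebraically identical to re-regressing ĝ on b̂
   with the same weights and selection
   (`τ + [Σ I ĝ b̂ w − τ Σ I b̂² w]/Σ I b̂² w = Σ I ĝ b̂ w / Σ I b̂² w`),
   so no separate "total regression" variant exists to expose.

Iteration stops when |Δ| < `tol` (default 1e-6) or after `max_iter`
(default 100; non-convergence is flagged on the result, not raised).
The final standard error is the fixed-effect IVW one,
`se(τ̂) = (Σ I_j b̂_j² var(û_j)⁻¹)^(−1/2)`, with a two-sided normal
p-value. τ is initialized at 0 ("no causal effect") so the algorithm
cannot be pulled toward spurious signal by its starting point.

`cov(y, c)` is approximated once, before iterating, by the genetic
covariance `Σ_j ĝ_j b̂_j` over the instrument panel (valid for
approximately independent standardized SNPs) and clipped to (−1, 1) so
that `var(υ) = 1 + τ² − 2 τ cov` stays positive for every τ. Variances
are floored at 1e-12. If the selection empties mid-iteration the step
falls back to the relevance-only set with a warning (so permutation
replicates cannot crash); an empty selection at convergence is an error.

### Correlated instruments

When an LD correlation matrix Ω from a reference panel is supplied, the
marginal û are rotated to joint effects `Ω⁻¹û` with variances
`diag[(nΩ)⁻¹](var(υ) − R²)`, `R² = û'Ω⁻¹û` capped below var(υ). Ω gets a
ridge of 1e-3 on the diagonal when its smallest eigenvalue drops below
1e-6 (logged). With Ω = I and negligible R² this reduces exactly to the
independent-SNP path.

### Individual-level path

`fit_individual` forms υ explicitly per individual. In the two-sample
design the exposure is unobserved in the outcome cohort, so it is
replaced by its genetic prediction X b̂ (b̂ from the exposure cohort's
GWAS); in the one-sample design (same cohort object passed twice) the
observed exposure is used. Phenotypes and dosages are standardized
within cohort; per-iteration û_j come from per-SNP simple regressions of
υ on each standardized dosage.

## Diagnostics

* **Permutation test.** The (ĝ, se ĝ) pairs — the latent-outcome
  statistics at the τ = 0 initialization — are jointly shuffled against
  b̂; the complete EM (including instrument re-selection) is re-run per
  shuffle and `p = (1 + #{|τ_perm| ≥ |τ̂|})/(B + 1)`. Re-running the
  selection propagates its uncertainty and keeps the null honest, at a
  price: under a strong alternative the shuffled panels retain
  large-magnitude outcome statistics from which the adaptive selection
  can occasionally assemble a sizable slope, so the test is conservative
  (its p rarely reaches the attainable minimum even for clear signals).
  Under exchangeable nulls its p-values are uniform (property-tested).
* **Directional pleiotropy.** One-sample t-test of mean(û) against 0.
* **InSIDE violation.** Pearson correlation test of cor(û, b̂) (t
  transform, m − 2 df). A genetic confounder makes instrument strength
  co-vary with the direct effect, which this detects.

Both pleiotropy tests use û evaluated at the converged τ̂ over **all**
relevance-passing instruments, not only the selected ones — the excluded
instruments carry precisely the pleiotropy signal being tested.

## Summary-statistic handling

Input tables are whitespace/TAB-delimited with configurable column names
(defaults SNP/A1/A2/BETA/SE/P/N). Harmonization intersects SNP ids,
flips outcome betas where the allele pair is swapped, drops incompatible
pairs, and optionally drops palindromic (A/T, C/G) SNPs — off by
default, since strand issues are assumed resolved upstream.
Standardization maps (β, se, n) to (z/√n, 1/√n) with z = β/se, ignoring
the O(z²/n) correction, which is negligible when a single variant
explains ~0% of trait variance. Relevance filtering keeps SNPs with
exposure p < 5e-8 by default. LD clumping is *not* performed; instruments
are expected to be pre-clumped (e.g. plink, r² < 0.1 within 500 kb).

## Synthetic-data generator

The simulator adds an unobserved confounder z with genetic component:

```
z = X φ + η,   c = X b + z + ε,   y = c τ + X u + z + e
```

Genotypes are Binomial(2, f) with MAF f ~ U(0.1, 0.3) redrawn each
replicate and shared by the two (disjoint) cohorts; η, ε, e are standard
normal. Instrument strengths b come from a left-truncated normal —
N(0, sd 0.1) truncated at 0.1 for m = 30, N(0, sd 0.05) truncated at
0.05 for m = 100 — sampled by rejection. Scenarios: (1) no pleiotropy;
(2) balanced, u ~ N(0, sd 0.15) on the invalid subset; (3) directional,
u ~ N(0.1, sd 0.075); (4) directional plus φ ~ U(0, θ) on the *same*
invalid subset, the sterner InSIDE violation (the generator interprets
the second parameter of every normal as a standard deviation, which
makes scenario 3 strongly directional, mean/sd ≈ 1.33). A fraction
`prop_invalid` ∈ {0, 0.3, 0.5, 0.7} of the m SNPs is invalid. The causal
effect is specified on the scaled-trait scale and converted to the raw
scale by fixed-point iteration of `τ_raw = τ_scaled·SD(y)/SD(c)` on a
pilot cohort whose noise draws are held fixed (tolerance 1e-4, ≤ 10
iterations).

Note that even with φ = u = τ = 0 the exposure and outcome remain
correlated through the shared non-genetic confounder η (cov(c, y) = 1 on
the raw scale) — this is what makes naive regression of y on c invalid
and instruments necessary.

The evaluation harness provides **all m SNPs to every method** (the
relevance screen and the inclusion rule's exposure threshold are set to
1.0 in simulations): with the simulated instrument strengths and the
confounder's contribution to var(c), genome-wide significance would be
unattainable for most SNPs, and the study design is to hand each method
the full panel. The 5e-8 defaults remain in force for real-data use,
where instruments are pre-selected at genome-wide significance anyway.
Selection quality is scored against the true labels (valid = u_j = 0 and
φ_j = 0): sensitivity = TP/(TP+FN) over valid SNPs, specificity =
TN/(FP+TN) over invalid ones, metrics averaged over replicates.
Reproducibility: one master seed spawns per-replicate independent
streams; the same seed gives a bit-identical metrics table.

What the generator does *not* emulate about real GWAS: residual LD
between instruments, allele-frequency/effect-size coupling, sample
overlap between cohorts, binary outcomes, population stratification, and
genotyping error. Passing simulation benchmarks therefore demonstrates
correctness of the estimator under its own assumptions, not robustness
to those artefacts.

## Problem sizes and numerical choices

Reference simulation conditions are two cohorts of n = 50,000, m = 100
instruments, 100 replicates per condition (~1.2 s per replicate; the
full benchmark suite runs in ~10 minutes on one CPU). Smaller unit tests
use direct summary-level draws (b̂ = b + N(0,1/n), ĝ = τb + u + N(0,1/n))
to bypass cohort simulation where individual-level structure is not
under test.

Tolerances: EM stopping 1e-6 on |Δτ|; variance floor 1e-12; cov(y,c)
clip at ±0.999; LD ridge 1e-3 below eigenvalue 1e-6; R² cap at
0.999·var(υ). P-values are two-sided normal throughout (GWAS n is
large); no multiple-testing correction is applied inside the inclusion
rule, mirroring the fixed 0.05/5e-8 thresholds. The permutation p uses
the (1+k)/(B+1) estimator so it is never exactly zero.

## Known limitations

* No correction for overlapping exposure/outcome samples.
* Binary outcomes are treated on the linear (standardized) scale; no
  logistic-scale calibration.
* The permutation test is conservative under strong alternatives (see
  above); the analytic IVW p-value is the primary inference.
* cov(y, c) is approximated from the instrument panel only, which
  under-counts the non-genetic part of the covariance; the affected
  variance term is O(1/n) and immaterial at GWAS sample sizes.
* Multivariable MR, Steiger directionality filtering and heterogeneity
  statistics are out of scope.
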