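# Methods

## Generative model of the synthetic cohort

`simulate_cohort` draws, for `n` individuals:

- genotype dosages `x_ij ~ Binomial(2, MAF_j)`, with per-variant MAFs
  uniform on `maf_range` (default 0.05–0.5). Dosages are integer genotype
  counts; continuous imputed dosages in [0, 2] are accepted on input but
  never generated.
- per-variant weights `w_j ~ N(0, 1)`; the PRS is the weighted dosage sum,
  standardized to mean 0 / SD 1 by default (`standardize_prs`). Every
  downstream partial R² is invariant to this affine choice; the flag exists
  because raw-scale scores are sometimes wanted for export.
- sex `~ Bernoulli(sex_ratio)` (default 0.5), independent of the PRS, as is
  appropriate for autosomal weights;
- covariates (age, ten genetic principal components, a head-size scaling
  factor) i.i.d. standard normal, with linear effects `covariate_effects`
  on both phenotypes (default all zero);
- phenotypes from a single-mediator chain with sex-specific paths,

      mediator = a_sex · PRS + covariates·γ + ε_m,   ε_m ~ N(0, σ_m²)
      outcome  = c′_sex · PRS + b_sex · mediator + covariates·γ + ε_y

  so the population direct effect in stratum `s` is `c′_s` and the indirect
  effect is `a_s·b_s`. With a standardized PRS and unit noise SDs the
  `effect_*` parameters are approximately partial correlations, which is
  how the simulation studies plant "standardized effects" of 0.05–0.25 —
  the magnitude range relevant to PRS–cognition associations.

Randomness is split by `SeedSequence(seed).spawn` into one named stream per
step (dosages, weights, sex, covariates, mediator noise, outcome noise), in
that fixed order, so changing the variant panel cannot perturb phenotype
noise; the test suite asserts this isolation.

What the generator deliberately omits: linkage disequilibrium, relatedness
and population stratification (the PCs are pure noise covariates, not
confounders), genotype missingness, multiple correlated mediators, and
case/control liability. Passing tests therefore validate the estimators and
the pipeline logic under the assumed model, not robustness to the
confounding structure of real biobank data.

## Summary-statistic QC

Filters, applied in order with each removed row counted once: malformed
rows (itemized in the report log, never silently dropped), strand-ambiguous
allele pairs {A,T} or {C,G} (no frequency-based rescue — ambiguous SNPs are
removed outright), INDELs (any allele not a single A/C/G/T), the MHC
region, and variants absent from the reference ID list. The MHC default is
chr6:25,000,000–35,000,000 (GRCh37, 1-based inclusive), configurable; the
locus is conventionally excluded because of its extreme LD. Reference
intersection is by variant ID, not position.

Allele alignment resolves identity, swap (sign flip), strand complement and
complement-swap; irreconcilable allele sets are flagged `mismatch` and
excluded. Alignment is only defined after ambiguous pairs are gone, which
is why QC precedes it.

Effective sample size for case/control GWAS is
`⌊4·N_case·N_control/(N_case+N_control)⌋`. Floor rather than round: floor
reproduces the five published values that follow the formula; rounding
fails one of them (3,421/22,155 → 11,853, where rounding gives 11,854).

## Partial R² and the permutation test

Partial R² of the PRS is `(RSS_reduced − RSS_full)/RSS_reduced`, with the
reduced model containing intercept + covariates and the full model adding
the PRS; this equals the squared partial correlation of outcome and PRS
given covariates. The alternative ΔR² (difference of full-model R²) is
available via `method="delta"`. Covariate sets: age + 10 PCs always, sex
added only in the pooled stratum, the head-size/total-brain-volume column
added only for traits declared volumetric.

Permutation inference shuffles the PRS vector jointly across all subjects
(covariates and stratum labels stay attached to individuals) and recomputes
each stratum's partial R² per shuffle; `p = (1 + #{R²* ≥ R²_obs})/(B + 1)`.
The add-one estimator never returns 0 and is valid (super-uniform under the
null) by construction; B defaults to 10,000, while tests and the
acceptance studies use B ≤ 1,000. Within-stratum shuffling is available as
an option; the two nulls coincide here because sex is exchangeable with
respect to the PRS under the null. An exhaustive mode enumerates all n!
permutations for small n and is checked against an independent
enumeration oracle.

Implementation note: single fits go through QR with explicit rank
diagnostics (rank-deficient designs raise an error naming the collinear
columns, tolerance 1e-10 relative to the leading R diagonal). Permutation
and bootstrap loops use chunked, batched normal-equation solves
(B × p × p stacked Cholesky solves over a gathered 3-d design array); the
reduced-model RSS reuses the leading Gram block. Singular or non-finite
replicates are redrawn and counted, with a hard cap of 100 redraws.

BH-FDR is the statsmodels step-up implementation with enforced
monotonicity; the test suite verifies it against a literal step-up
definition on random p-vectors. The default FDR family is
disorder × trait-category × stratum, configurable.

## Sex-heterogeneity procedure

Run only when the observed association is significant in both sexes (a
failed gate is reported as "not evaluated", never dropped). Each sex's
stratum is resampled with replacement B times (size preserved, model refit
each time, resampling within sex because each sex's regression uses only
that sex); the two bootstrap R² distributions are compared by a two-sided
Wilcoxon rank-sum test, and `stronger_sex` is the sex with the larger
median bootstrap R². The effect size is the rank-biserial
`r = |1 − 2U/(n₁n₂)|`, chosen because it attains 1.0 exactly when the two
distributions are disjoint — the only effect-size convention consistent
with reported values of exactly 1. A signed-rank variant on paired
replicates is available by flag.

Recorded caveat: applying a rank-sum test to B bootstrap replicates of
fixed data makes the p-value shrink as B grows even when the data do not
change. The suite asserts this anti-conservatism on a fixed cohort at
B ∈ {100, 1000} so the behavior is an explicit contract of the reproduced
procedure rather than a surprise; the rank-biserial r, which is invariant
to B in expectation, is the quantity to interpret.

## Mediation

Paths come from three least-squares fits sharing one covariate set:
`mediator ~ PRS + cov` (a), `outcome ~ PRS + mediator + cov` (c′, b),
`outcome ~ PRS + cov` (c). The indirect effect is `ab = a·b`, which equals
`c − c′` exactly under shared covariates; the identity is asserted to 1e-8
on arbitrary data as a free correctness oracle.

Inference is a percentile bootstrap over individuals (not BCa — the
simplest defensible interval; BCa could be added); significance is "the
95% CI excludes 0", with a two-sided bootstrap p
`2·min(P(ab* ≤ 0), P(ab* ≥ 0))` floored at 1/B. Measured coverage at
n = 2,000 over (a,b) ∈ {0, 0.2, 0.5}² is 0.92–0.95 except the doubly-null
corner a = b = 0, where the product of two near-zero coefficients makes
the percentile interval over-cover (measured 1.00) — a known property of
product-of-coefficients bootstraps, asserted as such in the tests.

Variance shares: `R²(c′)` is the partial R² of the PRS in the outcome
model that includes the mediator. `R²(ab)` is defined here as
`(a_std·b_std)²` with the paths refit on covariate-residualized,
standardized variables — a convention of this package (no standard
definition of an "indirect-effect R²" exists); under the standardized
generative model it converges to `(a·b)²`, which the tests verify at
n = 20,000. Sex differences of both shares are rank-sum comparisons of
their per-sex bootstrap distributions.

The mediator-type classifier maps per-sex tri-states
(significantly positive / significantly negative / nonsignificant at
FDR < 0.05) of ab and c′, plus the direction of the R²(ab) sex difference,
to labels: **type2** (female ab significantly positive, male ab
nonsignificant or negative), **type1** (male ab significantly negative with
female ab nonsignificant, or both negative with the male effect stronger —
both sub-patterns accepted), **cancel_out** (some sex's significant ab
opposes that sex's significant c′), **other**. Precedence
type2 > type1 > cancel_out > other resolves overlaps deterministically; the
suite enumerates the full input grid.

Replication concordance is the exact one-sided binomial tail
`P(X ≥ k | n, ½)` on the number of effect pairs with matching sign (zero
effects excluded and counted). For 27 concordant of 44 the exact tail is
0.0871; the package reports the exact value.

## Phenotype preparation

Age adjustment takes residuals from `trait ~ intercept + age`
(mean-centering, with a logged warning, when age is constant);
residualization is idempotent and leaves residuals orthogonal to age. The
sex comparison uses the Mann–Whitney test with scipy's "auto" method —
exact for small tie-free samples, tie-corrected normal approximation at
scale — while the effect size is always `r = |Z|/√N` from the tie-corrected
normal Z (the convention that matches the small magnitudes reported at
biobank n). The g factor is the first eigenvector of the correlation matrix
of the task battery (correlation, not covariance: tasks are on different
scales), with sign fixed so that g correlates positively with mean
standardized performance; the variance fraction is the top eigenvalue over
the number of tasks.

## Pipeline

`prstrata run` executes simulate/load → associate → sexdiff → mediate with
the master seed split per stage (fixed stage order, `SeedSequence.spawn`),
so stage-level reruns reproduce full-pipeline runs bit-exactly; the
manifest records the package version, seed, a config hash and a SHA-256
per output table. Output is tidy long-format (one result per row);
`prstrata report` pivots to trait × disorder matrices for presentation.
Config validation enumerates all problems rather than stopping at the
first.

## Problem sizes used in the validation studies

Null calibration: one cohort of 500 individuals, 500 pure-noise traits,
B = 500 permutations. Sex-difference power: 100 replicate cohorts of
10,000 (≈5,000 per sex), gate at per-sex permutation p ≤ 0.05 with
B = 500, bootstrap B = 500; planted standardized effects 0.15 vs 0.05
(power scenario) and 0.10 vs 0.10 (balance scenario). CI coverage:
500 replicates of n = 2,000 per (a, b) setting, bootstrap B = 400. These
sizes make the Monte-Carlo error small relative to the tolerances asserted
(3 binomial standard errors throughout).

## Known limitations

- No LD or relatedness in the generator; estimator behavior under cryptic
  structure is untested.
- The bootstrap-vs-rank-sum heterogeneity test is anti-conservative in B by
  construction (see above); an interaction-term Wald test would be better
  calibrated but is out of scope beyond the recorded caveat.
- `R²(ab)` is a package convention, not a community standard.
- Weight estimation (Bayesian shrinkage, clumping+thresholding), imputation
  and image processing are out of scope: weights, dosages and traits are
  consumed as given.
- Mediation is cross-sectional; no causal-inference sensitivity analysis is
  attempted.
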