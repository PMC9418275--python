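# prstrata

Sex-stratified polygenic-score analysis: association, heterogeneity testing
and mediation, with a synthetic-cohort generator so the whole pipeline runs
offline.

## The problem

Psychiatric disorders such as schizophrenia differ between the sexes in
onset, symptoms and cognitive impact, and part of that difference may be
genetic. A standard way to probe this in healthy cohorts is to score each
individual with a polygenic risk score (PRS) — a weighted sum of risk-allele
dosages, `PRS_i = Σ_j w_j x_ij` — and ask how strongly the PRS predicts
cognition, behavior or brain-imaging traits separately in males and
females. Individual-level biobank data are access-restricted, so `prstrata`
ships a generator that simulates cohorts with the exact structure the
analysis assumes (binomial dosages, sex-specific linear effects, a single
mediation chain), letting every stage be exercised and validated end to
end.

The pipeline implements:

- **Summary-statistic QC** — removal of strand-ambiguous SNPs (A/T, C/G),
  INDELs, MHC-region variants and variants absent from a reference panel;
  allele alignment with strand complementing; effective sample size
  `⌊4·N_case·N_control/(N_case+N_control)⌋` for case/control GWAS.
- **Additive PRS scoring** from a dosage matrix and a 3-column weight file.
- **Phenotype preparation** — age adjustment by residualization, rank-based
  sex comparison with effect size `r = |Z|/√N`, and a *g* factor (first
  principal component of the standardized task battery).
- **Stratified association** — partial R² of the PRS,
  `(RSS_reduced − RSS_full)/RSS_reduced`, in covariate-adjusted regressions
  per stratum (male / female / pooled); significance by permuting the PRS
  among subjects (`p = (1 + #{R²* ≥ R²})/(B + 1)`); Benjamini–Hochberg FDR.
- **Sex-heterogeneity testing** — when the association is significant in
  both sexes, bootstrap each sex's partial R² B times and compare the two
  distributions by a Wilcoxon rank-sum test with rank-biserial effect size
  `r = |1 − 2U/(n₁n₂)|`.
- **Mediation** — Baron–Kenny paths `a` (PRS→mediator), `b`
  (mediator→outcome), `c` (total), `c′` (direct), indirect effect
  `ab = a·b = c − c′`, percentile-bootstrap CI and p, variance shares
  `R²(ab)` and `R²(c′)`, a mediator-type classifier
  (type1 / type2 / cancel_out / other), and an exact binomial
  sign-concordance test for replication.

## Worked example

Simulate a cohort of 2,000 children with a male-only direct PRS effect on
the outcome (standardized effect 0.25 in males, 0 in females) and scan it:

```python
from prstrata import SimulationConfig, simulate_cohort, run_association_scan

cfg = SimulationConfig(n_individuals=2000, n_variants=100,
                       effect_c_prime=(0.25, 0.0), seed=99)
cohort = simulate_cohort(cfg)
table = run_association_scan(cohort, ["PRS"], ["outcome"], B=999, seed=1)
print(table[["stratum", "n", "partial_r2", "beta_sign", "perm_p", "fdr_q"]])
```

```
stratum    n  partial_r2 beta_sign  perm_p  fdr_q
   male 1003    0.095232         +   0.001  0.001
 female  997    0.000682         -   0.445  0.445
    all 2000    0.020459         +   0.001  0.001
```

The male stratum recovers the planted effect (partial R² ≈ 0.25² ≈ 0.06–0.1
depending on the draw) at the smallest attainable permutation p with B=999,
while the female stratum is null; the pooled stratum dilutes the effect.
Because the association is not significant in females, the downstream
sex-difference bootstrap is gated off for this trait — exactly the
procedure's logic.

The same analysis is available from the shell:

```
prstrata run config.yaml outdir/     # simulate -> associate -> sexdiff -> mediate
prstrata qc sumstats.txt out         # summary-statistic QC
prstrata score dosages.tsv weights.tsv prs.tsv
```

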