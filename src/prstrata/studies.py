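"""Simulation studies: calibration, power and coverage of the pipeline.

These drivers wrap the generator and the inference modules into repeatable
Monte-Carlo experiments: permutation-p uniformity under the null, power and
directional accuracy of the gated bootstrap sex-difference procedure, and
coverage of the percentile bootstrap CI for the indirect effect.  They are
used both by the test suite and for reproducing the package's headline
operating characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .heterogeneity import bootstrap_r2, rank_sum_compare
from .association import permutation_test
from .mediation import bootstrap_mediation
from .simulate import SimulationConfig, add_null_traits, simulate_cohort


def _child_seeds(seed: int, k: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(2**31, size=k)]


@dataclass(frozen=True)
class CalibrationResult:
    p_values: np.ndarray
    ks_p: float
    rejection_rate_05: float


def permutation_calibration_study(
    n_traits: int = 500,
    n_individuals: int = 500,
    B: int = 500,
    seed: int = 0,
) -> CalibrationResult:
    """Permutation p-values over pure-noise traits of one null cohort.

    All PRS effects are zero, so every p-value is null; returns the pooled-
    stratum p-values, a Kolmogorov-Smirnov uniformity p, and the empirical
    rejection rate at 0.05.
    """
    cohort_seed, trait_seed, perm_seed = _child_seeds(seed, 3)
    cfg = SimulationConfig(
        n_individuals=n_individuals, n_variants=100, seed=cohort_seed
    )
    cohort = simulate_cohort(cfg)
    cohort = add_null_traits(cohort, n_traits, seed=trait_seed)
    prs = cohort["PRS"].to_numpy()
    cov = cohort[["age"]].to_numpy()
    ps = np.empty(n_traits)
    perm_seeds = _child_seeds(perm_seed, n_traits)
    for j in range(n_traits):
        y = cohort[f"null_trait{j + 1:04d}"].to_numpy()
        res = permutation_test(y, prs, covariates=cov, B=B, seed=perm_seeds[j])
        ps[j] = res["all"].p_value
    ks_p = float(stats.kstest(ps, "uniform").pvalue)
    return CalibrationResult(ps, ks_p, float(np.mean(ps <= 0.05)))


@dataclass(frozen=True)
class SexDiffPowerResult:
    n_replicates: int
    n_gate_passed: int
    n_male_stronger: int  # among gate-passing replicates
    frac_male_stronger: float  # among gate-passing replicates
    gate_pass_rate: float


def sexdiff_power_study(
    effect_male: float,
    effect_female: float,
    n_replicates: int = 100,
    n_individuals: int = 10_000,
    B: int = 500,
    gate_B: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> SexDiffPowerResult:
    """Directional accuracy of the gated bootstrap sex-difference procedure.

    Each replicate simulates a cohort with sex-specific standardized PRS
    effects on the outcome (no mediation), gates on per-sex permutation
    significance at ``alpha``, bootstraps the per-sex partial R-squared, and
    records which sex has the larger median.
    """
    seeds = _child_seeds(seed, n_replicates)
    n_gate = n_male = 0
    for rep_seed in seeds:
        rs = _child_seeds(rep_seed, 4)
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_variants=50,
            effect_c_prime=(effect_male, effect_female),
            seed=rs[0],
        )
        cohort = simulate_cohort(cfg)
        y = cohort["outcome"].to_numpy()
        prs = cohort["PRS"].to_numpy()
        sex = cohort["sex"].to_numpy()
        res = permutation_test(
            y, prs, strata_labels=sex, B=gate_B, seed=rs[1]
        )
        if not (res["male"].p_value <= alpha and res["female"].p_value <= alpha):
            continue
        n_gate += 1
        boots = {
            s: bootstrap_r2(y, prs, stratum_mask=sex == s, B=B, seed=rs[2 + i])
            for i, s in enumerate(("male", "female"))
        }
        if np.median(boots["male"]) > np.median(boots["female"]):
            n_male += 1
    return SexDiffPowerResult(
        n_replicates=n_replicates,
        n_gate_passed=n_gate,
        n_male_stronger=n_male,
        frac_male_stronger=n_male / n_gate if n_gate else float("nan"),
        gate_pass_rate=n_gate / n_replicates,
    )


@dataclass(frozen=True)
class CoverageResult:
    a: float
    b: float
    n_replicates: int
    coverage: float  # fraction of replicates whose 95% CI covers a*b


def mediation_coverage_study(
    a: float,
    b: float,
    n_replicates: int = 500,
    n_individuals: int = 2_000,
    B: int = 400,
    seed: int = 0,
) -> CoverageResult:
    """Coverage of the percentile bootstrap CI for the indirect effect.

    Simulates ``mediator = a*PRS + noise``, ``outcome = b*mediator + noise``
    (equal paths in both sexes, unit noise), so the generative indirect
    effect is ``a*b``; counts how often the 95% CI covers it.
    """
    truth = a * b
    seeds = _child_seeds(seed, n_replicates)
    hits = 0
    for rep_seed in seeds:
        rs = _child_seeds(rep_seed, 2)
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_variants=50,
            effect_a=(a, a),
            effect_b=(b, b),
            seed=rs[0],
        )
        cohort = simulate_cohort(cfg)
        boot = bootstrap_mediation(
            cohort["outcome"].to_numpy(),
            cohort["mediator"].to_numpy(),
            cohort["PRS"].to_numpy(),
            B=B,
            seed=rs[1],
        )
        if boot.ci_low <= truth <= boot.ci_high:
            hits += 1
    return CoverageResult(a, b, n_replicates, hits / n_replicates)
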