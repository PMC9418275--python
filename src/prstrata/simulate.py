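"""Synthetic cohort generator.

Individual-level psychiatric-genetics data (ABCD, UK Biobank) are access
restricted, so every downstream stage of this package is exercised on
simulated cohorts that reproduce the statistical structure the analysis
assumes: binomial genotype dosages, an additive polygenic score (PRS), and a
single-mediator chain with sex-specific linear paths

    mediator = a_sex * PRS + covariates @ g + eps_m
    outcome  = c'_sex * PRS + b_sex * mediator + covariates @ g + eps_y

so the population direct effect in stratum ``s`` is ``c'_s`` and the
indirect effect is ``a_s * b_s``.  Sex is drawn independently of the PRS
(autosomal weights), and covariates (age, ten genetic principal components,
a head-size scaling factor) are standard normal with configurable linear
effects, zero by default.

Randomness is split into one named stream per generation step via
``numpy.random.SeedSequence(seed).spawn``; streams are consumed in the fixed
order dosages, weights, sex, covariates, mediator noise, outcome noise, so
e.g. enlarging the variant panel never perturbs the phenotype noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .scoring import score_individuals, standardize_scores

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
COVARIATE_COLUMNS = ["age"] + PC_COLUMNS + ["headsize"]

_STREAMS = ("dosages", "weights", "sex", "covariates", "mediator", "outcome")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Per-sex pairs are ordered ``(male, female)`` and are in standardized
    units (the PRS is standardized before entering the phenotype models by
    default, so e.g. ``effect_c_prime = (0.15, 0.05)`` plants partial
    correlations of roughly those magnitudes when the noise SDs are 1).
    """

    n_individuals: int = 1_000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    sex_ratio: float = 0.5
    effect_a: tuple[float, float] = (0.0, 0.0)
    effect_b: tuple[float, float] = (0.0, 0.0)
    effect_c_prime: tuple[float, float] = (0.0, 0.0)
    covariate_effects: tuple[float, ...] = field(
        default_factory=lambda: (0.0,) * len(COVARIATE_COLUMNS)
    )
    noise_sd_mediator: float = 1.0
    noise_sd_outcome: float = 1.0
    standardize_prs: bool = True
    prs_name: str = "PRS"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValidationError("n_individuals and n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5]: {self.maf_range}")
        if not (0 < self.sex_ratio < 1):
            raise ValidationError(f"sex_ratio must be in (0, 1): {self.sex_ratio}")
        if self.noise_sd_mediator <= 0 or self.noise_sd_outcome <= 0:
            raise ValidationError("noise standard deviations must be > 0")
        for name in ("effect_a", "effect_b", "effect_c_prime"):
            if len(getattr(self, name)) != 2:
                raise ValidationError(f"{name} must be a (male, female) pair")
        if len(self.covariate_effects) != len(COVARIATE_COLUMNS):
            raise ValidationError(
                f"covariate_effects must have {len(COVARIATE_COLUMNS)} entries "
                f"(order: {', '.join(COVARIATE_COLUMNS)})"
            )

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {n: np.random.default_rng(s) for n, s in zip(_STREAMS, children)}


def simulate_dosages(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float],
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw an (individuals x variants) matrix of binomial(2, MAF) dosages.

    Per-variant MAFs are uniform on ``maf_range``.  Returns the dosage table
    (individual IDs as index, variant IDs as columns) and the MAF vector.
    """
    if n_individuals < 1 or n_variants < 1:
        raise ValidationError("counts must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError(f"maf_range must lie within (0, 0.5]: {maf_range}")
    if rng is None:
        rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_variants)
    dosage = rng.binomial(2, maf, size=(n_individuals, n_variants))
    variant_ids = [f"var{j + 1:05d}" for j in range(n_variants)]
    individual_ids = [f"ind{i + 1:06d}" for i in range(n_individuals)]
    return (
        pd.DataFrame(dosage, index=individual_ids, columns=variant_ids, dtype=float),
        pd.Series(maf, index=variant_ids, name="maf"),
    )


def simulate_weights(
    variant_ids, rng: np.random.Generator, scale: float = 1.0
) -> pd.DataFrame:
    """Standard-normal per-variant weights in the 3-column scoring layout."""
    w = rng.normal(0.0, scale, size=len(variant_ids))
    return pd.DataFrame(
        {"variant_id": list(variant_ids), "effect_allele": "A", "weight": w}
    )


def simulate_cohort(
    config: SimulationConfig, *, return_genotypes: bool = False
):
    """Generate a complete cohort table under ``config``.

    The returned DataFrame has columns ``individual_id``, ``sex`` (labels
    ``male``/``female``), the covariates, one PRS column (standardized
    weighted dosage sum when ``config.standardize_prs``), the mediator and
    the outcome.  With ``return_genotypes=True`` also returns the dosage
    table, MAF vector and weight table used to build the PRS.
    """
    streams = config.streams()
    n = config.n_individuals

    dosages, maf = simulate_dosages(
        n, config.n_variants, config.maf_range, rng=streams["dosages"]
    )
    weights = simulate_weights(dosages.columns, streams["weights"])
    prs = score_individuals(dosages, weights)
    if config.standardize_prs:
        prs = standardize_scores(prs)

    male = streams["sex"].random(n) < config.sex_ratio
    if male.all() or not male.any():
        raise DegenerateDataError(
            "simulated cohort contains a single sex; increase n_individuals "
            "or move sex_ratio away from the boundary"
        )
    sex = np.where(male, "male", "female")

    cov = streams["covariates"].normal(size=(n, len(COVARIATE_COLUMNS)))
    cov_term = cov @ np.asarray(config.covariate_effects, dtype=float)

    a = np.where(male, config.effect_a[0], config.effect_a[1])
    b = np.where(male, config.effect_b[0], config.effect_b[1])
    c_prime = np.where(male, config.effect_c_prime[0], config.effect_c_prime[1])

    prs_values = prs.to_numpy()
    mediator = (
        a * prs_values
        + cov_term
        + streams["mediator"].normal(0.0, config.noise_sd_mediator, size=n)
    )
    outcome = (
        c_prime * prs_values
        + b * mediator
        + cov_term
        + streams["outcome"].normal(0.0, config.noise_sd_outcome, size=n)
    )

    cohort = pd.DataFrame({"individual_id": dosages.index, "sex": sex})
    cohort[COVARIATE_COLUMNS] = cov
    cohort[config.prs_name] = prs_values
    cohort[config.mediator_name] = mediator
    cohort[config.outcome_name] = outcome

    if cohort.columns.duplicated().any():
        raise ValidationError("cohort column names collide; rename prs/mediator/outcome")
    if return_genotypes:
        return cohort, dosages, maf, weights
    return cohort


def add_null_traits(
    cohort: pd.DataFrame,
    n_traits: int,
    seed: int,
    noise_sd: float = 1.0,
    prefix: str = "null_trait",
) -> pd.DataFrame:
    """Append ``n_traits`` pure-noise trait columns (independent of everything).

    Used for calibration studies: under these traits every association
    p-value is null by construction.
    """
    if n_traits < 1:
        raise ValidationError("n_traits must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(len(cohort), n_traits))
    names = [f"{prefix}{j + 1:04d}" for j in range(n_traits)]
    extra = pd.DataFrame(noise, columns=names, index=cohort.index)
    return pd.concat([cohort, extra], axis=1)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def write_dosages(dosages: pd.DataFrame, path: str | Path) -> None:
    dosages.to_csv(path, sep="\t", index_label="individual_id")


def read_dosages(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual_id")


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False)
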