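"""Sex-stratified PRS association: partial R-squared, permutation p, BH-FDR.

For each (disorder PRS, trait, stratum) cell the trait is regressed on
covariates with and without the PRS; the partial R-squared
``(RSS_reduced - RSS_full) / RSS_reduced`` is the variance explained by the
PRS beyond the covariates.  Significance comes from a permutation test: the
PRS vector is randomly permuted among all study subjects B times, the
per-stratum partial R-squared recomputed each time, and
``p = (1 + #{perm R2 >= observed}) / (B + 1)`` (the add-one estimator, which
never returns 0).  Benjamini-Hochberg controls the FDR within a
configurable family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._ols import check_full_rank, partial_r2_qr, residualize, with_intercept
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

STRATA = ("male", "female", "all")


@dataclass(frozen=True)
class CovariateSpec:
    """Which cohort columns act as regression covariates per stratum.

    Age and the genetic principal components are always included; sex is
    added only in the pooled ("all") stratum; the head-size / total-brain-
    volume column is appended only for traits listed in
    ``volumetric_traits``.
    """

    age_col: str = "age"
    pc_cols: tuple[str, ...] = tuple(f"pc{i}" for i in range(1, 11))
    sex_col: str = "sex"
    headsize_col: str | None = "headsize"
    volumetric_traits: frozenset[str] = frozenset()
    trait_categories: dict = field(default_factory=dict)

    def columns_for(self, trait: str, stratum: str) -> list[str]:
        cols = [self.age_col, *self.pc_cols]
        if stratum == "all":
            cols.append(self.sex_col)
        if self.headsize_col and trait in self.volumetric_traits:
            cols.append(self.headsize_col)
        return cols

    def matrix(self, cohort: pd.DataFrame, trait: str, stratum: str) -> tuple[np.ndarray, list[str]]:
        cols = self.columns_for(trait, stratum)
        missing = [c for c in cols if c not in cohort.columns]
        if missing:
            raise ValidationError(f"covariate column(s) missing from cohort: {missing}")
        M = cohort[cols].copy()
        if self.sex_col in M.columns:
            M[self.sex_col] = (M[self.sex_col] == "male").astype(float)
        return M.to_numpy(dtype=float), cols


@dataclass(frozen=True)
class AssociationResult:
    disorder: str
    trait: str
    stratum: str
    n: int
    partial_r2: float
    beta_sign: str  # "+" or "-"
    perm_p: float
    fdr_q: float
    n_permutations: int


def fit_partial_r2(
    outcome,
    prs,
    covariate_matrix=None,
    subset_mask=None,
    method: str = "classical",
    covariate_names: list[str] | None = None,
) -> tuple[float, str]:
    """Partial R-squared of the PRS and the sign of its coefficient.

    ``method="classical"`` is (RSS_red - RSS_full)/RSS_red; ``"delta"`` is
    the difference of full-model R-squared values.  Raises
    :class:`CollinearityError` listing offending columns on rank-deficient
    designs.
    """
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(prs, dtype=float)
    if subset_mask is not None:
        mask = np.asarray(subset_mask, dtype=bool)
        y, p = y[mask], p[mask]
        C_in = None if covariate_matrix is None else np.asarray(covariate_matrix, dtype=float)[mask]
    else:
        C_in = None if covariate_matrix is None else np.asarray(covariate_matrix, dtype=float)
    C = with_intercept(C_in, len(y))
    names = ["intercept"] + (
        covariate_names
        if covariate_names is not None
        else [f"cov{j}" for j in range(C.shape[1] - 1)]
    )
    check_full_rank(np.column_stack([C, p]), names + ["prs"])
    r2, beta, rss_red, rss_full = partial_r2_qr(y, p, C)
    if method == "delta":
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = (rss_red - rss_full) / tss if tss > 0 else 0.0
    elif method != "classical":
        raise ValidationError(f"unknown partial R2 method: {method}")
    return float(r2), ("+" if beta >= 0 else "-")


@dataclass(frozen=True)
class PermutationResult:
    stratum: str
    n: int
    observed_r2: float
    beta_sign: str
    p_value: float
    n_permutations: int


def _stratum_masks(strata_labels, n: int) -> dict[str, np.ndarray]:
    if strata_labels is None:
        return {"all": np.ones(n, dtype=bool)}
    labels = np.asarray(strata_labels)
    masks = {str(s): labels == s for s in pd.unique(labels)}
    masks["all"] = np.ones(n, dtype=bool)
    return masks


def permutation_test(
    outcome,
    prs,
    covariates=None,
    strata_labels=None,
    B: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
    within_stratum: bool = False,
    chunk: int = 512,
) -> dict[str, PermutationResult]:
    """Permutation p-values for the partial R-squared, per stratum.

    The PRS is permuted jointly across all subjects (covariates and stratum
    labels stay attached to individuals), matching a label-exchange null for
    the PRS; ``within_stratum=True`` restricts shuffles to each stratum.
    ``exhaustive=True`` enumerates all n! permutations (small n only) and
    returns the exact proportion ``#{perm R2 >= observed} / n!`` (the
    identity permutation guarantees p > 0).
    """
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(prs, dtype=float)
    n = len(y)
    if not exhaustive and B < 1:
        raise ValidationError("B must be >= 1")
    C_all = None if covariates is None else np.asarray(covariates, dtype=float)
    rng = np.random.default_rng(seed)
    masks = _stratum_masks(strata_labels, n)

    results: dict[str, PermutationResult] = {}
    prepared = {}
    for name, mask in masks.items():
        n_s = int(mask.sum())
        C_s = with_intercept(None if C_all is None else C_all[mask], n_s)
        if n_s <= C_s.shape[1] + 1:
            logger.warning("stratum %r too small for the model (n=%d); skipped", name, n_s)
            continue
        Q, _ = np.linalg.qr(C_s)
        ry = residualize(Q, y[mask])
        ryy = float(ry @ ry)
        if ryy <= 0:
            logger.warning("stratum %r outcome degenerate; skipped", name)
            continue
        rp = residualize(Q, p[mask])
        pp = float(rp @ rp)
        if pp <= 0:
            raise DegenerateDataError(f"PRS constant within covariate span in stratum {name!r}")
        obs = (float(ry @ rp)) ** 2 / (ryy * pp)
        sign = "+" if float(ry @ rp) >= 0 else "-"
        prepared[name] = (mask, Q, ry, ryy, obs, sign, n_s)

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        total = len(perms)
        for name, (mask, Q, ry, ryy, obs, sign, n_s) in prepared.items():
            P = p[perms][:, mask]  # (total, n_s)
            RP = P.T - Q @ (Q.T @ P.T)
            num = ry @ RP
            den = np.einsum("ij,ij->j", RP, RP)
            r2 = np.where(den > 0, num**2 / (ryy * den), 0.0)
            count = int(np.sum(r2 >= obs - 1e-15))
            results[name] = PermutationResult(name, n_s, obs, sign, count / total, total)
        return results

    counts = {name: 0 for name in prepared}
    done = 0
    while done < B:
        c = min(chunk, B - done)
        if within_stratum:
            idx = np.tile(np.arange(n), (c, 1))
            for _, mask in masks.items():
                if mask.all():
                    continue
                sub = np.flatnonzero(mask)
                shuf = rng.permuted(np.tile(sub, (c, 1)), axis=1)
                idx[:, sub] = shuf
        else:
            idx = rng.permuted(np.tile(np.arange(n), (c, 1)), axis=1)
        P_full = p[idx]  # (c, n)
        for name, (mask, Q, ry, ryy, obs, sign, n_s) in prepared.items():
            P_s = P_full[:, mask].T  # (n_s, c)
            RP = P_s - Q @ (Q.T @ P_s)
            num = ry @ RP
            den = np.einsum("ij,ij->j", RP, RP)
            r2 = np.where(den > 0, num**2 / (ryy * den), 0.0)
            counts[name] += int(np.sum(r2 >= obs - 1e-15))
        done += c

    for name, (mask, Q, ry, ryy, obs, sign, n_s) in prepared.items():
        p_val = (1 + counts[name]) / (B + 1)
        results[name] = PermutationResult(name, n_s, obs, sign, p_val, B)
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-adjusted)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_association_scan(
    cohort: pd.DataFrame,
    prs_columns,
    trait_columns,
    covariate_spec: CovariateSpec | None = None,
    B: int = 1_000,
    seed: int | None = None,
    fdr_family=("disorder", "category", "stratum"),
) -> pd.DataFrame:
    """Partial-R2 + permutation + BH-FDR over the disorder x trait x stratum grid.

    Returns a tidy table with one row per cell; q-values are computed within
    groups defined by ``fdr_family`` (any subset of disorder / trait /
    category / stratum; the trait category defaults to "default" unless
    mapped in ``covariate_spec.trait_categories``).
    """
    spec = covariate_spec or CovariateSpec()
    missing = [
        c for c in list(prs_columns) + list(trait_columns) if c not in cohort.columns
    ]
    if missing:
        raise ValidationError(f"column(s) missing from cohort: {missing}")
    if cohort[list(prs_columns) + list(trait_columns)].isna().any().any():
        raise ValidationError("cohort contains missing values in analysis columns")

    grid = list(itertools.product(prs_columns, trait_columns))
    streams = np.random.SeedSequence(seed).spawn(len(grid))
    sex = cohort[spec.sex_col].to_numpy()
    rows = []
    for (disorder, trait), ss in zip(grid, streams):
        y = cohort[trait].to_numpy(dtype=float)
        p = cohort[disorder].to_numpy(dtype=float)
        rng = np.random.default_rng(ss)
        # Single-sex strata: PRS permuted jointly among all subjects, with
        # the per-sex partial R2 recomputed on each shuffle.
        C_sex, _ = spec.matrix(cohort, trait, "male")
        res = permutation_test(
            y, p, covariates=C_sex, strata_labels=sex, B=B, seed=int(rng.integers(2**31))
        )
        # Pooled stratum refits with sex as an extra covariate.
        C_pool, _ = spec.matrix(cohort, trait, "all")
        res_all = permutation_test(
            y, p, covariates=C_pool, strata_labels=None, B=B, seed=int(rng.integers(2**31))
        )
        res["all"] = res_all.get("all")
        for stratum in STRATA:
            r = res.get(stratum)
            if r is None:
                continue  # stratum skipped (too small / degenerate); logged upstream
            rows.append(
                {
                    "disorder": disorder,
                    "trait": trait,
                    "category": spec.trait_categories.get(trait, "default"),
                    "stratum": stratum,
                    "n": r.n,
                    "partial_r2": r.observed_r2,
                    "beta_sign": r.beta_sign,
                    "perm_p": r.p_value,
                    "n_permutations": r.n_permutations,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    keys = [k for k in fdr_family if k in table.columns]
    if keys:
        table["fdr_q"] = (
            table.groupby(keys, group_keys=False)["perm_p"].transform(lambda s: bh_fdr(s.to_numpy()))
        )
    else:
        table["fdr_q"] = bh_fdr(table["perm_p"].to_numpy())
    return table
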