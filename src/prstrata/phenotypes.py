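"""Phenotype preparation: age adjustment, sex comparison, g factor.

Cognitive and behavioral traits are adjusted for age by taking residuals
from a least-squares fit of trait on age; adjusted traits are compared
between sexes by a rank-sum test with effect size r = |Z|/sqrt(N); general
cognition (the g factor) is the first principal component of the
correlation matrix of the standardized task battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SexComparisonResult:
    trait: str
    mean_male: float
    mean_female: float
    sd_male: float
    sd_female: float
    statistic: float  # Mann-Whitney U for the male sample
    p_value: float
    effect_size_r: float  # |Z| / sqrt(N), tie-corrected normal Z
    higher_sex: str | None  # label with the larger mean rank; None on exact tie


def residualize_on_age(trait_values, ages) -> np.ndarray:
    """Residuals of the least-squares fit trait ~ intercept + age.

    With constant age the fit degenerates to mean-centering (logged).
    """
    y = np.asarray(trait_values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("trait and age must be 1-d vectors of equal length")
    if y.size < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        logger.warning("constant age: age adjustment degenerates to mean-centering")
        return y - y.mean()
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U for x, tie-corrected normal-approximation Z without continuity)."""
    nx, ny = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    n = nx + ny
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u_x, 0.0
    return u_x, (u_x - nx * ny / 2.0) / np.sqrt(var_u)


def compare_sexes(residuals, sex_labels, trait: str = "") -> SexComparisonResult:
    """Two-sample rank test of an adjusted trait between the sexes.

    The p-value uses scipy's Mann-Whitney "auto" method (exact for small
    tie-free samples, tie-corrected normal approximation otherwise); the
    effect size is always r = |Z|/sqrt(N) from the tie-corrected normal Z,
    which matches the small magnitudes seen at biobank sample sizes.
    """
    values = np.asarray(residuals, dtype=float)
    labels = np.asarray(sex_labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise DegenerateDataError("both sexes must be present for a sex comparison")
    if len(groups) > 2:
        raise ValidationError(f"expected 2 sex labels, got {list(groups)}")
    ga, gb = sorted(map(str, groups))
    x = values[labels == ga]
    y = values[labels == gb]
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each sex needs at least 2 members")

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u_x, z = _rank_sum_z(x, y)
    r = abs(z) / np.sqrt(len(values))
    if u_x > len(x) * len(y) / 2.0:
        higher = ga
    elif u_x < len(x) * len(y) / 2.0:
        higher = gb
    else:
        higher = None

    stats_by = {ga: x, gb: y}
    male_like = "male" if "male" in stats_by else ga
    female_like = "female" if "female" in stats_by else gb
    return SexComparisonResult(
        trait=trait,
        mean_male=float(stats_by[male_like].mean()),
        mean_female=float(stats_by[female_like].mean()),
        sd_male=float(stats_by[male_like].std(ddof=1)),
        sd_female=float(stats_by[female_like].std(ddof=1)),
        statistic=float(res.statistic if ga == male_like else len(x) * len(y) - res.statistic),
        p_value=float(res.pvalue),
        effect_size_r=float(min(r, 1.0)),
        higher_sex=higher,
    )


def compute_g_factor(
    task_matrix: pd.DataFrame | np.ndarray,
    allow_single_task: bool = False,
) -> tuple[np.ndarray, float]:
    """First principal component of the task battery's correlation matrix.

    Returns the per-individual g score and the fraction of total variance
    captured by the first component (top eigenvalue / number of tasks).
    The sign is fixed so g correlates positively with the mean standardized
    task score (higher g = better overall performance).
    """
    if isinstance(task_matrix, pd.DataFrame):
        names = list(task_matrix.columns)
        X = task_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(task_matrix, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"task{j + 1}" for j in range(X.shape[1])]
    n, k = X.shape
    if n < 3:
        raise ValidationError("need at least 3 individuals")
    sds = X.std(axis=0)
    constant = [names[j] for j in np.flatnonzero(sds == 0)]
    if constant:
        raise DegenerateDataError(f"constant task column(s): {constant}")
    Z = (X - X.mean(axis=0)) / sds
    if k == 1:
        if allow_single_task:
            return Z[:, 0], 1.0
        raise ValidationError("need at least 2 tasks (or pass allow_single_task=True)")

    corr = (Z.T @ Z) / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    top = eigvals[-1]
    v = eigvecs[:, -1]
    g = Z @ v
    if g @ Z.mean(axis=1) < 0:
        g = -g
    return g, float(top / k)
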