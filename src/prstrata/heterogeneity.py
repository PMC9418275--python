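"""Bootstrap + rank-sum test for sex differences in PRS partial R-squared.

When a PRS-trait association is significant in both sexes, each sex's
individuals are resampled with replacement B times (stratum size preserved,
regression refit per replicate) to obtain B partial R-squared values per
sex; the two bootstrap distributions are compared by a Wilcoxon rank-sum
test with a rank-biserial effect size r = |1 - 2U/(n_x n_y)| (bounded by 1,
reaching it exactly when the distributions are disjoint).

A recorded caveat of this procedure: because the rank-sum test is applied
to B resampling replicates of fixed data, its p-value shrinks as B grows
even when the data do not change.  The test suite asserts this behavior as
a contract rather than hiding it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import batched_partial_r2, with_intercept
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


def bootstrap_r2(
    outcome,
    prs,
    covariates=None,
    stratum_mask=None,
    B: int = 1_000,
    seed: int | None = None,
    chunk: int = 256,
    max_redraws: int = 100,
) -> np.ndarray:
    """B bootstrap replicates of the partial R-squared within one stratum.

    Individuals are resampled with replacement (stratum size preserved) and
    the covariate+PRS regression refit on every replicate.  Singular
    resample designs are redrawn (count logged).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(prs, dtype=float)
    if stratum_mask is not None:
        mask = np.asarray(stratum_mask, dtype=bool)
        y, p = y[mask], p[mask]
        C_in = None if covariates is None else np.asarray(covariates, dtype=float)[mask]
    else:
        C_in = None if covariates is None else np.asarray(covariates, dtype=float)
    n = len(y)
    X = np.column_stack([with_intercept(C_in, n), p])
    if n <= X.shape[1]:
        raise DegenerateDataError(
            f"stratum of size {n} cannot fit a model with {X.shape[1]} parameters"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    filled = 0
    redraws = 0
    while filled < B:
        c = min(chunk, B - filled)
        idx = rng.integers(0, n, size=(c, n))
        r2, ok = batched_partial_r2(X[idx], y[idx])
        n_ok = int(ok.sum())
        out[filled : filled + n_ok] = r2[ok]
        filled += n_ok
        bad = c - n_ok
        if bad:
            redraws += bad
            if redraws > max_redraws:
                raise DegenerateDataError("too many singular bootstrap resamples")
    if redraws:
        logger.info("redrew %d singular bootstrap resamples", redraws)
    return out


def rank_sum_compare(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U (for x), two-sided normal-approximation p with tie
    correction, and the rank-biserial effect size r = |1 - 2U/(n_x n_y)|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    u = float(res.statistic)
    r = abs(1.0 - 2.0 * u / (len(x) * len(y)))
    return u, float(res.pvalue), r


@dataclass(frozen=True)
class SexDiffResult:
    disorder: str
    trait: str
    evaluated: bool  # False when the both-sexes-significant gate failed
    gate_note: str = ""
    r2_boot_male: np.ndarray | None = None
    r2_boot_female: np.ndarray | None = None
    wilcoxon_p: float = float("nan")
    effect_size_r: float = float("nan")
    stronger_sex: str | None = None


def sex_difference_test(
    cohort: pd.DataFrame,
    disorder: str,
    trait: str,
    covariate_spec=None,
    B: int = 1_000,
    seed: int | None = None,
    gate: dict[str, bool] | None = None,
    use_signed_rank: bool = False,
) -> SexDiffResult:
    """Gated bootstrap comparison of male vs female partial R-squared.

    ``gate`` maps each sex to whether its observed association was
    significant; the comparison runs only when both are True (a failed gate
    is returned as an explicit "not evaluated" record, never dropped).
    ``stronger_sex`` is the sex with the larger median bootstrap R-squared.
    """
    from .association import CovariateSpec

    if gate is None:
        raise ValidationError("gate (per-sex significance flags) is required")
    if not (gate.get("male") and gate.get("female")):
        failed = [s for s in ("male", "female") if not gate.get(s)]
        return SexDiffResult(
            disorder,
            trait,
            evaluated=False,
            gate_note=f"not evaluated: association not significant in {', '.join(failed)}",
        )
    spec = covariate_spec or CovariateSpec()
    y = cohort[trait].to_numpy(dtype=float)
    p = cohort[disorder].to_numpy(dtype=float)
    sex = cohort[spec.sex_col].to_numpy()
    C, _ = spec.matrix(cohort, trait, "male")
    ss = np.random.SeedSequence(seed).spawn(2)
    boots = {}
    for s, child in zip(("male", "female"), ss):
        boots[s] = bootstrap_r2(
            y, p, covariates=C, stratum_mask=sex == s, B=B,
            seed=np.random.default_rng(child).integers(2**31),
        )
    if use_signed_rank:
        res = stats.wilcoxon(boots["male"], boots["female"])
        u, p_val, r = rank_sum_compare(boots["male"], boots["female"])
        p_val = float(res.pvalue)
    else:
        u, p_val, r = rank_sum_compare(boots["male"], boots["female"])
    med_m, med_f = np.median(boots["male"]), np.median(boots["female"])
    stronger = "male" if med_m > med_f else ("female" if med_f > med_m else None)
    return SexDiffResult(
        disorder,
        trait,
        evaluated=True,
        r2_boot_male=boots["male"],
        r2_boot_female=boots["female"],
        wilcoxon_p=p_val,
        effect_size_r=r,
        stronger_sex=stronger,
    )
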