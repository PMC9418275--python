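"""Sex-stratified Baron-Kenny mediation of PRS effects through imaging traits.

Three least-squares fits sharing one covariate set give the paths

    mediator ~ PRS + covariates          -> a
    outcome  ~ PRS + mediator + covariates -> c' (PRS), b (mediator)
    outcome  ~ PRS + covariates          -> c (total effect)

The indirect effect is ``ab = a * b``, identical to ``c - c'`` under shared
covariates (an exact OLS identity used as a free correctness check).
Bootstrap over individuals yields a percentile confidence interval and a
two-sided p for ab.  Variance shares: ``r2_c_prime`` is the partial
R-squared of the PRS in the outcome model that includes the mediator;
``r2_ab = (a_std * b_std)^2`` from the paths refit on covariate-residualized,
standardized variables.  Mediators are classified by the per-sex signs and
significance of ab and c' (type1 / type2 / cancel_out / other), and
discovery-vs-replication agreement is an exact binomial sign-concordance
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import batched_ols, check_full_rank, partial_r2_qr, residualize, with_intercept
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

TRI_STATES = ("sig_neg", "sig_pos", "ns")
TYPE_LABELS = ("type1", "type2", "cancel_out", "other")


@dataclass(frozen=True)
class PathEstimates:
    a: float
    b: float
    c: float
    c_prime: float

    @property
    def ab(self) -> float:
        return self.a * self.b


def _ols_coefs(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_paths(outcome, mediator, prs, covariates=None, subset=None) -> PathEstimates:
    """Estimate (a, b, c, c') from the three shared-covariate regressions."""
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(mediator, dtype=float)
    p = np.asarray(prs, dtype=float)
    C_in = None if covariates is None else np.asarray(covariates, dtype=float)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        y, m, p = y[mask], m[mask], p[mask]
        C_in = None if C_in is None else C_in[mask]
    n = len(y)
    C = with_intercept(C_in, n)
    k = C.shape[1]
    cov_names = ["intercept"] + [f"cov{j}" for j in range(k - 1)]
    if n <= k + 2:
        raise DegenerateDataError("subset smaller than the parameter count")
    a = _ols_coefs(np.column_stack([C, p]), m, cov_names + ["prs"])[k]
    beta_out = _ols_coefs(
        np.column_stack([C, p, m]), y, cov_names + ["prs", "mediator"]
    )
    c_prime, b = beta_out[k], beta_out[k + 1]
    c = _ols_coefs(np.column_stack([C, p]), y, cov_names + ["prs"])[k]
    return PathEstimates(a=float(a), b=float(b), c=float(c), c_prime=float(c_prime))


@dataclass(frozen=True)
class MediationBootstrap:
    ab: float  # point estimate on the original sample
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool  # CI excludes zero
    n_redrawn: int
    ab_samples: np.ndarray


def bootstrap_mediation(
    outcome,
    mediator,
    prs,
    covariates=None,
    stratum_mask=None,
    B: int = 1_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    chunk: int = 256,
    max_redraws: int = 100,
) -> MediationBootstrap:
    """Percentile bootstrap for the indirect effect ab within one stratum.

    Resamples individuals with replacement, refits the a- and b-paths per
    replicate; the two-sided p is ``2 * min(P(ab* <= 0), P(ab* >= 0))``
    floored at 1/B, and the significance flag is "CI excludes zero".
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(mediator, dtype=float)
    p = np.asarray(prs, dtype=float)
    C_in = None if covariates is None else np.asarray(covariates, dtype=float)
    if stratum_mask is not None:
        mask = np.asarray(stratum_mask, dtype=bool)
        y, m, p = y[mask], m[mask], p[mask]
        C_in = None if C_in is None else C_in[mask]
    n = len(y)
    point = fit_paths(y, m, p, C_in)
    C = with_intercept(C_in, n)
    k = C.shape[1]
    X_med = np.column_stack([C, p])  # a-path design
    rng = np.random.default_rng(seed)
    ab = np.empty(B)
    filled = 0
    redraws = 0
    while filled < B:
        c = min(chunk, B - filled)
        idx = rng.integers(0, n, size=(c, n))
        Xa = X_med[idx]  # (c, n, k+1)
        beta_a, _, ok_a = batched_ols(Xa, m[idx])
        Xb = np.concatenate([Xa, m[idx][..., None]], axis=2)
        beta_b, _, ok_b = batched_ols(Xb, y[idx])
        ok = ok_a & ok_b
        vals = beta_a[:, k] * beta_b[:, k + 1]
        ok &= np.isfinite(vals)
        n_ok = int(ok.sum())
        ab[filled : filled + n_ok] = vals[ok]
        filled += n_ok
        bad = c - n_ok
        if bad:
            redraws += bad
            if redraws > max_redraws:
                raise DegenerateDataError("too many singular bootstrap resamples")
    if redraws:
        logger.info("redrew %d singular mediation resamples", redraws)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(ab, [alpha / 2, 1 - alpha / 2])
    p_two = 2.0 * min(np.mean(ab <= 0), np.mean(ab >= 0))
    p_two = float(min(1.0, max(p_two, 1.0 / B)))
    return MediationBootstrap(
        ab=point.ab,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p_two,
        significant=not (lo <= 0.0 <= hi),
        n_redrawn=redraws,
        ab_samples=ab,
    )


def mediation_r2(
    outcome, mediator, prs, covariates=None, subset=None
) -> tuple[float, float]:
    """(r2_ab, r2_c_prime): variance shares of the indirect and direct paths.

    ``r2_c_prime`` is the partial R-squared of the PRS in
    ``outcome ~ PRS + mediator + covariates``.  ``r2_ab`` squares the
    standardized indirect path: PRS, mediator and outcome are residualized
    on the covariates, standardized, and the a/b coefficients refit.
    """
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(mediator, dtype=float)
    p = np.asarray(prs, dtype=float)
    C_in = None if covariates is None else np.asarray(covariates, dtype=float)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        y, m, p = y[mask], m[mask], p[mask]
        C_in = None if C_in is None else C_in[mask]
    n = len(y)
    C = with_intercept(C_in, n)
    Q, _ = np.linalg.qr(C)
    resids = []
    for name, v in (("prs", p), ("mediator", m), ("outcome", y)):
        rv = residualize(Q, v)
        sd = rv.std()
        if sd <= 0:
            raise DegenerateDataError(f"{name} has zero residual variance given covariates")
        resids.append(rv / sd)
    pz, mz, yz = resids
    a_std = float(pz @ mz) / float(pz @ pz)
    X = np.column_stack([pz, mz])
    beta = np.linalg.lstsq(X, yz, rcond=None)[0]
    b_std = float(beta[1])
    r2_ab = min((a_std * b_std) ** 2, 1.0)

    C_med = np.column_stack([C, m])
    r2_c_prime, _, _, _ = partial_r2_qr(y, p, C_med)
    return r2_ab, float(r2_c_prime)


def classify_mediator(
    ab_male: str,
    ab_female: str,
    c_prime_male: str,
    c_prime_female: str,
    ab_stronger_sex: str | None = None,
) -> str:
    """Map per-sex tri-state (sig_pos / sig_neg / ns) patterns to a type label.

    * ``type2``: female ab significantly positive, male ab nonsignificant or
      negative;
    * ``type1``: male ab significantly negative, female ab nonsignificant, or
      both significantly negative with the male effect stronger
      (``ab_stronger_sex == "male"``, from the R-squared sex comparison);
    * ``cancel_out``: in at least one sex a significant ab opposes that
      sex's significant c' in sign;
    * ``other`` otherwise.

    Precedence (type2 > type1 > cancel_out > other) resolves overlapping
    patterns deterministically.
    """
    states = {
        "ab_male": ab_male,
        "ab_female": ab_female,
        "c_prime_male": c_prime_male,
        "c_prime_female": c_prime_female,
    }
    for key, val in states.items():
        if val not in TRI_STATES:
            raise ValidationError(f"{key}={val!r}; expected one of {TRI_STATES}")
    if ab_stronger_sex not in (None, "male", "female"):
        raise ValidationError(f"ab_stronger_sex={ab_stronger_sex!r}")

    if ab_female == "sig_pos" and ab_male in ("ns", "sig_neg"):
        return "type2"
    if ab_male == "sig_neg" and (
        ab_female == "ns" or (ab_female == "sig_neg" and ab_stronger_sex == "male")
    ):
        return "type1"
    sign = {"sig_neg": -1, "sig_pos": 1, "ns": 0}
    for ab_s, cp_s in ((ab_male, c_prime_male), (ab_female, c_prime_female)):
        if sign[ab_s] != 0 and sign[cp_s] != 0 and sign[ab_s] != sign[cp_s]:
            return "cancel_out"
    return "other"


@dataclass(frozen=True)
class ConcordanceResult:
    n_total: int
    n_concordant: int
    n_excluded_zero: int
    proportion: float
    p_value: float  # one-sided exact binomial tail vs 0.5


def sign_concordance(discovery_effects, replication_effects) -> ConcordanceResult:
    """Exact binomial test of direction agreement between two effect vectors.

    Pairs where either effect is exactly zero are excluded (and counted);
    p is the exact upper-tail probability of >= the observed number of
    concordant signs under fair coin flipping.
    """
    d = np.asarray(discovery_effects, dtype=float)
    r = np.asarray(replication_effects, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ValidationError("effect vectors must be 1-d and of equal length")
    nonzero = (d != 0) & (r != 0)
    n_excluded = int((~nonzero).sum())
    d, r = d[nonzero], r[nonzero]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("no nonzero effect pairs to compare")
    k = int(np.sum(np.sign(d) == np.sign(r)))
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return ConcordanceResult(
        n_total=n,
        n_concordant=k,
        n_excluded_zero=n_excluded,
        proportion=k / n,
        p_value=float(p),
    )


def _tri_state(significant: bool, estimate: float) -> str:
    if not significant:
        return "ns"
    return "sig_neg" if estimate < 0 else "sig_pos"


def run_mediation(
    cohort: pd.DataFrame,
    mediators,
    outcome: str,
    prs: str,
    covariate_spec=None,
    B: int = 1_000,
    seed: int | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-mediator, per-sex mediation table with R-squared sex comparisons
    and a type label per mediator.

    For each mediator and sex: paths, bootstrap ab CI/p, and bootstrap
    distributions of r2_ab and r2_c_prime; the sex difference of each
    R-squared is a rank-sum comparison of the two bootstrap vectors.
    Significance flags for the classification come from BH-FDR over the
    bootstrap ab p-values (family: all mediator x sex cells) and the c'
    bootstrap CIs.
    """
    from .association import CovariateSpec, bh_fdr
    from .heterogeneity import rank_sum_compare

    spec = covariate_spec or CovariateSpec()
    missing = [c for c in [*mediators, outcome, prs] if c not in cohort.columns]
    if missing:
        raise ValidationError(f"column(s) missing from cohort: {missing}")
    sex = cohort[spec.sex_col].to_numpy()
    y = cohort[outcome].to_numpy(dtype=float)
    p_vec = cohort[prs].to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed).spawn(len(mediators))

    records = []
    for med, med_ss in zip(mediators, ss):
        m = cohort[med].to_numpy(dtype=float)
        C, _ = spec.matrix(cohort, med, "male")
        per_sex = {}
        for s, child in zip(("male", "female"), med_ss.spawn(2)):
            mask = sex == s
            rngs = np.random.default_rng(child)
            paths = fit_paths(y, m, p_vec, C, subset=mask)
            boot = bootstrap_mediation(
                y, m, p_vec, C, stratum_mask=mask, B=B,
                seed=int(rngs.integers(2**31)),
            )
            r2_ab, r2_cp = mediation_r2(y, m, p_vec, C, subset=mask)
            # bootstrap distributions of the two variance shares
            idx_rng = np.random.default_rng(rngs.integers(2**31))
            sub = np.flatnonzero(mask)
            r2_ab_b = np.empty(B)
            r2_cp_b = np.empty(B)
            Cm = C[sub]
            for i in range(B):
                take = sub[idx_rng.integers(0, len(sub), size=len(sub))]
                try:
                    r2_ab_b[i], r2_cp_b[i] = mediation_r2(
                        y[take], m[take], p_vec[take], C[take]
                    )
                except DegenerateDataError:
                    r2_ab_b[i], r2_cp_b[i] = np.nan, np.nan
            # c' significance from the percentile CI of bootstrap c' draws is
            # approximated by the analytic t-test of the outcome model; the
            # bootstrap ab CI drives the indirect-effect flag.
            cp_p = _cprime_p_value(y, m, p_vec, Cm, mask)
            per_sex[s] = dict(
                paths=paths, boot=boot, r2_ab=r2_ab, r2_c_prime=r2_cp,
                r2_ab_boot=r2_ab_b[np.isfinite(r2_ab_b)],
                r2_cp_boot=r2_cp_b[np.isfinite(r2_cp_b)],
                cp_p=cp_p,
            )
        _, p_ab_sex, r_ab_sex = rank_sum_compare(
            per_sex["male"]["r2_ab_boot"], per_sex["female"]["r2_ab_boot"]
        )
        _, p_cp_sex, r_cp_sex = rank_sum_compare(
            per_sex["male"]["r2_cp_boot"], per_sex["female"]["r2_cp_boot"]
        )
        ab_stronger = (
            "male"
            if np.median(per_sex["male"]["r2_ab_boot"]) >= np.median(per_sex["female"]["r2_ab_boot"])
            else "female"
        )
        records.append(
            dict(mediator=med, per_sex=per_sex, p_ab_sexdiff=p_ab_sex,
                 r_ab_sexdiff=r_ab_sex, p_cp_sexdiff=p_cp_sex,
                 r_cp_sexdiff=r_cp_sex, ab_stronger=ab_stronger)
        )

    # FDR over the ab bootstrap p-values, family = mediator x sex
    ab_ps = [rec["per_sex"][s]["boot"].p_value for rec in records for s in ("male", "female")]
    cp_ps = [rec["per_sex"][s]["cp_p"] for rec in records for s in ("male", "female")]
    ab_qs = bh_fdr(ab_ps)
    cp_qs = bh_fdr(cp_ps)

    rows = []
    i = 0
    for rec in records:
        tri = {}
        for s in ("male", "female"):
            info = rec["per_sex"][s]
            tri[("ab", s)] = _tri_state(ab_qs[i] < fdr_level, info["boot"].ab)
            tri[("cp", s)] = _tri_state(cp_qs[i] < fdr_level, info["paths"].c_prime)
            i += 1
        label = classify_mediator(
            tri[("ab", "male")], tri[("ab", "female")],
            tri[("cp", "male")], tri[("cp", "female")],
            ab_stronger_sex=rec["ab_stronger"],
        )
        j = i - 2
        for s in ("male", "female"):
            info = rec["per_sex"][s]
            paths = info["paths"]
            boot = info["boot"]
            rows.append(
                {
                    "mediator": rec["mediator"],
                    "sex": s,
                    "a": paths.a,
                    "b": paths.b,
                    "c": paths.c,
                    "c_prime": paths.c_prime,
                    "ab": boot.ab,
                    "ab_ci_low": boot.ci_low,
                    "ab_ci_high": boot.ci_high,
                    "ab_p": boot.p_value,
                    "ab_q": ab_qs[j],
                    "ab_state": tri[("ab", s)],
                    "c_prime_p": info["cp_p"],
                    "c_prime_q": cp_qs[j],
                    "c_prime_state": tri[("cp", s)],
                    "r2_ab": info["r2_ab"],
                    "r2_c_prime": info["r2_c_prime"],
                    "r2_ab_sexdiff_p": rec["p_ab_sexdiff"],
                    "r2_ab_sexdiff_r": rec["r_ab_sexdiff"],
                    "r2_c_prime_sexdiff_p": rec["p_cp_sexdiff"],
                    "r2_c_prime_sexdiff_r": rec["r_cp_sexdiff"],
                    "ab_stronger_sex": rec["ab_stronger"],
                    "type_label": label,
                }
            )
            j += 1
    return pd.DataFrame(rows)


def _cprime_p_value(y, m, p_vec, C_stratum, mask) -> float:
    """Two-sided t-test p for the PRS coefficient in outcome ~ PRS + mediator + cov."""
    ys, ms, ps = y[mask], m[mask], p_vec[mask]
    n = len(ys)
    X = np.column_stack([with_intercept(C_stratum, n), ps, ms])
    beta, res_, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta
    dof = n - X.shape[1]
    if dof <= 0:
        raise DegenerateDataError("not enough observations for the outcome model")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[-2, -2])
    if se == 0:
        return 1.0 if beta[-2] == 0 else np.finfo(float).tiny
    t = beta[-2] / se
    return float(2 * stats.t.sf(abs(t), dof))
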