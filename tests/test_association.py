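import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prstrata import (
    CollinearityError,
    CovariateSpec,
    ValidationError,
    bh_fdr,
    fit_partial_r2,
    permutation_test,
    run_association_scan,
)
from prstrata._ols import residualize, with_intercept


def bh_step_up_oracle(p):
    """Literal step-up definition: q_(k) = min_{j >= k} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        k = rank_idx + 1
        candidates = [p[order[j - 1]] * m / j for j in range(k, m + 1)]
        q[i] = min(1.0, min(candidates))
    return q


def exhaustive_permutation_oracle(y, prs, C):
    """Exact permutation p by enumerating every PRS reordering."""
    Q, _ = np.linalg.qr(C)
    ry = residualize(Q, y)

    def pr2(p):
        rp = residualize(Q, p)
        return (ry @ rp) ** 2 / ((ry @ ry) * (rp @ rp))

    obs = pr2(prs)
    r2s = [pr2(prs[list(perm)]) for perm in itertools.permutations(range(len(y)))]
    return sum(r >= obs - 1e-15 for r in r2s) / len(r2s)


class TestFitPartialR2:
    def test_outcome_equal_to_prs_gives_one(self, rng):
        prs = rng.normal(size=30)
        r2, sign = fit_partial_r2(prs, prs)
        assert r2 == pytest.approx(1.0)
        assert sign == "+"

    def test_orthogonal_prs_gives_zero(self, rng):
        C = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        prs = rng.normal(size=50)
        # make prs exactly orthogonal (in-sample) to y and covariates
        basis, _ = np.linalg.qr(np.column_stack([np.ones(50), C, y]))
        prs = residualize(basis, prs)
        r2, _ = fit_partial_r2(y, prs, C)
        assert r2 == pytest.approx(0.0, abs=1e-20)

    def test_matches_two_rss_normal_equation_oracle(self, rng):
        """Fixed 8-observation fixture against explicit normal-equation solves."""
        n = 8
        C = rng.normal(size=(n, 2))
        prs = rng.normal(size=n)
        y = 0.4 * prs + C @ [0.3, -0.5] + rng.normal(size=n)
        r2, sign = fit_partial_r2(y, prs, C)

        X_red = with_intercept(C, n)
        X_full = np.column_stack([X_red, prs])
        rss = {}
        for name, X in (("red", X_red), ("full", X_full)):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            rss[name] = resid @ resid
        expected = (rss["red"] - rss["full"]) / rss["red"]
        assert r2 == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self, rng):
        n = 60
        C = rng.normal(size=(n, 3))
        prs = rng.normal(size=n)
        y = 0.2 * prs + rng.normal(size=n)
        r2, _ = fit_partial_r2(y, prs, C)
        r2_t, _ = fit_partial_r2(5 * y - 3, -2 * prs + 7, C)
        assert r2 == pytest.approx(r2_t, abs=1e-12)

    def test_invariant_to_covariate_recombination(self, rng):
        n = 60
        C = rng.normal(size=(n, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible recombination
        prs = rng.normal(size=n)
        y = 0.2 * prs + C @ [1.0, -1.0, 0.5] + rng.normal(size=n)
        r2, _ = fit_partial_r2(y, prs, C)
        r2_t, _ = fit_partial_r2(y, prs, C @ A)
        assert r2 == pytest.approx(r2_t, abs=1e-10)

    def test_sign_matches_partial_correlation(self, rng):
        n = 100
        C = rng.normal(size=(n, 2))
        prs = rng.normal(size=n)
        for coef in (0.5, -0.5):
            y = coef * prs + rng.normal(size=n) * 0.1
            _, sign = fit_partial_r2(y, prs, C)
            assert sign == ("+" if coef > 0 else "-")

    def test_collinear_design_names_columns(self, rng):
        n = 40
        x = rng.normal(size=n)
        C = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError):
            fit_partial_r2(rng.normal(size=n), rng.normal(size=n), C)


class TestPermutationTest:
    def test_boundary_of_add_one_estimator(self, rng):
        prs = rng.normal(size=50)
        res = permutation_test(prs, prs, B=999, seed=0)
        assert res["all"].p_value == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration(self, rng):
        n = 5
        y = rng.normal(size=n)
        prs = rng.normal(size=n)
        res = permutation_test(y, prs, exhaustive=True)
        C = with_intercept(None, n)
        assert res["all"].p_value == pytest.approx(
            exhaustive_permutation_oracle(y, prs, C)
        )
        assert res["all"].n_permutations == 120

    def test_seeded_determinism(self, rng):
        y = rng.normal(size=80)
        prs = rng.normal(size=80)
        p1 = permutation_test(y, prs, B=200, seed=42)["all"].p_value
        p2 = permutation_test(y, prs, B=200, seed=42)["all"].p_value
        assert p1 == p2

    def test_per_stratum_results(self, planted_cohort):
        y = planted_cohort["outcome"].to_numpy()
        prs = planted_cohort["PRS"].to_numpy()
        sex = planted_cohort["sex"].to_numpy()
        res = permutation_test(y, prs, strata_labels=sex, B=499, seed=1)
        assert set(res) == {"male", "female", "all"}
        assert res["male"].p_value <= 0.01  # planted male-only effect
        assert res["female"].p_value > 0.05

    def test_small_stratum_skipped_with_warning(self, rng, caplog):
        y = rng.normal(size=30)
        prs = rng.normal(size=30)
        labels = np.array(["big"] * 28 + ["tiny"] * 2)
        with caplog.at_level("WARNING"):
            res = permutation_test(y, prs, strata_labels=labels, B=50, seed=0)
        assert "tiny" not in res
        assert any("tiny" in m for m in caplog.messages)

    def test_within_stratum_option_valid(self, planted_cohort):
        y = planted_cohort["outcome"].to_numpy()
        prs = planted_cohort["PRS"].to_numpy()
        sex = planted_cohort["sex"].to_numpy()
        res = permutation_test(
            y, prs, strata_labels=sex, B=199, seed=3, within_stratum=True
        )
        assert res["male"].p_value <= 0.05


class TestBhFdr:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        q = bh_fdr(np.ones(5))
        np.testing.assert_allclose(q, 1.0)
        assert not (q < 0.05).any()

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.0, 0.5])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), bh_step_up_oracle(p), atol=1e-12)


class TestAssociationScan:
    def test_grid_is_disorders_by_traits_by_strata(self, planted_cohort):
        table = run_association_scan(
            planted_cohort, ["PRS"], ["outcome"], B=99, seed=0
        )
        assert len(table) == 3
        assert set(table["stratum"]) == {"male", "female", "all"}

    def test_planted_male_effect_flagged_only_in_males(self, planted_cohort):
        table = run_association_scan(
            planted_cohort,
            ["PRS"],
            ["outcome", "mediator"],
            B=499,
            seed=0,
            fdr_family=("disorder", "stratum"),
        ).set_index(["trait", "stratum"])
        assert table.loc[("outcome", "male"), "fdr_q"] < 0.05
        assert table.loc[("outcome", "female"), "fdr_q"] > 0.05

    def test_missing_column_fails_before_compute(self, planted_cohort):
        with pytest.raises(ValidationError, match="missing"):
            run_association_scan(planted_cohort, ["PRS"], ["no_such_trait"], B=10)

    def test_volumetric_covariate_changes_design(self, planted_cohort):
        spec = CovariateSpec(volumetric_traits=frozenset({"outcome"}))
        cols = spec.columns_for("outcome", "male")
        assert "headsize" in cols
        assert "headsize" not in spec.columns_for("mediator", "male")
        assert "sex" in spec.columns_for("outcome", "all")
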