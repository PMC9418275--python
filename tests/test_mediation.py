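import itertools

import numpy as np
import pytest

from prstrata import (
    CollinearityError,
    DegenerateDataError,
    SimulationConfig,
    ValidationError,
    bootstrap_mediation,
    classify_mediator,
    fit_paths,
    mediation_r2,
    run_mediation,
    sign_concordance,
    simulate_cohort,
)
from prstrata.mediation import TRI_STATES, TYPE_LABELS


class TestFitPaths:
    def test_near_noiseless_chain(self, rng):
        p = rng.normal(size=300)
        m = 2 * p + 1e-7 * rng.normal(size=300)
        y = 3 * m
        paths = fit_paths(y, m, p)
        assert paths.a == pytest.approx(2.0, abs=1e-5)
        assert paths.b == pytest.approx(3.0, abs=1e-5)
        assert paths.c == pytest.approx(6.0, abs=1e-5)
        assert paths.c_prime == pytest.approx(0.0, abs=1e-4)

    def test_exactly_collinear_mediator_rejected(self, rng):
        p = rng.normal(size=100)
        with pytest.raises(CollinearityError):
            fit_paths(3 * 2 * p, 2 * p, p)

    def test_noise_mediator_leaves_total_effect_direct(self, rng):
        n = 5_000
        p = rng.normal(size=n)
        m = rng.normal(size=n)  # generative b = 0, a = 0
        y = 0.5 * p + rng.normal(size=n)
        paths = fit_paths(y, m, p)
        assert paths.c == pytest.approx(paths.c_prime, abs=0.01)
        assert paths.ab == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("k_cov", [0, 3])
    def test_ols_identity_on_arbitrary_data(self, k_cov):
        """c - c' = a*b exactly whenever the three fits share covariates."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = 50
            C = rng.normal(size=(n, k_cov)) if k_cov else None
            p = rng.normal(size=n)
            m = rng.normal(size=n)
            y = rng.normal(size=n)
            paths = fit_paths(y, m, p, C)
            assert abs(paths.c - paths.c_prime - paths.a * paths.b) < 1e-8


class TestBootstrapMediation:
    def test_near_noiseless_chain_ci_degenerate(self, rng):
        # outcome an exact function of the mediator: the only sampling noise
        # left is the tiny jitter that keeps the design identifiable
        p = rng.normal(size=200)
        m = 2 * p + 1e-4 * rng.normal(size=200)
        y = 3 * m
        boot = bootstrap_mediation(y, m, p, B=200, seed=0)
        assert boot.ci_high - boot.ci_low < 1e-3
        assert boot.ab == pytest.approx(6.0, abs=1e-3)
        assert boot.significant

    def test_point_estimate_inside_ci_and_deterministic(self, rng):
        n = 800
        p = rng.normal(size=n)
        m = 0.3 * p + rng.normal(size=n)
        y = 0.4 * m + rng.normal(size=n)
        b1 = bootstrap_mediation(y, m, p, B=300, seed=9)
        b2 = bootstrap_mediation(y, m, p, B=300, seed=9)
        assert b1.ci_low <= b1.ab <= b1.ci_high
        assert (b1.ci_low, b1.ci_high, b1.p_value) == (b2.ci_low, b2.ci_high, b2.p_value)
        assert b1.ci_low <= 0.12 <= b1.ci_high  # generative ab

    def test_null_indirect_effect_not_flagged(self, rng):
        n = 2_000
        p = rng.normal(size=n)
        m = 0.4 * p + rng.normal(size=n)
        y = rng.normal(size=n)  # b = 0
        boot = bootstrap_mediation(y, m, p, B=300, seed=4)
        assert boot.ci_low <= 0.0 <= boot.ci_high
        assert not boot.significant


class TestMediationR2:
    def test_zero_b_path_gives_zero_indirect_share(self, rng):
        n = 500
        p = rng.normal(size=n)
        m = 0.5 * p + rng.normal(size=n)
        y = rng.normal(size=n)
        r2_ab, _ = mediation_r2(y, m, p)
        assert r2_ab < 0.01

    def test_matches_manual_standardized_computation(self, rng):
        n = 300
        C = rng.normal(size=(n, 2))
        p = rng.normal(size=n)
        m = 0.5 * p + C @ [0.2, -0.1] + rng.normal(size=n)
        y = 0.4 * m + 0.2 * p + rng.normal(size=n)
        r2_ab, r2_cp = mediation_r2(y, m, p, C)

        X = np.column_stack([np.ones(n), C])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        rp, rm, ry = (v - H @ v for v in (p, m, y))
        rp, rm, ry = (v / v.std() for v in (rp, rm, ry))
        a_std = np.linalg.lstsq(rp[:, None], rm, rcond=None)[0][0]
        b_std = np.linalg.lstsq(np.column_stack([rp, rm]), ry, rcond=None)[0][1]
        assert r2_ab == pytest.approx((a_std * b_std) ** 2, abs=1e-12)
        assert 0 <= r2_cp <= 1

    def test_recovers_squared_indirect_path_in_standardized_model(self):
        """With unit-variance mediator and outcome the indirect variance
        share approaches (a*b)^2."""
        a, b = 0.5, 0.5
        cfg = SimulationConfig(
            n_individuals=20_000,
            n_variants=50,
            effect_a=(a, a),
            effect_b=(b, b),
            noise_sd_mediator=float(np.sqrt(1 - a**2)),
            noise_sd_outcome=float(np.sqrt(1 - (a * b) ** 2 - b**2 * (1 - a**2))),
            seed=31,
        )
        cohort = simulate_cohort(cfg)
        r2_ab, _ = mediation_r2(
            cohort["outcome"], cohort["mediator"], cohort["PRS"]
        )
        assert r2_ab == pytest.approx((a * b) ** 2, abs=0.01)

    def test_zero_residual_variance_rejected(self, rng):
        p = rng.normal(size=50)
        with pytest.raises(DegenerateDataError):
            mediation_r2(rng.normal(size=50), np.zeros(50), p)


class TestClassifyMediator:
    def test_quoted_type1_pattern(self):
        # male indirect significantly negative, female nonsignificant,
        # direct effects negative in both sexes
        assert classify_mediator("sig_neg", "ns", "sig_neg", "sig_neg") == "type1"

    def test_quoted_type2_pattern_takes_precedence(self):
        # female indirect significantly positive while male nonsignificant;
        # also cancel-out-eligible (female ab opposes female c') but type2
        # wins by the documented precedence
        assert classify_mediator("ns", "sig_pos", "sig_neg", "sig_neg") == "type2"

    def test_both_nonsignificant_is_other(self):
        assert classify_mediator("ns", "ns", "sig_neg", "sig_neg") == "other"

    def test_both_negative_needs_male_stronger_for_type1(self):
        args = ("sig_neg", "sig_neg", "sig_neg", "sig_neg")
        assert classify_mediator(*args, ab_stronger_sex="male") == "type1"
        assert classify_mediator(*args, ab_stronger_sex="female") == "other"

    def test_cancel_out_on_opposing_signs(self):
        assert classify_mediator("sig_pos", "ns", "sig_neg", "ns") == "cancel_out"

    def test_total_and_deterministic_over_grid(self):
        """Every tri-state combination maps to exactly one known label,
        and repeated calls agree."""
        for combo in itertools.product(TRI_STATES, repeat=4):
            for stronger in (None, "male", "female"):
                first = classify_mediator(*combo, ab_stronger_sex=stronger)
                assert first in TYPE_LABELS
                assert first == classify_mediator(*combo, ab_stronger_sex=stronger)

    def test_malformed_states_rejected(self):
        with pytest.raises(ValidationError):
            classify_mediator("positive", "ns", "ns", "ns")


class TestSignConcordance:
    def test_perfect_concordance_exact_tail(self):
        res = sign_concordance([1.0] * 10, [0.5] * 10)
        assert res.proportion == 1.0
        assert res.p_value == pytest.approx(2.0**-10)

    def test_half_concordance_exact_tail(self):
        d = [1.0] * 10
        r = [1.0] * 5 + [-1.0] * 5
        res = sign_concordance(d, r)
        assert res.proportion == 0.5
        assert res.p_value == pytest.approx(638 / 1024)  # P(X >= 5 | 10, 1/2)

    def test_sign_flip_symmetry(self, rng):
        d = rng.normal(size=30)
        r = rng.normal(size=30)
        res = sign_concordance(d, r)
        flipped = sign_concordance(d, -r)
        assert flipped.n_concordant == res.n_total - res.n_concordant

    def test_zero_effects_excluded_and_counted(self):
        res = sign_concordance([1.0, 0.0, -1.0], [1.0, 1.0, -1.0])
        assert res.n_total == 2 and res.n_excluded_zero == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            sign_concordance([1.0], [1.0, 2.0])


class TestRunMediation:
    def test_male_specific_indirect_path_labelled_type1(self, mediated_cohort):
        """Planted a_male=0.4/a_female=0, shared negative-direction outcome
        paths: the mediator should classify as type1-compatible."""
        cfg_cohort = mediated_cohort.copy()
        # flip outcome so the indirect effect is negative, as in the
        # disorder-PRS -> imaging -> cognition setting the labels describe
        cfg_cohort["outcome"] = -cfg_cohort["outcome"]
        table = run_mediation(
            cfg_cohort, ["mediator"], outcome="outcome", prs="PRS", B=150, seed=3
        )
        assert set(table["sex"]) == {"male", "female"}
        male = table[table["sex"] == "male"].iloc[0]
        female = table[table["sex"] == "female"].iloc[0]
        assert male["ab"] < 0 and male["ab_state"] == "sig_neg"
        assert female["ab_state"] == "ns"
        assert male["type_label"] == "type1"
        assert male["ab_stronger_sex"] == "male"

    def test_missing_column_rejected(self, mediated_cohort):
        with pytest.raises(ValidationError, match="missing"):
            run_mediation(mediated_cohort, ["ghost"], outcome="outcome", prs="PRS", B=10)
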