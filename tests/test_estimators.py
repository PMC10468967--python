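"""Wald ratio, IVW, Cochran Q, MR-Egger and OR/CI conversions."""

import numpy as np
import pytest

import mrtriad as m
from .conftest import make_instruments


class TestWaldRatio:
    def test_ratio_and_scaled_se(self):
        r = m.wald_ratio(0.5, 0.05, 0.25, 0.10)
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)
        assert r.nsnp == 1 and r.method == "wald_ratio"

    def test_zero_outcome_effect(self):
        r = m.wald_ratio(1.0, 0.1, 0.0, 0.3)
        assert r.beta == 0.0 and r.se == pytest.approx(0.3)
        assert r.pval == pytest.approx(1.0)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(ZeroDivisionError):
            m.wald_ratio(0.0, 0.1, 0.2, 0.3)

    def test_second_order_se_against_monte_carlo(self):
        """Second-order delta SE should track the empirical ratio SD and
        improve on the first-order SE when the exposure beta is noisy."""
        b_gx, se_gx, b_gy, se_gy = 1.0, 0.05, 0.5, 0.1
        rng = np.random.default_rng(42)
        draws = (b_gy + rng.normal(0, se_gy, 10**5)) / \
                (b_gx + rng.normal(0, se_gx, 10**5))
        empirical = draws.std()
        first = m.wald_ratio(b_gx, se_gx, b_gy, se_gy).se
        second = m.wald_ratio(b_gx, se_gx, b_gy, se_gy, second_order=True).se
        assert second == pytest.approx(empirical, rel=0.05)
        assert abs(second - empirical) < abs(first - empirical)


class TestIvw:
    def test_identical_ratios_q_zero(self):
        iv = make_instruments([1, 1, 1], [1e-6] * 3, [0.2] * 3, [0.1] * 3)
        r, het = m.ivw_estimate(iv, mode="fixed")
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1 / np.sqrt(3))
        assert het.Q == pytest.approx(0.0, abs=1e-20)

    def test_two_instrument_hand_arithmetic(self):
        # ratios (0.1, se 0.1) and (0.4, se 0.2): weighted mean and Q by hand
        iv = make_instruments([1, 1], [1e-6] * 2, [0.1, 0.4], [0.1, 0.2])
        r, het = m.ivw_estimate(iv, mode="fixed")
        assert r.beta == pytest.approx(0.16)
        assert r.se == pytest.approx(125 ** -0.5)
        assert het.Q == pytest.approx(1.80)
        assert het.df == 1

    def test_single_instrument_directs_to_wald(self):
        iv = make_instruments([1], [0.1], [0.2], [0.1])
        with pytest.raises(ValueError, match="wald_ratio"):
            m.ivw_estimate(iv)

    def test_equal_precision_equals_unweighted_mean_and_root_k_se(self):
        rng = np.random.default_rng(5)
        for k in (2, 5, 10):
            ratios = rng.normal(0.3, 0.05, k)
            iv = make_instruments(np.ones(k), np.full(k, 1e-6), ratios,
                                  np.full(k, 0.2))
            r, _ = m.ivw_estimate(iv, mode="fixed")
            assert r.beta == pytest.approx(ratios.mean())
            assert r.se == pytest.approx(0.2 / np.sqrt(k))

    def test_q_invariant_under_reordering(self):
        rng = np.random.default_rng(6)
        bx, by = rng.uniform(0.05, 0.2, 6), rng.normal(0.05, 0.02, 6)
        se = rng.uniform(0.01, 0.05, 6)
        iv = make_instruments(bx, np.full(6, 1e-3), by, se)
        perm = rng.permutation(6)
        iv2 = make_instruments(bx[perm], np.full(6, 1e-3), by[perm], se[perm])
        _, het1 = m.ivw_estimate(iv)
        _, het2 = m.ivw_estimate(iv2)
        assert het1.Q == pytest.approx(het2.Q, rel=1e-12)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(8)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k = 5
            iv = make_instruments(rng.uniform(0.05, 0.2, k), np.full(k, 1e-3),
                                  rng.normal(0.02, 0.05, k), rng.uniform(0.01, 0.1, k))
            fixed, _ = m.ivw_estimate(iv, mode="fixed")
            random_, _ = m.ivw_estimate(iv, mode="multiplicative_random")
            assert random_.se >= fixed.se - 1e-15
            assert random_.beta == pytest.approx(fixed.beta)


class TestEgger:
    def test_exact_linear_fit_recovers_intercept_and_slope(self):
        x = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        y = 0.1 + 0.5 * x
        iv = make_instruments(x, np.full(5, 1e-3), y, np.array([0.1, 0.2, 0.05, 0.3, 0.15]))
        e = m.egger_regression(iv)
        assert e.intercept == pytest.approx(0.1, abs=1e-12)
        assert e.slope == pytest.approx(0.5, abs=1e-12)

    def test_against_normal_equations_oracle(self):
        """WLS on 5 points checked against an independent matrix-algebra fit."""
        rng = np.random.default_rng(11)
        x = rng.uniform(0.05, 0.3, 5)
        y = 0.02 + 0.4 * x + rng.normal(0, 0.02, 5)
        se_y = rng.uniform(0.05, 0.2, 5)
        iv = make_instruments(x, np.full(5, 1e-3), y, se_y)
        e = m.egger_regression(iv)

        W = np.diag(1.0 / se_y**2)
        X = np.column_stack([np.ones(5), x])
        xtwx = X.T @ W @ X
        params = np.linalg.solve(xtwx, X.T @ W @ y)
        resid = y - X @ params
        sigma2 = float(resid @ W @ resid) / (5 - 2)
        bse = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtwx)))
        assert e.intercept == pytest.approx(params[0], abs=1e-10)
        assert e.slope == pytest.approx(params[1], abs=1e-10)
        assert e.intercept_se == pytest.approx(bse[0], abs=1e-10)
        assert e.slope_se == pytest.approx(bse[1], abs=1e-10)

    def test_orientation_makes_exposure_betas_non_negative(self):
        x = np.array([0.1, -0.15, 0.2])
        y = 0.5 * x  # no pleiotropy; flipping pairs preserves the line
        iv = make_instruments(x, np.full(3, 1e-3), y, np.full(3, 0.1))
        e = m.egger_regression(iv)
        assert e.intercept == pytest.approx(0.0, abs=1e-12)
        assert e.slope == pytest.approx(0.5, abs=1e-12)

    def test_slope_equals_ivw_when_intercept_is_zero(self):
        x = np.array([0.05, 0.12, 0.2, 0.28])
        y = 0.7 * x  # exact fit through origin
        iv = make_instruments(x, np.full(4, 1e-3), y, np.full(4, 0.1))
        e = m.egger_regression(iv)
        ivw, _ = m.ivw_estimate(iv, mode="fixed")
        assert e.intercept == pytest.approx(0.0, abs=1e-12)
        assert e.slope == pytest.approx(ivw.beta, abs=1e-10)

    def test_too_few_instruments(self):
        iv = make_instruments([0.1, 0.2], [1e-3] * 2, [0.05, 0.1], [0.1] * 2)
        with pytest.raises(ValueError, match="3"):
            m.egger_regression(iv)


class TestOrCi:
    @pytest.mark.parametrize("beta,se,expected", [
        (-0.346, 0.135, (0.708, 0.544, 0.921)),
        (0.683, 0.283, (1.98, 1.137, 3.448)),
    ])
    def test_published_rows_reproduced(self, beta, se, expected):
        or_, lo, hi = m.effect_to_or_ci(beta, se)
        assert or_ == pytest.approx(expected[0], abs=2e-3)
        assert lo == pytest.approx(expected[1], abs=2e-3)
        assert hi == pytest.approx(expected[2], abs=2e-3)

    def test_null_effect_symmetric_ci(self):
        or_, lo, hi = m.effect_to_or_ci(0.0, 0.3)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)
        assert lo < or_ < hi

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            m.effect_to_or_ci(0.1, 0.0)


class TestRunUnivariable:
    def test_dispatch_by_instrument_count(self):
        one = m.simulate_exposure_outcome(m.SimConfig(
            n_exposures=1, n_causal=1, k_min=1, k_max=1, n_satellites=0,
            n_null_variants=5, chains=(), instrument_effect_range=(0.08, 0.1),
            seed=4))
        res = m.run_univariable_mr(one.exposures["exposure_01"], one.outcome,
                                   one.ld, levels=["e5"])
        if res:  # the single instrument may be a dropped palindrome
            assert res[0].method == "wald_ratio"
            assert res[0].q_pval is None and res[0].p_pleio is None

        many = m.simulate_exposure_outcome(m.SimConfig(
            n_exposures=1, n_causal=1, k_min=14, k_max=14, n_satellites=0,
            n_null_variants=5, chains=(), instrument_effect_range=(0.08, 0.12),
            eaf_range=(0.3, 0.7), seed=4))
        res = m.run_univariable_mr(many.exposures["exposure_01"], many.outcome,
                                   many.ld, levels=["e5"])
        assert res[0].method == "ivw" and res[0].nsnp >= 3
        assert res[0].q_pval is not None and res[0].p_pleio is not None

    def test_planted_effect_recovered_within_3_se(self):
        study = m.simulate_exposure_outcome(m.SimConfig(
            n_exposures=1, n_causal=1, theta_causal=0.5, k_min=20, k_max=20,
            n_satellites=0, n_null_variants=0, chains=(), seed=12))
        res = m.run_univariable_mr(study.exposures["exposure_01"],
                                   study.outcome, study.ld, levels=["e5"])
        r = res[0]
        assert abs(r.beta - 0.5) <= 3 * r.se

    def test_or_ci_consistency_invariant(self):
        study = m.simulate_exposure_outcome(
            m.SimConfig(n_exposures=3, n_causal=2, chains=(), seed=9))
        for eid, table in study.exposures.items():
            for r in m.run_univariable_mr(table, study.outcome, study.ld):
                assert r.or_ == pytest.approx(np.exp(r.beta))
                assert r.ci_low < r.or_ < r.ci_high
                assert r.ci_low == pytest.approx(np.exp(r.beta - 1.96 * r.se))
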