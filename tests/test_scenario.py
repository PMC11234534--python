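"""Calibration of the normal linear predictor to (prevalence, c-statistic)."""

import numpy as np
import pytest
from scipy.special import expit, logit

from predsize.dgm import equal_strength_spec, simulate_dataset
from predsize.metrics import c_statistic
from predsize.scenario import (
    ScenarioSpec,
    approx_r2cs,
    calibrate_scenario,
    coefficients_from_lp,
    induced_cstatistic,
    induced_prevalence,
    r2cs_from_large_sample,
    solve_lp_distribution,
)


class TestInducedPrevalence:
    def test_degenerate_lp(self):
        assert induced_prevalence(0.0, 0.0) == pytest.approx(0.5)
        assert induced_prevalence(logit(0.1), 0.0) == pytest.approx(0.1)

    def test_matches_monte_carlo_oracle(self, rng):
        mu, sigma = 0.0, 2.0
        draws = expit(rng.normal(mu, sigma, size=10_000_000))
        mc, se = draws.mean(), draws.std() / np.sqrt(draws.size)
        assert abs(induced_prevalence(mu, sigma) - mc) < 3 * se

    def test_increasing_in_mu(self):
        vals = [induced_prevalence(m, 1.5) for m in (-2, -1, 0, 1)]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            induced_prevalence(np.nan, 1.0)
        with pytest.raises(ValueError):
            induced_prevalence(0.0, -1.0)


class TestInducedCstatistic:
    def test_no_discrimination_at_zero_sigma(self):
        assert induced_cstatistic(-3.0, 0.0) == 0.5
        assert induced_cstatistic(2.0, 0.0) == 0.5

    def test_matches_simulation_oracle(self, rng):
        # c-statistic of the true risks on a large sample drawn from the model
        mu, sigma = 0.0, 1.0
        eta = rng.normal(mu, sigma, size=400_000)
        y = (rng.random(eta.size) < expit(eta)).astype(int)
        c_hat = c_statistic(expit(eta), y)
        n1, n0 = int(y.sum()), int((1 - y).sum())
        # Hanley-McNeil standard error of the empirical AUC
        c = c_hat
        q1, q2 = c / (2 - c), 2 * c**2 / (1 + c)
        se = np.sqrt(
            (c * (1 - c) + (n1 - 1) * (q1 - c**2) + (n0 - 1) * (q2 - c**2))
            / (n1 * n0)
        )
        assert abs(induced_cstatistic(mu, sigma) - c_hat) < 3 * se

    def test_increasing_in_sigma(self):
        for mu in (-2.0, 0.0, 1.0):
            assert induced_cstatistic(mu, 2.0) > induced_cstatistic(mu, 1.0)


class TestSolveLpDistribution:
    def test_symmetric_null_limit(self):
        mu, sigma = solve_lp_distribution(0.5, 0.501)
        assert abs(mu) < 0.01
        assert sigma < 0.01

    @pytest.mark.parametrize("phi,c", [(0.1, 0.85), (0.3, 0.7), (0.174, 0.89)])
    def test_self_consistent(self, phi, c):
        mu, sigma = solve_lp_distribution(phi, c, tol=1e-6)
        assert induced_prevalence(mu, sigma) == pytest.approx(phi, abs=1e-6)
        assert induced_cstatistic(mu, sigma) == pytest.approx(c, abs=1e-6)

    def test_large_sample_roundtrip(self, example_spec, example_model):
        data = simulate_dataset(example_model, example_spec, 1_000_000, seed=11)
        assert data.y.mean() == pytest.approx(0.174, abs=0.002)
        c_emp = c_statistic(data.pi_true, data.y)
        assert c_emp == pytest.approx(0.89, abs=0.003)


class TestR2CoxSnell:
    def test_vanishes_without_discrimination(self):
        assert approx_r2cs(0.3, 0.500001) == pytest.approx(0.0, abs=1e-4)
        assert approx_r2cs(0.3, 0.500001, method="marginal") == pytest.approx(
            0.0, abs=1e-4
        )

    def test_worked_example_value(self):
        assert approx_r2cs(0.174, 0.89) == pytest.approx(0.29, abs=0.005)

    def test_monotone_in_c(self):
        vals = [approx_r2cs(0.3, c) for c in (0.6, 0.7, 0.8, 0.9)]
        assert np.all(np.diff(vals) > 0)

    def test_methods_agree_moderate_strength(self):
        # binormal and marginal-normal derivations nearly coincide below c=0.9
        for phi, c in [(0.1, 0.75), (0.3, 0.8), (0.5, 0.65)]:
            assert approx_r2cs(phi, c) == pytest.approx(
                approx_r2cs(phi, c, method="marginal"), abs=0.01
            )

    def test_agrees_with_large_sample_estimate(self):
        spec = equal_strength_spec(0.3, 0.75, 8)
        r2_sim = r2cs_from_large_sample(spec, N=400_000, seed=3)
        assert approx_r2cs(0.3, 0.75) == pytest.approx(r2_sim, abs=0.012)

    def test_large_sample_requires_big_n(self):
        with pytest.raises(ValueError):
            r2cs_from_large_sample(equal_strength_spec(0.3, 0.7, 4), N=1000)


class TestCoefficientsFromLp:
    def test_single_active_predictor(self):
        spec = ScenarioSpec(0.3, 0.7, 3, relative_strengths=[1.0, 0.0, 0.0])
        m = coefficients_from_lp(spec, mu=-1.0, sigma=0.8)
        assert m.scale_f == pytest.approx(0.8)
        assert m.beta0 == pytest.approx(-1.0)
        np.testing.assert_allclose(m.beta, [0.8, 0.0, 0.0])

    @pytest.mark.parametrize("kind", ["continuous_main", "binary"])
    def test_lp_variance_reproduced(self, kind, rng):
        from predsize.dgm import main_study_spec

        if kind == "continuous_main":
            spec = main_study_spec(0.1, 0.8)
        else:
            spec = ScenarioSpec(0.1, 0.8, 6, predictor_kind="binary")
        model = calibrate_scenario(spec)
        data = simulate_dataset(model, spec, 1_000_000, seed=5)
        var_emp = data.lp_true.var()
        assert var_emp == pytest.approx(model.sigma**2, rel=0.01)

    def test_no_signal_rejected(self):
        spec = ScenarioSpec(0.3, 0.7, 2, relative_strengths=[1.0, 0.0])
        spec.relative_strengths = np.zeros(2)  # bypass ctor check
        with pytest.raises(ValueError):
            coefficients_from_lp(spec, 0.0, 1.0)


class TestScenarioSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec(1.2, 0.8, 3)
        with pytest.raises(ValueError):
            ScenarioSpec(0.3, 0.4, 3)
        with pytest.raises(ValueError):
            ScenarioSpec(0.3, 0.8, 3, relative_strengths=[1.0, 1.0])
        with pytest.raises(ValueError):
            ScenarioSpec(0.3, 0.8, 2, correlation=[[1.0, 0.2], [0.3, 1.0]])

    def test_json_roundtrip(self, example_spec):
        restored = ScenarioSpec.from_json(example_spec.to_json())
        assert restored.prevalence == example_spec.prevalence
        np.testing.assert_array_equal(
            restored.correlation, example_spec.correlation
        )
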