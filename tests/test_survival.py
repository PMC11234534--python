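"""Exponential-survival DGM, concordance and survival calibration slope."""

import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from predsize.dgm import equal_strength_spec, main_study_spec
from predsize.scenario import LinearPredictorModel
from predsize.survival import (
    calibrate_censor_time,
    censorfree_cindex,
    evaluate_survival_performance,
    harrell_cindex,
    simulate_survival,
    solve_lp_sigma_for_cindex,
    survival_calibration_slope,
    survival_lp_model,
)


def null_model(p):
    return LinearPredictorModel(
        mu=0.0, sigma=0.0, beta0=0.0, scale_f=0.0,
        beta=np.zeros(p), r2cs=0.0,
    )


def brute_force_cindex(lp, time, event):
    """All comparable pairs under right censoring; lp ties score 0.5."""
    num = den = 0.0
    n = len(lp)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if lp[i] > lp[j]:
                    num += 1
                elif lp[i] == lp[j]:
                    num += 0.5
    return num / den


class TestConcordanceCalibration:
    def test_no_signal(self):
        assert censorfree_cindex(0.0) == 0.5

    @pytest.mark.parametrize("c", [0.65, 0.75, 0.9])
    def test_sigma_roundtrip(self, c):
        sigma = solve_lp_sigma_for_cindex(c)
        assert censorfree_cindex(sigma) == pytest.approx(c, abs=1e-6)

    def test_empirical_cindex_matches_target(self):
        spec = main_study_spec(0.5, 0.75)  # prevalence unused for survival
        model = survival_lp_model(spec, 0.75)
        d = simulate_survival(model, spec, 60_000, 0.1, 1e12, seed=6)
        assert harrell_cindex(d.lp_true, d.time, d.event) == pytest.approx(
            0.75, abs=0.005
        )


class TestSimulateSurvival:
    def test_null_times_are_exponential(self):
        spec = equal_strength_spec(0.5, 0.7, 3)
        d = simulate_survival(null_model(3), spec, 100_000, 0.5, 1e12, seed=7)
        assert d.uncensored_prop == 1.0
        assert kstest(d.time, "expon", args=(0, 2.0)).pvalue > 0.01

    def test_higher_lp_shortens_survival(self):
        spec = main_study_spec(0.5, 0.8)
        model = survival_lp_model(spec, 0.8)
        d = simulate_survival(model, spec, 20_000, 0.1, 1e12, seed=8)
        assert spearmanr(d.lp_true, d.time).statistic < -0.3

    def test_censoring_flags(self):
        spec = main_study_spec(0.5, 0.8)
        model = survival_lp_model(spec, 0.8)
        d = simulate_survival(model, spec, 5000, 0.1, 5.0, seed=9)
        assert np.all(d.time <= 5.0)
        assert np.array_equal(d.event == 0, d.time == 5.0)


class TestCalibrateCensorTime:
    def test_no_censoring_limit(self):
        spec = main_study_spec(0.5, 0.8)
        model = survival_lp_model(spec, 0.8)
        assert calibrate_censor_time(model, spec, 0.1, 1.0) == np.inf

    def test_null_median(self):
        spec = equal_strength_spec(0.5, 0.7, 3)
        t = calibrate_censor_time(null_model(3), spec, 0.4, 0.5)
        assert t == pytest.approx(np.log(2) / 0.4, rel=1e-6)

    @pytest.mark.parametrize("target", [0.1, 0.5, 0.9])
    def test_empirical_uncensored_proportion(self, target):
        spec = main_study_spec(0.5, 0.85)
        model = survival_lp_model(spec, 0.85)
        t = calibrate_censor_time(model, spec, 0.1, target)
        d = simulate_survival(model, spec, 1_000_000, 0.1, t, seed=10)
        assert d.uncensored_prop == pytest.approx(target, abs=0.005)

    def test_invalid_target(self):
        spec = main_study_spec(0.5, 0.8)
        with pytest.raises(ValueError):
            calibrate_censor_time(survival_lp_model(spec, 0.8), spec, 0.1, 0.0)


class TestHarrellCindex:
    def test_perfectly_anti_monotone(self):
        lp = np.arange(10.0)
        time = 10.0 - lp
        assert harrell_cindex(lp, time, np.ones(10)) == 1.0

    def test_random_lp_near_half(self, rng):
        lp = rng.standard_normal(4000)
        time = rng.exponential(size=4000)
        assert harrell_cindex(lp, time, np.ones(4000)) == pytest.approx(0.5, abs=0.03)

    def test_equals_brute_force_with_censoring(self, rng):
        n = 200
        lp = np.round(rng.standard_normal(n), 1)
        time = rng.exponential(size=n)
        event = (rng.random(n) < 0.6).astype(int)
        assert harrell_cindex(lp, time, event) == pytest.approx(
            brute_force_cindex(lp, time, event), abs=1e-12
        )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            harrell_cindex(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5))


class TestSurvivalCalibrationSlope:
    def test_true_model_slope_is_one(self):
        spec = main_study_spec(0.5, 0.8)
        model = survival_lp_model(spec, 0.8)
        d = simulate_survival(model, spec, 30_000, 0.1, 1e12, seed=12)
        assert survival_calibration_slope(d.lp_true, d.time, d.event) == pytest.approx(
            1.0, abs=0.05
        )

    def test_doubled_lp_halves_slope(self):
        spec = main_study_spec(0.5, 0.8)
        model = survival_lp_model(spec, 0.8)
        d = simulate_survival(model, spec, 30_000, 0.1, 1e12, seed=13)
        assert survival_calibration_slope(
            2.0 * d.lp_true, d.time, d.event
        ) == pytest.approx(0.5, abs=0.03)


def test_underestimation_worse_with_less_censoring():
    """At high model strength the calibration-formula size (with the
    survival R2_CS estimated under the same censoring) leaves the mean
    survival CS below target, and further below when more observations
    are uncensored."""
    from predsize.formulas import rvs1_n
    from predsize.survival import r2cs_survival_from_large_sample

    def cs_at_formula_n(uncensored):
        spec = main_study_spec(0.5, 0.85)
        model = survival_lp_model(spec, 0.85)
        ct = calibrate_censor_time(model, spec, 0.1, uncensored)
        r2 = r2cs_survival_from_large_sample(model, spec, 0.1, ct, N=40_000, seed=2)
        n = rvs1_n(12, 0.9, r2, rounding="up10").n_rounded
        res = evaluate_survival_performance(
            spec, n, c_index=0.85, uncensored=uncensored,
            n_sim=25, n_val=3000, seed=30,
        )
        return res["mean_cs"]

    cs_half = cs_at_formula_n(0.5)
    cs_most = cs_at_formula_n(0.9)
    assert cs_most < cs_half < 0.9
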