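"""Extended Kalman filter: step mechanics, estimation runs, and summaries."""

import numpy as np
import pandas as pd
import pytest

from heatstrain.core_temp_kf import (
    KfParams,
    bias_vs_reference,
    exertion_summary,
    kf_step,
    run_estimator,
)
from heatstrain.synthetic_wearer import hr_from_observation_model


@pytest.fixture
def params():
    return KfParams()


def rmse(a, b):
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


class TestStep:
    def test_missing_observation_applies_time_update_only(self, params):
        ct, v = kf_step((37.0, 0.01), None, params)
        assert ct == 37.0
        assert v == pytest.approx(0.01 + params.gamma**2)

    def test_out_of_range_hr_treated_as_missing(self, params, caplog):
        with caplog.at_level("WARNING"):
            ct, v = kf_step((37.0, 0.01), 230.0, params)
        assert ct == 37.0 and v == pytest.approx(0.01 + params.gamma**2)
        assert any("missing" in m for m in caplog.messages)

    def test_huge_sigma_limit_equals_time_update(self):
        loose = KfParams(sigma=1e9)
        ct, v = kf_step((37.0, 0.05), 120.0, loose)
        assert ct == pytest.approx(37.0, abs=1e-6)
        assert v == pytest.approx(0.05 + loose.gamma**2, rel=1e-6)

    def test_posterior_variance_never_exceeds_prior(self, params, rng):
        ct, v = 37.0, 0.0
        for hr in rng.uniform(60, 180, 200):
            v_prior = v + params.gamma**2
            ct, v = kf_step((ct, v), float(hr), params)
            assert v <= v_prior + 1e-15

    def test_variance_non_increasing_when_process_noise_vanishes(self):
        tiny = KfParams(gamma=1e-9, v0=0.05)
        ct, v = 37.0, tiny.v0
        history = [v]
        for _ in range(50):
            ct, v = kf_step((ct, v), 78.5, tiny)
            history.append(v)
        assert np.all(np.diff(history) <= 1e-12)

    def test_gap_variance_grows_exactly_linearly(self, params):
        ct, v = 37.0, 0.004
        k = 17
        for _ in range(k):
            ct, v = kf_step((ct, v), None, params)
        assert v == pytest.approx(0.004 + k * params.gamma**2, abs=1e-15)
        assert ct == 37.0


class TestParams:
    def test_observation_model_must_increase_on_physiologic_range(self):
        with pytest.raises(ValueError, match="increasing"):
            KfParams(a1=0.0, a2=-1.0, a0=100.0)

    def test_invert_is_the_right_inverse_of_observe(self, params):
        ct = np.linspace(36.5, 40.5, 9)
        np.testing.assert_allclose(params.invert(params.observe(ct)), ct, atol=1e-9)

    @pytest.mark.parametrize("kwargs", [{"gamma": 0.0}, {"sigma": 0.0}, {"v0": -1.0}])
    def test_invalid_noise_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KfParams(**kwargs)


class TestRun:
    def test_fixed_init_emits_37_before_any_update(self, params):
        trace = run_estimator(np.arange(10) * 60.0, np.full(10, 120.0), params)
        assert trace["ct_est"].iloc[0] == 37.0
        assert trace["ct_var"].iloc[0] == params.v0

    def test_first_reference_init(self, params):
        refs = pd.DataFrame({"timestamp": [0.0], "temp_c": [36.8]})
        trace = run_estimator(np.arange(5) * 60.0, np.full(5, 90.0), params,
                              init_mode="first_reference", reference_temps=refs)
        assert trace["ct_est"].iloc[0] == 36.8

    def test_empty_series_is_an_error(self, params):
        with pytest.raises(ValueError, match="empty"):
            run_estimator(np.array([]), np.array([]), params)

    def test_steady_state_stays_near_initialization(self, params):
        """Constant HR at m(37) keeps the estimate within ±0.05 degC over 3.5 h."""
        n = 210
        hr = np.full(n, float(params.observe(37.0)))
        trace = run_estimator(np.arange(n) * 60.0, hr, params)
        assert np.all(np.abs(trace["ct_est"] - 37.0) < 0.05)

    def test_time_shift_invariance(self, params, rng):
        n = 120
        hr = rng.uniform(70, 150, n)
        t = np.arange(n) * 60.0
        a = run_estimator(t, hr, params)
        b = run_estimator(t + 86400.0, hr, params)
        np.testing.assert_allclose(a["ct_est"], b["ct_est"])
        np.testing.assert_allclose(a["ct_var"], b["ct_var"])

    def test_internal_gaps_are_filled_and_flagged(self, params):
        t = np.array([0.0, 60.0, 240.0])
        hr = np.array([100.0, 100.0, 100.0])
        trace = run_estimator(t, hr, params)
        assert len(trace) == 5
        assert trace["gap"].tolist() == [False, False, True, True, False]

    def test_recovery_of_a_slow_ramp(self, params):
        """8 h of observations from the filter's own model: RMSE <= 0.3 degC."""
        n = 480
        ct_true = 37.0 + 1.3 * np.arange(n) / n
        hr = hr_from_observation_model(ct_true, params, params.sigma, seed=7)
        trace = run_estimator(np.arange(n) * 60.0, hr, params)
        assert rmse(trace["ct_est"], ct_true) <= 0.3

    def test_rmse_decreases_with_observation_noise(self):
        n = 480
        ct_true = 37.0 + 1.3 * np.arange(n) / n
        errors = []
        for sigma in (5.0, 18.88, 40.0):
            p = KfParams(sigma=sigma)
            hr = hr_from_observation_model(ct_true, p, sigma, seed=7)
            trace = run_estimator(np.arange(n) * 60.0, hr, p)
            errors.append(rmse(trace["ct_est"], ct_true))
        assert errors[0] < errors[1] < errors[2]


class TestSummaries:
    def _trace(self, hr):
        hr = np.asarray(hr, float)
        return pd.DataFrame(
            {
                "timestamp": np.arange(hr.size) * 60.0,
                "hr_bpm": hr,
                "ct_est": np.full(hr.size, 37.5),
                "ct_var": np.full(hr.size, 0.01),
            }
        )

    def test_108_minutes_above_threshold_is_1p8_hours(self):
        hr = np.concatenate([np.full(108, 130.0), np.full(60, 100.0)])
        out = exertion_summary(self._trace(hr), threshold_bpm=125.0)
        assert out["time_above_threshold_h"] == pytest.approx(1.8)
        assert out["max_hr_bpm"] == 130.0

    def test_all_below_threshold_gives_zero(self):
        out = exertion_summary(self._trace(np.full(60, 100.0)), threshold_bpm=125.0)
        assert out["time_above_threshold_h"] == 0.0

    def test_threshold_at_validity_floor_counts_every_minute(self):
        hr = np.full(90, 100.0)
        out = exertion_summary(self._trace(hr), threshold_bpm=40.0)
        assert out["time_above_threshold_h"] == pytest.approx(90 / 60.0)

    def test_bias_zero_for_identical_trace(self):
        trace = self._trace(np.full(30, 100.0))
        refs = pd.DataFrame({"timestamp": [300.0, 900.0], "temp_c": [37.5, 37.5]})
        assert bias_vs_reference(trace, refs) == pytest.approx(0.0)

    def test_constant_offset_is_recovered(self):
        trace = self._trace(np.full(30, 100.0))
        refs = pd.DataFrame({"timestamp": [300.0, 600.0, 900.0], "temp_c": [37.0] * 3})
        assert bias_vs_reference(trace, refs) == pytest.approx(0.5)

    def test_no_usable_reference_is_an_error(self):
        trace = self._trace(np.full(10, 100.0))
        refs = pd.DataFrame({"timestamp": [1e6], "temp_c": [37.0]})
        with pytest.raises(ValueError):
            bias_vs_reference(trace, refs)

    @pytest.mark.parametrize("shift, sign", [(5.0, 1), (-5.0, -1)])
    def test_miscalibrated_offset_flips_bias_sign(self, shift, sign):
        """Shifting a0 shifts predicted HR, so the filter chases a core
        temperature offset whose sign matches the shift."""
        true_params = KfParams()
        n = 240
        ct_true = np.full(n, 37.6)
        hr = hr_from_observation_model(ct_true, true_params, 5.0, seed=3)
        biased = KfParams(a0=true_params.a0 - shift)  # model expects lower HR -> reads high
        trace = run_estimator(np.arange(n) * 60.0, hr, biased)
        refs = pd.DataFrame({"timestamp": np.arange(60, n, 30) * 60.0,
                             "temp_c": 37.6})
        assert np.sign(bias_vs_reference(trace, refs)) == sign
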