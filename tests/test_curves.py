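"""Normalisation, bump exclusion and log-logistic fitting."""

import numpy as np
import pytest
from sklearn.base import clone

from mothpupil import (
    BumpParams,
    KineticTruth,
    LogLogisticRegressor,
    NormalizedCurve,
    ReflectanceSeries,
    detect_bump,
    fit_log_logistic,
    log_logistic,
    normalize,
    simulate_induced_series,
    trim_to_rise,
)


def _corrected(times, values, **kw):
    return ReflectanceSeries(np.asarray(times, float), np.asarray(values, float), units="corrected", **kw)


def _opening_curve(bump=None, noise_seed=None, sigma=0.0):
    from mothpupil import IDENTITY_CAMERA, NoiseModel

    noise = NoiseModel(sigma, noise_seed) if noise_seed is not None else None
    series = simulate_induced_series(
        KineticTruth(-2.0, 1800.0), 5400.0, 60.0, bump=bump, calib=IDENTITY_CAMERA, noise=noise
    )
    return normalize(_corrected(series.times, series.values), direction="opening")


class TestLogLogistic:
    def test_zero_time_limits(self):
        assert log_logistic(0.0, 2.0, 300.0) == 1.0
        assert log_logistic(0.0, -2.0, 300.0) == 0.0

    def test_half_maximum_at_t50(self):
        assert log_logistic(300.0, 2.0, 300.0) == pytest.approx(0.5)
        assert log_logistic(1800.0, -3.1, 1800.0) == pytest.approx(0.5)

    def test_strictly_monotone(self):
        t = np.linspace(1, 1000, 500)
        assert np.all(np.diff(log_logistic(t, 2.0, 300.0)) < 0)
        assert np.all(np.diff(log_logistic(t, -2.0, 300.0)) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="t50"):
            log_logistic(1.0, 2.0, 0.0)
        with pytest.raises(ValueError, match="nonnegative"):
            log_logistic(-1.0, 2.0, 300.0)


class TestNormalize:
    def test_affine_map(self):
        out = normalize(_corrected([0, 1, 2], [2.0, 6.0, 10.0]))
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])
        assert out.times[0] == 0.0

    def test_output_range_exact(self, rng):
        out = normalize(_corrected(np.arange(30.0), rng.random(30)))
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0

    def test_idempotent_up_to_affine(self):
        series = _corrected(np.arange(5.0), [3.0, 4.0, 8.0, 2.0, 7.0])
        once = normalize(series)
        twice = normalize(_corrected(once.times, once.values))
        np.testing.assert_allclose(once.values, twice.values)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize(_corrected([0, 1, 2], [4.0, 4.0, 4.0]))

    def test_requires_corrected_units(self):
        raw = ReflectanceSeries(np.arange(3.0), np.array([1.0, 2.0, 3.0]), units="raw")
        with pytest.raises(ValueError, match="corrected"):
            normalize(raw)

    def test_direction_inference(self):
        assert normalize(_corrected([0, 1], [5.0, 1.0])).direction == "closing"
        assert normalize(_corrected([0, 1], [1.0, 5.0])).direction == "opening"


class TestDetectBump:
    def test_synthetic_bump_located_between_peak_and_t50(self, bump):
        curve = _opening_curve(bump=bump)
        ann = detect_bump(curve)
        assert ann.present
        assert bump.peak_time_s < ann.bump_end_time_s < 1800.0

    def test_detection_robust_to_noise(self, bump):
        curve = _opening_curve(bump=bump, noise_seed=7, sigma=0.03)
        ann = detect_bump(curve)
        assert ann.present
        assert bump.peak_time_s < ann.bump_end_time_s < 1800.0

    def test_pure_sigmoid_has_no_bump(self):
        ann = detect_bump(_opening_curve())
        assert not ann.present
        assert ann.bump_end_time_s == 0.0

    def test_flat_then_rise_has_no_bump(self):
        t = np.arange(0.0, 5400.0, 60.0)
        v = np.clip((t - 1200.0) / 2400.0, 0.0, 1.0)
        ann = detect_bump(NormalizedCurve(t, v, "opening"))
        assert not ann.present

    def test_window_larger_than_recording_rejected(self):
        curve = _opening_curve()
        with pytest.raises(ValueError, match="window"):
            detect_bump(curve, window_s=10_000.0)

    def test_closing_curves_rejected(self):
        t = np.arange(0.0, 900.0)
        curve = NormalizedCurve(t, log_logistic(np.maximum(t, 0.5), 2.0, 300.0), "closing")
        with pytest.raises(ValueError, match="opening"):
            detect_bump(curve)


class TestTrimToRise:
    def test_no_bump_is_identity(self):
        curve = _opening_curve()
        ann = detect_bump(curve)
        trimmed = trim_to_rise(curve, ann)
        np.testing.assert_allclose(trimmed.values, curve.values)
        np.testing.assert_allclose(trimmed.times, curve.times)

    def test_first_retained_value_is_zero(self, bump):
        curve = _opening_curve(bump=bump)
        trimmed = trim_to_rise(curve, detect_bump(curve))
        assert trimmed.values[0] == 0.0
        assert trimmed.times[0] == 0.0

    def test_retained_length_counts(self, bump):
        curve = _opening_curve(bump=bump)
        ann = detect_bump(curve)
        trimmed = trim_to_rise(curve, ann)
        assert len(trimmed) == len(curve) - int(np.sum(curve.times < ann.bump_end_time_s))

    def test_too_few_samples_rejected(self):
        from mothpupil import BumpAnnotation

        t = np.arange(0.0, 10.0)
        curve = NormalizedCurve(t, np.linspace(0, 1, 10), "opening")
        with pytest.raises(ValueError, match="samples"):
            trim_to_rise(curve, BumpAnnotation(True, 7.0, 0.5))


class TestFitLogLogistic:
    @pytest.mark.parametrize("b, t50", [(2.5, 300.0), (-2.5, 1800.0), (0.8, 120.0)])
    def test_exact_on_model_data(self, b, t50):
        t = np.arange(1.0, 901.0) * (t50 / 300.0)
        curve = NormalizedCurve(t, log_logistic(t, b, t50), "closing" if b > 0 else "opening")
        fit = fit_log_logistic(curve)
        assert fit.converged
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.t50 == pytest.approx(t50, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fitted_curve_halves_at_its_own_t50(self):
        t = np.arange(1.0, 901.0)
        fit = fit_log_logistic(NormalizedCurve(t, log_logistic(t, 2.0, 250.0), "closing"))
        assert fit(fit.t50) == pytest.approx(0.5)

    def test_monte_carlo_recovery_under_noise(self):
        # mean recovered parameters within 5% of the generating truth
        for b, t50, dur, dt, direction in [
            (2.5, 300.0, 900.0, 1.0, "closing"),
            (-2.5, 1800.0, 5400.0, 60.0, "opening"),
        ]:
            bs, t50s = [], []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                t = np.arange(dt, dur + dt / 2, dt)
                y = log_logistic(t, b, t50) + 0.03 * rng.standard_normal(len(t))
                fit = fit_log_logistic(NormalizedCurve(t, y, direction))
                bs.append(fit.b)
                t50s.append(fit.t50)
            assert np.mean(bs) == pytest.approx(b, rel=0.05)
            assert np.mean(t50s) == pytest.approx(t50, rel=0.05)

    def test_r_squared_decreases_with_noise(self):
        t = np.arange(1.0, 901.0)
        clean = log_logistic(t, 2.5, 300.0)
        r2 = []
        for sigma in (0.0, 0.03, 0.1):
            rng = np.random.default_rng(0)
            fit = fit_log_logistic(NormalizedCurve(t, clean + sigma * rng.standard_normal(len(t)), "closing"))
            r2.append(fit.r_squared)
        assert r2[0] > r2[1] > r2[2]

    def test_time_unit_equivariance(self):
        t = np.arange(1.0, 901.0)
        y = log_logistic(t, 2.5, 300.0)
        fit_s = fit_log_logistic(NormalizedCurve(t, y, "closing"))
        fit_min = fit_log_logistic(NormalizedCurve(t * 60.0, y, "closing"))
        assert fit_min.b == pytest.approx(fit_s.b, rel=1e-6)
        assert fit_min.t50 == pytest.approx(fit_s.t50 * 60.0, rel=1e-6)

    def test_zero_time_sample_is_shifted(self):
        t = np.arange(0.0, 900.0)
        y = log_logistic(np.maximum(t, 0.5), 2.5, 300.0)
        fit = fit_log_logistic(NormalizedCurve(t, y, "closing"))
        assert fit.converged
        assert fit.t50 == pytest.approx(300.0, rel=1e-3)

    def test_all_nan_rejected(self):
        t = np.arange(1.0, 11.0)
        with pytest.raises(ValueError, match="non-finite"):
            fit_log_logistic(NormalizedCurve(t, np.full(10, np.nan), "closing"))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            fit_log_logistic(NormalizedCurve(np.arange(1.0, 4.0), np.array([1.0, 0.5, 0.0]), "closing"))

    def test_grid_fallback_without_quartile_crossings(self):
        # slow tail only: values never cross 0.25 from below
        t = np.arange(1.0, 301.0)
        y = log_logistic(t, 1.5, 5000.0)  # stays above 0.75 throughout
        fit = fit_log_logistic(NormalizedCurve(t, y, "closing"))
        assert fit.converged
        assert fit.b == pytest.approx(1.5, rel=1e-3)


class TestLogLogisticRegressor:
    def test_fit_predict(self):
        t = np.arange(1.0, 901.0)
        y = log_logistic(t, 2.5, 300.0)
        est = LogLogisticRegressor().fit(t, y)
        assert est.b_ == pytest.approx(2.5, abs=1e-6)
        assert est.t50_ == pytest.approx(300.0, rel=1e-6)
        assert est.direction_ == "closing"
        np.testing.assert_allclose(est.predict(t), y, atol=1e-9)

    def test_sklearn_clone_compatible(self):
        est = LogLogisticRegressor(direction="opening")
        assert clone(est).get_params() == est.get_params()
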