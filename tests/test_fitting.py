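"""Double-exponential fitting, observables, extrapolation, bleach calibration."""

import warnings

import numpy as np
import pytest
from scipy.optimize import nnls

import pulsescape as ps

SCHEDULE = np.array([60.0 * m for m in ps.PULSE_ESCAPE_SCHEDULE_MIN])


def _curve(A, a, B, b, C, t=SCHEDULE, noise=None, rng=None):
    y = A * np.exp(-a * t) + B * np.exp(-b * t) + C
    if noise:
        y = y * rng.lognormal(0.0, noise, size=t.size)
    return ps.DecayCurve(t, y)


def _single_exp_sse(t, y):
    """Independent single-exponential-plus-plateau baseline (varpro grid)."""
    best = np.inf
    for rate in np.geomspace(1e-6, 1e-1, 200):
        X = np.column_stack([np.exp(-rate * t), np.ones_like(t)])
        _, rnorm = nnls(X, y)
        best = min(best, rnorm ** 2)
    return best


class TestDoubleExponentialFit:
    def test_exact_recovery_of_noiseless_parameters(self):
        fit = ps.fit_double_exponential(_curve(0.4, 0.01, 0.6, 1e-4, 0.0))
        assert fit.A == pytest.approx(0.4, rel=1e-4)
        assert fit.B == pytest.approx(0.6, rel=1e-4)
        assert fit.a == pytest.approx(0.01, rel=1e-4)
        assert fit.b == pytest.approx(1e-4, rel=1e-4)
        assert fit.C == pytest.approx(0.0, abs=1e-6)

    def test_constant_curve_is_pure_plateau(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ps.fit_double_exponential(ps.DecayCurve(SCHEDULE, np.ones_like(SCHEDULE)))
        assert fit.C == pytest.approx(1.0, abs=1e-9)
        assert fit.A == pytest.approx(0.0, abs=1e-9)
        assert fit.B == pytest.approx(0.0, abs=1e-9)
        assert fit.plateau_fraction == pytest.approx(1.0)

    def test_model_generated_curve_has_negligible_plateau(self, reference_fit):
        # the measured average decays essentially to zero
        assert reference_fit.plateau_fraction < 1e-6

    def test_scale_invariance_of_fractions_and_observables(self, reference_curve):
        fit1 = ps.fit_double_exponential(reference_curve)
        doubled = ps.DecayCurve(reference_curve.times, 2.0 * reference_curve.values)
        fit2 = ps.fit_double_exponential(doubled)
        assert fit2.fast_fraction == pytest.approx(fit1.fast_fraction, rel=1e-6)
        assert fit2.plateau_fraction == pytest.approx(fit1.plateau_fraction, abs=1e-9)
        np.testing.assert_allclose(ps.observables(fit1), ps.observables(fit2), rtol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nested_model_dominance(self, seed):
        rng = np.random.default_rng(seed)
        curve = _curve(0.3, 2e-3, 0.7, 1.2e-4, 0.0, noise=0.05, rng=rng)
        fit = ps.fit_double_exponential(curve)
        assert fit.sse <= _single_exp_sse(curve.times, curve.values) + 1e-12

    def test_single_phase_input_collapses_to_single_phase_fit(self):
        # genuinely single-exponential data must not be split into two
        # phases: one amplitude vanishes (or the rates coincide and the
        # fit collapses with a warning)
        t = SCHEDULE
        y = 0.8 * np.exp(-1e-3 * t) + 0.2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ps.fit_double_exponential(ps.DecayCurve(t, y))
        assert min(fit.fast_fraction, fit.slow_fraction) < 1e-6 or fit.a == fit.b
        np.testing.assert_allclose(fit(t), y, atol=1e-8)

    def test_too_few_points_rejected(self):
        t = SCHEDULE[:5]
        with pytest.raises(ValueError, match="6 time points"):
            ps.fit_double_exponential(ps.DecayCurve(t, np.exp(-1e-3 * t)))

    def test_median_slow_rate_error_under_multiplicative_noise(self):
        rng = np.random.default_rng(2024)
        errors = []
        for _ in range(200):
            curve = _curve(0.3, 1.9e-3, 0.7, 1.2e-4, 0.0, noise=0.05, rng=rng)
            fit = ps.fit_double_exponential(curve)
            errors.append(abs(fit.b / 1.2e-4 - 1.0))
        assert np.median(errors) < 0.15

    def test_estimator_params_round_trip(self):
        est = ps.DoubleExponentialDecay(rate_grid_size=10)
        est.set_params(**est.get_params())
        assert est.get_params()["rate_grid_size"] == 10
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestObservablesAndExtrapolation:
    def test_initial_slope_arithmetic(self):
        fit = ps.DoubleExpFit(A=0.4, B=0.6, C=0.0, a=0.01, b=1e-4, sse=0.0)
        slope, slow = ps.observables(fit)
        assert slope == pytest.approx(0.00406)
        assert slow == 1e-4

    def test_single_phase_limit(self):
        fit = ps.DoubleExpFit(A=0.0, B=0.6, C=0.2, a=0.01, b=1e-4, sse=0.0)
        slope, _ = ps.observables(fit)
        assert slope == pytest.approx(1e-4 * 0.6 / 0.8)

    def test_empty_fit_has_no_observables(self):
        fit = ps.DoubleExpFit(A=0.0, B=0.0, C=0.0, a=0.01, b=1e-4, sse=0.0)
        with pytest.raises(ValueError):
            ps.observables(fit)

    def test_extrapolation_endpoints(self):
        fit = ps.DoubleExpFit(A=0.3, B=0.5, C=0.2, a=0.01, b=1e-4, sse=0.0)
        assert ps.extrapolate(fit, 0.0) == pytest.approx(fit.total)
        assert ps.extrapolate(fit, 1e9) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            ps.extrapolate(fit, -1.0)

    def test_model_curve_extrapolates_to_one_percent_at_ten_hours(self, reference_fit):
        remaining = ps.extrapolate(reference_fit, 36_000.0 - 60.0) / reference_fit.total
        assert remaining == pytest.approx(0.01, abs=0.005)

    def test_canonical_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            ps.DoubleExpFit(A=0.5, B=0.5, C=0.0, a=1e-4, b=1e-2, sse=0.0)


class TestBleachCalibration:
    def test_thirteen_percent_over_eleven_exposures(self):
        n = np.arange(12.0)
        k_true = np.log(1 / 0.87) / 11
        curves = [ps.DecayCurve(n, np.exp(-k_true * n))]
        assert ps.fit_bleach_calibration(curves) == pytest.approx(k_true, rel=1e-6)
        assert ps.fit_bleach_calibration(curves) == pytest.approx(0.0127, abs=2e-4)

    def test_constant_series_gives_zero_rate(self):
        n = np.arange(12.0)
        assert ps.fit_bleach_calibration([ps.DecayCurve(n, np.ones(12))]) == 0.0

    def test_subsampled_series_recovers_same_rate(self):
        rng = np.random.default_rng(5)
        n = np.arange(22.0)
        k_true = 0.0127
        curves = [ps.DecayCurve(n, np.exp(-k_true * n) * rng.lognormal(0, 0.005, n.size))
                  for _ in range(20)]
        k_full = ps.fit_bleach_calibration(curves)
        sub = [ps.DecayCurve(c.times[::2], c.values[::2]) for c in curves]
        k_sub = ps.fit_bleach_calibration(sub)
        assert k_sub == pytest.approx(k_full, rel=0.01)

    def test_rising_intensity_is_invalid(self):
        n = np.arange(12.0)
        with pytest.raises(ValueError, match="rises"):
            ps.fit_bleach_calibration([ps.DecayCurve(n, np.exp(0.01 * n))])

    def test_mismatched_exposure_grids_rejected(self):
        with pytest.raises(ValueError, match="exposure grid"):
            ps.fit_bleach_calibration([
                ps.DecayCurve(np.arange(12.0), np.ones(12)),
                ps.DecayCurve(np.arange(10.0), np.ones(10)),
            ])
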