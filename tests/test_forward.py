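"""Forward solvers: grid master equation, Monte Carlo, and model observables."""

import numpy as np
import pytest

import pulsescape as ps

ARRESTED = ps.MotilityParams(v_a=0.0, v_r=0.0, p_dir_a=0.6)


def _grid_cfg(samples, **kw):
    return ps.SimulationConfig(sample_times=tuple(samples), duration=max(samples),
                               solver="grid", **kw)


class TestExpectedDecay:
    def test_no_mobilization_keeps_curve_at_one(self, motility, geom):
        # the glycolytic-inhibition limit: nothing ever mobilises
        r = ps.RateConstants(0.0, 2.01e-1, 0.0, 2.21e-4)
        curve = ps.expected_decay(r, motility, geom, _grid_cfg([600.0, 10_800.0]))
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-9)

    def test_zero_velocity_keeps_curve_at_one(self, rates, geom):
        curve = ps.expected_decay(rates, ARRESTED, geom, _grid_cfg([600.0, 10_800.0]))
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_three_hour_endpoint_matches_measured_escape(self, model_curve):
        # ~19% of the activated fluorescence remains after 3 h, ~1% after 10 h
        assert model_curve.values[10] == pytest.approx(0.19, abs=0.01)
        assert model_curve.values[11] == pytest.approx(0.01, abs=0.005)

    def test_grid_refinement_converged(self, rates, motility, geom, schedule_s):
        coarse = ps.expected_decay(rates, motility, geom,
                                   _grid_cfg(schedule_s, grid_spacing=0.25))
        fine = ps.expected_decay(rates, motility, geom,
                                 _grid_cfg(schedule_s, grid_spacing=0.125))
        assert np.all(np.abs(fine.values / coarse.values - 1.0) < 0.005)

    def test_mass_conserved_with_reflecting_boundaries(self, rates, motility, geom):
        _, mass = ps.expected_decay(
            rates, motility, geom, _grid_cfg([1800.0]), boundary="reflecting",
            return_mass=True,
        )
        assert np.all(np.abs(mass - 1.0) < 1e-8)

    @pytest.mark.parametrize("rate_set", [
        ps.RateConstants(3.72e-3, 2.01e-1, 1.34e-4, 2.21e-4),
        ps.RateConstants(1e-2, 5e-1, 1e-3, 1e-3),
        ps.RateConstants(3.72e-3, 2.01e-1, 1.34e-4, 2.21e-4, 1e-3, 1.5e-3),
    ])
    def test_decay_is_monotone_non_increasing(self, rate_set, motility, geom, schedule_s):
        curve = ps.expected_decay(rate_set, motility, geom, _grid_cfg(schedule_s))
        assert np.all(np.diff(curve.values) <= 1e-12)

    def test_cfl_violation_names_admissible_step(self, rates, motility, geom):
        with pytest.raises(ValueError, match="time_step <= 0.5"):
            ps.expected_decay(rates, motility, geom,
                              _grid_cfg([60.0], grid_spacing=0.25, time_step=1.0))

    def test_requires_grid_solver_tag(self, rates, motility, geom):
        cfg = ps.SimulationConfig(sample_times=(60.0,), duration=60.0, solver="monte_carlo")
        with pytest.raises(ValueError, match="grid"):
            ps.expected_decay(rates, motility, geom, cfg)

    def test_empty_sample_times_rejected(self):
        with pytest.raises(ValueError, match="sample_times"):
            ps.SimulationConfig(sample_times=(), duration=60.0)

    def test_modal_solver_agrees_with_grid(self, rates, motility, model_curve, schedule_s):
        y = ps.modal_decay(rates, motility, 5.0, schedule_s)
        assert np.max(np.abs(y - model_curve.values[:11])) < 0.01


class TestMonteCarlo:
    def _run(self, rates, motility, geom, n=20_000, seed=3, samples=None):
        cfg = ps.SimulationConfig(
            n_filaments=n, duration=10_800.0, solver="monte_carlo", seed=seed,
            sample_times=tuple(samples if samples is not None
                               else 60.0 * np.array([1, 5, 15, 30, 60, 120, 180.0])),
        )
        return ps.simulate_pulse_escape(rates, motility, geom, cfg)

    def test_agrees_with_grid_solver_within_three_standard_errors(
            self, rates, motility, geom, schedule_s, model_curve):
        mc = self._run(rates, motility, geom, samples=schedule_s)
        expected = model_curve.values[:11]
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert np.all(np.abs(mc.values - expected) < 3.0 * se)

    def test_fixed_seed_is_bit_reproducible(self, rates, motility, geom):
        a = self._run(rates, motility, geom, n=2000)
        b = self._run(rates, motility, geom, n=2000)
        assert np.array_equal(a.values, b.values)

    def test_seeds_differ(self, rates, motility, geom):
        a = self._run(rates, motility, geom, n=2000, seed=1)
        b = self._run(rates, motility, geom, n=2000, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_no_mobilization_keeps_all_filaments(self, motility, geom):
        r = ps.RateConstants(0.0, 2.01e-1, 0.0, 2.21e-4)
        mc = self._run(r, motility, geom, n=2000)
        np.testing.assert_allclose(mc.values, 1.0)

    def test_boundary_crossings_warn_when_reentry_possible(self, motility):
        r = ps.RateConstants(3.72e-3, 2.01e-1, 1.34e-4, 2.21e-4, 1e-3, 1.5e-3)
        tight = ps.WindowGeometry(window_length=5.0, domain_margin=6.0)
        with pytest.warns(UserWarning, match="domain_margin"):
            self._run(r, motility, tight, n=4000)


class TestObservables:
    def test_initial_slope_positive_and_faster_than_slow_phase(self, rates, motility, geom):
        s = ps.initial_slope(rates, motility, geom)
        b = ps.long_term_decay_constant(rates, motility, geom)
        assert 0 < b < s

    def test_initial_slope_zero_without_motion(self, rates, geom):
        assert ps.initial_slope(rates, ARRESTED, geom) == 0.0

    def test_analytic_slope_is_moving_outflux(self, rates, motility, geom):
        dist = ps.steady_state(rates, motility)
        expected = dist.f_moving * motility.mean_bout_speed / geom.window_length
        assert ps.initial_slope_analytic(rates, motility, geom) == pytest.approx(expected)

    def test_slope_linear_in_speed(self, rates, geom):
        # perturbative regime: escape flux scales with |v|
        slow = ps.MotilityParams(v_a=0.02, v_r=-0.02, p_dir_a=0.6)
        fast = ps.MotilityParams(v_a=0.04, v_r=-0.04, p_dir_a=0.6)
        s1 = ps.initial_slope(rates, slow, geom)
        s2 = ps.initial_slope(rates, fast, geom)
        assert s2 / s1 == pytest.approx(2.0, rel=0.02)

    def test_slow_constant_below_mobilization_rate(self, rates, motility, geom):
        # mobilised filaments may go off-track again before escaping,
        # so the window-escape rate is strictly below gamma_on
        for method in ("slope", "eigen"):
            b = ps.long_term_decay_constant(rates, motility, geom, method=method)
            assert 0 < b < rates.gamma_on
            assert b > 0.5 * rates.gamma_on

    def test_slope_and_eigen_estimates_bracket_each_other(self, rates, motility, geom):
        # the slow spectrum is a quasi-continuous band: the asymptotic mode
        # (eigen) bounds the finite-horizon log-slope from above, within ~7%
        slope = ps.long_term_decay_constant(rates, motility, geom, method="slope")
        eigen = ps.long_term_decay_constant(rates, motility, geom, method="eigen")
        assert slope <= eigen <= 1.07 * slope

    def test_smaller_window_decays_faster(self, rates, motility):
        wide = ps.long_term_decay_constant(rates, motility, ps.WindowGeometry(5.0, 50.0))
        narrow = ps.long_term_decay_constant(rates, motility, ps.WindowGeometry(0.5, 50.0))
        assert narrow > wide

    def test_zero_motility_flagged_as_zero_rate(self, rates, geom):
        assert ps.long_term_decay_constant(rates, ARRESTED, geom) == 0.0
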