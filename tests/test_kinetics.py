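"""Closure-velocity fitting and the algebraic motility decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundkinetics import (
    WoundTimeSeries,
    edge_speed,
    fit_closure_velocity,
    fit_doubling_time,
    forward_speed,
    growth_rate,
    motility_from_speed,
    simulate_growth_curve,
    thiele_modulus,
)
from woundkinetics.kinetics import LN2, estimate_motility


def _series(times, values):
    return WoundTimeSeries(times=np.asarray(times, float), a_over_a0=np.asarray(values, float))


class TestClosureVelocity:
    def test_pure_line_recovered_exactly(self):
        t = np.arange(0.0, 10.0, 0.5)
        fit = fit_closure_velocity(_series(t, 1.0 - 0.05 * t))
        assert fit.alpha == pytest.approx(0.05, rel=1e-9)
        assert fit.t_lag == 0.0
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.no_closure

    def test_lag_then_decline_finds_breakpoint(self):
        t = np.arange(0.0, 10.01, 0.25)
        y = np.where(t <= 2.0, 1.0, 1.0 - 0.1 * (t - 2.0))
        fit = fit_closure_velocity(_series(t, y))
        assert abs(fit.t_lag - 2.0) <= 0.25  # within one sampling interval
        assert fit.alpha == pytest.approx(0.1, rel=0.05)

    def test_flat_series_flags_no_closure(self):
        t = np.arange(0.0, 5.0, 0.5)
        fit = fit_closure_velocity(_series(t, np.ones_like(t)))
        assert fit.alpha == 0.0
        assert fit.no_closure

    def test_increasing_series_flags_no_closure(self):
        t = np.arange(0.0, 5.0, 0.5)
        fit = fit_closure_velocity(_series(t, 1.0 + 0.02 * t))
        assert fit.alpha == 0.0
        assert fit.no_closure

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_closure_velocity(_series([0.0, 1.0, 2.0, 3.0], [1.0, 0.9, 0.8, 0.7]))

    def test_long_lag_warns(self):
        t = np.arange(0.0, 20.01, 0.5)
        y = np.where(t <= 14.0, 1.0, 1.0 - 0.05 * (t - 14.0))
        with pytest.warns(UserWarning, match="lag time"):
            fit_closure_velocity(_series(t, y))


class TestEdgeSpeed:
    def test_printed_formula(self):
        assert edge_speed(0.05, 400.0) == pytest.approx(10.0)

    def test_zero_alpha_zero_speed(self):
        assert edge_speed(0.0, 400.0) == 0.0

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            edge_speed(0.05, 0.0)


class TestDoublingTime:
    def test_noiseless_exact_recovery(self):
        curve = simulate_growth_curve(5e3, 24.0, np.arange(0.0, 73.0, 12.0))
        fit = fit_doubling_time(curve)
        assert fit.tau == pytest.approx(24.0, rel=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-18)

    def test_one_doubling_per_day(self):
        curve = simulate_growth_curve(100.0, 24.0, np.array([0.0, 24.0, 48.0]))
        assert np.allclose(curve.counts, [100.0, 200.0, 400.0])
        assert fit_doubling_time(curve).tau == pytest.approx(24.0)

    def test_median_recovery_under_noise(self):
        # 200 noisy curves at 5% CV: the median estimate stays within 3%
        taus = []
        times = np.arange(0.0, 61.0, 10.0)
        for seed in range(200):
            curve = simulate_growth_curve(1e4, 20.0, times, noise_cv=0.05, seed=seed)
            taus.append(fit_doubling_time(curve).tau)
        assert abs(np.median(taus) / 20.0 - 1.0) < 0.03

    def test_no_growth_rejected(self):
        curve = simulate_growth_curve(100.0, 24.0, np.array([0.0, 12.0, 24.0]))
        shrinking = type(curve)(times=curve.times, counts=curve.counts[::-1].copy())
        with pytest.raises(ValueError, match="no growth"):
            fit_doubling_time(shrinking)


class TestAlgebra:
    def test_growth_rate_values(self):
        assert growth_rate(LN2) == pytest.approx(1.0)
        assert growth_rate(24.0) == pytest.approx(0.028881, abs=1e-6)
        assert growth_rate(1e12) < 1e-12

    def test_motility_forced_unit_case(self):
        assert motility_from_speed(1.0, 4.0 * LN2) == pytest.approx(1.0)

    def test_motility_printed_example(self):
        assert motility_from_speed(10.0, 24.0) == pytest.approx(865.62, abs=0.01)

    def test_forward_speed_values(self):
        assert forward_speed(1.0, 4.0 * LN2) == pytest.approx(1.0)
        assert forward_speed(0.0, 24.0) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        v=st.floats(1e-6, 1e3),
        tau=st.floats(1e-3, 1e3),
    )
    def test_speed_motility_round_trip(self, v, tau):
        assert forward_speed(motility_from_speed(v, tau), tau) == pytest.approx(v, rel=1e-12)

    def test_thiele_modulus(self):
        assert thiele_modulus(1.0, 1.0, 1.0) == pytest.approx(1.0)
        # b = 400 µm, k = ln2/24 h^-1, D = 865.62 µm²/h
        assert thiele_modulus(400.0, LN2 / 24.0, 865.617) == pytest.approx(2.31, abs=0.005)
        assert thiele_modulus(2.0, 1.0, 1.0) == pytest.approx(2.0 * thiele_modulus(1.0, 1.0, 1.0))
        assert thiele_modulus(3.0, 2.0, 5.0, convention="literal") == pytest.approx(9.0 * 2.0 / 5.0)
        with pytest.raises(ValueError):
            thiele_modulus(1.0, 0.0, 1.0)

    def test_motility_estimate_increases_with_alpha(self):
        estimates = [estimate_motility(a, 400.0, 24.0).D for a in (0.01, 0.02, 0.04)]
        assert estimates == sorted(estimates)
        assert estimates[0] < estimates[1] < estimates[2]

    def test_estimate_chain_is_consistent(self):
        est = estimate_motility(0.05, 400.0, 24.0)
        assert est.v == pytest.approx(10.0)
        assert est.k == pytest.approx(LN2 / 24.0)
        assert forward_speed(est.D, 24.0) == pytest.approx(est.v, rel=1e-12)
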