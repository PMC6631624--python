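"""Solver checks: scratch geometry, diffusion limit, conservation, front speed."""

import numpy as np
import pytest

from woundkinetics import (
    DensityField,
    FKParameters,
    Grid1D,
    StabilityError,
    make_scratch_initial_condition,
    measure_front_speed,
    simulate_fk_1d,
)
from woundkinetics.kinetics import LN2, forward_speed


def _params(D=100.0, k=0.0, u_hat=1.0, b=100.0):
    return FKParameters(D=D, k=k, u_hat=u_hat, b=b)


class TestScratchInitialCondition:
    @pytest.mark.parametrize(
        "b, lo, hi, n_nodes, expected_zero",
        [
            (1000.0, 0.0, 2000.0, 401, 200),  # half the domain -> half the nodes
            (500.0, 0.0, 2000.0, 401, 100),
            (5.0, 0.0, 2000.0, 401, 1),  # one grid cell -> one interior node
        ],
    )
    def test_zero_node_count(self, b, lo, hi, n_nodes, expected_zero):
        grid = Grid1D(lo, hi, n_nodes, dt=0.01, t_end=1.0)
        field = make_scratch_initial_condition(_params(b=b), grid)
        n_zero = int((field.values[0] == 0).sum())
        assert abs(n_zero - expected_zero) <= 1

    def test_values_are_u_hat_outside_wound(self):
        grid = Grid1D(0.0, 2000.0, 401, dt=0.01, t_end=1.0)
        field = make_scratch_initial_condition(_params(b=500.0, u_hat=3.0), grid)
        u = field.values[0]
        assert set(np.unique(u)) == {0.0, 3.0}
        # zero run is contiguous and centered
        zeros = np.nonzero(u == 0)[0]
        assert np.all(np.diff(zeros) == 1)
        assert abs((zeros.mean() - 200.0)) <= 0.5

    def test_wound_wider_than_domain_raises(self):
        grid = Grid1D(0.0, 400.0, 101, dt=0.01, t_end=1.0)
        with pytest.raises(ValueError, match="does not fit"):
            make_scratch_initial_condition(_params(b=500.0), grid)


class TestFKSolver:
    def test_no_dynamics_identity(self):
        grid = Grid1D(0.0, 100.0, 51, dt=0.01, t_end=2.0)
        field = make_scratch_initial_condition(_params(D=0.0, k=0.0, b=30.0), grid)
        out = simulate_fk_1d(field, _params(D=0.0, k=0.0, b=30.0), grid)
        assert np.array_equal(out.values, np.broadcast_to(field.values[0], out.values.shape))

    def test_pure_diffusion_matches_heat_kernel(self):
        # Gaussian initial bump spreading under d u/dt = D d2u/dx2:
        # sigma(t)^2 = sigma0^2 + 2 D t, amplitude scales as sigma0/sigma(t)
        D, s0, T = 300.0, 30.0, 10.0
        grid = Grid1D(-1000.0, 1000.0, 801, dt=0.005, t_end=T)
        x = grid.x
        init = DensityField(np.array([0.0]), np.exp(-(x**2) / (2 * s0**2))[None, :], grid)
        out = simulate_fk_1d(init, _params(D=D, k=0.0, u_hat=10.0), grid, save_times=[0.0, T])
        s_t = np.sqrt(s0**2 + 2 * D * T)
        exact = s0 / s_t * np.exp(-(x**2) / (2 * s_t**2))
        rel_l2 = np.linalg.norm(out.values[-1] - exact) / np.linalg.norm(exact)
        assert rel_l2 < 0.01

    def test_mass_conserved_without_growth(self):
        grid = Grid1D(0.0, 500.0, 251, dt=0.005, t_end=5.0)
        rng = np.random.default_rng(0)
        u0 = rng.uniform(0.1, 1.0, grid.n_nodes)
        init = DensityField(np.array([0.0]), u0[None, :], grid)
        out = simulate_fk_1d(init, _params(D=150.0, k=0.0), grid)
        mass = out.total_mass()
        assert np.all(np.abs(mass / mass[0] - 1.0) < 1e-6)

    def test_density_bounded_and_front_stays_monotone(self):
        p = _params(D=200.0, k=LN2 / 12.0, u_hat=1.0, b=1.0)
        grid = Grid1D(0.0, 2000.0, 401, dt=0.02, t_end=40.0)
        u0 = np.where(grid.x < 500.0, 1.0, 0.0)
        init = DensityField(np.array([0.0]), u0[None, :], grid)
        out = simulate_fk_1d(init, p, grid)
        assert out.values.min() >= 0.0
        assert out.values.max() <= p.u_hat * (1.0 + 1e-9)
        # a monotone decreasing front remains monotone at every saved time
        assert np.all(np.diff(out.values, axis=1) <= 1e-12)

    def test_front_speed_approaches_fisher_kpp_minimum(self):
        D, tau = 600.0, 24.0
        k = LN2 / tau
        T = 30.0 / k
        v_th = forward_speed(D, tau)
        L = 2000.0 + v_th * T * 1.3 + 2000.0
        grid = Grid1D(0.0, L, int(L / 10) + 1, dt=min(0.4 * 100 / (2 * D), 0.2 / k), t_end=T)
        u0 = np.where(grid.x < 2000.0, 1.0, 0.0)
        init = DensityField(np.array([0.0]), u0[None, :], grid)
        out = simulate_fk_1d(init, _params(D=D, k=k), grid, save_times=np.linspace(0, T, 200))
        v = measure_front_speed(out)
        assert abs(v / v_th - 1.0) < 0.05

    def test_unstable_timestep_refused(self):
        grid = Grid1D(0.0, 100.0, 101, dt=1.0, t_end=2.0)  # dx=1, dt >> dx^2/2D
        field = make_scratch_initial_condition(_params(D=100.0, b=30.0), grid)
        with pytest.raises(StabilityError, match="stability"):
            simulate_fk_1d(field, _params(D=100.0), grid)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            Grid1D(10.0, 0.0, 101, dt=0.01, t_end=1.0)
        with pytest.raises(ValueError):
            Grid1D(0.0, 10.0, 2, dt=0.01, t_end=1.0)
        with pytest.raises(ValueError):
            FKParameters(D=-1.0, k=0.1)
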