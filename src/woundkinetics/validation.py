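"""Standard validation experiments for the wound-closure pipeline.

Three self-contained computations, each generating its own synthetic data:

* :func:`velocity_ratio_experiment` — the headline treated-vs-control
  comparison: two conditions with equal doubling time and a 3.24-fold
  motility difference, run through the full render → segment → fit
  pipeline; under the Fisher–KPP front-speed law v = 2·sqrt(D·k) the
  closure-velocity ratio is sqrt(3.24) = 1.80.

* :func:`front_speed_validation` — measured simulated front speed against
  the analytic 2·sqrt(D·k) over a grid of (D, τ).

* :func:`parameter_recovery_experiment` — plant (D*, τ*), image a wide
  wound long enough for the travelling-wave regime (k·t ≫ 1), and recover
  both through the full pipeline.  Within a short record (such as an 18 h
  protocol) the front is still accelerating and the algebraic inversion
  returns an effective, regime-dependent D; recovery of the planted value
  is only meaningful in the developed-front regime, so this experiment
  uses a long horizon and a wound wide enough that the edges never
  interact.
"""

from __future__ import annotations

import numpy as np

from .growth import simulate_growth_curve
from .kinetics import (
    LN2,
    estimate_motility,
    fit_closure_velocity,
    fit_doubling_time,
    forward_speed,
)
from .pipeline import ConditionSpec, ExperimentConfig, run_synthetic_experiment
from .render import RenderConfig, render_timelapse
from .segmentation import SegmentationConfig, initial_wound_width, measure_area_series, segment_wound
from .simulate import (
    DensityField,
    FKParameters,
    Grid1D,
    make_scratch_initial_condition,
    measure_front_speed,
    simulate_fk_1d,
)

__all__ = [
    "velocity_ratio_experiment",
    "front_speed_validation",
    "parameter_recovery_experiment",
]


def velocity_ratio_experiment(seed: int, out_dir, d_ratio: float = 3.24, **config_kw) -> dict:
    """Full-pipeline α ratio for a treated condition with D = d_ratio × control.

    Uses the default study protocol (15-min frames for 18 h, three
    replicate fields per condition, equal τ) and returns the report dict
    plus the fitted ``alpha_ratio`` and its paired-test p-value.
    """
    control = ConditionSpec(label="control", D=600.0, tau=24.0)
    treated = ConditionSpec(label="treated", D=d_ratio * control.D, tau=control.tau)
    config = ExperimentConfig(conditions=(control, treated), seed=seed, **config_kw)
    report = run_synthetic_experiment(config, out_dir)
    comp = report["comparisons"]["treated_vs_control"]["alpha_per_h"]
    report["alpha_ratio"] = comp["ratio"]
    report["alpha_p_value"] = comp["p_value"]
    return report


def front_speed_validation(
    D_values=(300.0, 600.0, 1000.0),
    tau_values=(12.0, 18.0, 24.0),
    horizon_doublings: float = 30.0,
    dx: float = 10.0,
    n_save: int = 200,
) -> list[dict]:
    """Measured vs analytic front speed over a (D, τ) grid.

    Each run starts from a confluent half-plane invading empty space and
    integrates for ``horizon_doublings``/k hours so the front reaches its
    asymptotic speed; the speed is fitted over the last 40% of the record.
    Returns one record per (D, τ) with measured speed, theory 2·sqrt(Dk),
    and the relative error.
    """
    out = []
    for D in D_values:
        for tau in tau_values:
            k = LN2 / tau
            T = horizon_doublings / k
            v_th = forward_speed(D, tau)
            margin = 2000.0
            L = margin + v_th * T * 1.3 + margin
            n = int(round(L / dx)) + 1
            dt = min(0.4 * dx * dx / (2 * D), 0.2 / k)
            grid = Grid1D(0.0, L, n, dt, T)
            u0 = np.where(grid.x < margin, 1.0, 0.0)
            init = DensityField(np.array([0.0]), u0[None, :], grid)
            params = FKParameters(D=D, k=k, u_hat=1.0, b=1.0)
            field = simulate_fk_1d(init, params, grid, save_times=np.linspace(0, T, n_save))
            v = measure_front_speed(field)
            out.append(
                {
                    "D": D,
                    "tau": tau,
                    "v_measured": v,
                    "v_theory": v_th,
                    "rel_error": v / v_th - 1.0,
                }
            )
    return out


def parameter_recovery_experiment(
    seed: int,
    D_true: float = 300.0,
    tau_true: float = 6.0,
    horizon_doublings: float = 60.0,
    b: float = 14000.0,
    dx: float = 8.0,
    pixel_size: float = 10.0,
    frame_rows: int = 150,
    n_frames: int = 80,
) -> dict:
    """Plant (D*, τ*), run render → segment → fit, recover both.

    The wound is imaged over ``horizon_doublings`` population doublings so
    the Fisher–KPP front runs at its asymptotic speed for most of the
    record, and is wide enough that the two edges never interact.  The
    doubling time comes from an independently simulated noisy growth
    curve, exactly as in the study protocol.
    """
    k = LN2 / tau_true
    t_end = horizon_doublings / k
    # domain: wound plus monolayer margins that the fronts never exhaust
    L = b + 2 * 2000.0
    n_nodes = int(round(L / dx)) + 1
    dt = min(0.4 * dx * dx / (2 * D_true), 0.2 / k)
    grid = Grid1D(0.0, L, n_nodes, dt, t_end)
    u_hat = 1.2e-3
    params = FKParameters(D=D_true, k=k, u_hat=u_hat, b=b)
    init = make_scratch_initial_condition(params, grid)
    frame_times = np.linspace(0.0, t_end, n_frames)
    field = simulate_fk_1d(init, params, grid, save_times=frame_times)

    ss = np.random.SeedSequence(seed)
    render_seed, growth_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    cfg = RenderConfig(
        pixel_size=pixel_size,
        frame_shape=(frame_rows, int(round(grid.length / pixel_size))),
        seed=render_seed,
    )
    stack, _ = render_timelapse(field, cfg, u_hat=u_hat)
    series = measure_area_series(stack)
    closure = fit_closure_velocity(series)
    b_hat = initial_wound_width(segment_wound(stack.frames[0]), pixel_size)

    growth_times = np.linspace(0.0, 4 * tau_true, 9)
    growth = simulate_growth_curve(9e3, tau_true, growth_times, noise_cv=0.05, seed=growth_seed)
    tau_hat = fit_doubling_time(growth).tau

    est = estimate_motility(closure.alpha, b_hat, tau_hat)
    return {
        "D_true": D_true,
        "tau_true": tau_true,
        "D_hat": est.D,
        "tau_hat": tau_hat,
        "alpha": closure.alpha,
        "b_hat": b_hat,
        "v_hat": est.v,
        "D_rel_error": est.D / D_true - 1.0,
        "tau_rel_error": tau_hat / tau_true - 1.0,
    }
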