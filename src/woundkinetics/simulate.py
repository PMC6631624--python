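"""Fisher–Kolmogoroff (Fisher–KPP) wound-closure dynamics in one dimension.

The cell density u(x, t) of a scratched monolayer obeys

    du/dt = D d2u/dx2 + k u (1 - u / u_hat)

where D is the random motility coefficient (µm²/h), k = ln2/τ the growth
kinetic constant (1/h) derived from the population doubling time τ, and
u_hat the confluent cell density.  A scratch wound is a cell-free band of
width b in an otherwise confluent field; the model predicts that, after a
transient, both wound edges advance at the constant front speed
v = 2·sqrt(D·k).

The solver is an explicit central-difference FTCS scheme with no-flux
(reflecting) boundaries and a hard stability guard; it is deliberately
simple and auditable rather than fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FKParameters",
    "Grid1D",
    "DensityField",
    "StabilityError",
    "make_scratch_initial_condition",
    "simulate_fk_1d",
    "front_positions",
    "measure_front_speed",
]


class StabilityError(ValueError):
    """Raised when the requested time step violates the FTCS stability bound."""


@dataclass(frozen=True)
class FKParameters:
    """Parameters of the Fisher–KPP wound model.

    Attributes
    ----------
    D : float
        Random motility coefficient, µm²/h.
    k : float
        Growth kinetic constant, 1/h (k = ln2/τ for doubling time τ).
    u_hat : float
        Confluent (carrying-capacity) cell density, cells/µm².
    b : float
        Initial wound width (edge-to-edge distance at t = 0), µm.
    """

    D: float
    k: float
    u_hat: float = 1.2e-3
    b: float = 800.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"motility coefficient D must be >= 0, got {self.D}")
        if self.k < 0:
            raise ValueError(f"growth constant k must be >= 0, got {self.k}")
        if self.u_hat <= 0:
            raise ValueError(f"confluent density u_hat must be > 0, got {self.u_hat}")
        if self.b <= 0:
            raise ValueError(f"wound width b must be > 0, got {self.b}")


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1D space–time discretization.

    ``dt`` must satisfy the FTCS stability contract ``dt <= dx**2 / (2 D)``
    (checked at simulation time, not here, because it depends on D).
    """

    x_min: float
    x_max: float
    n_nodes: int
    dt: float
    t_end: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.n_nodes < 3:
            raise ValueError(f"need at least 3 nodes, got {self.n_nodes}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_nodes)

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n_nodes - 1)

    @property
    def length(self) -> float:
        return self.x_max - self.x_min


@dataclass
class DensityField:
    """Cell density u(x, t) sampled on a :class:`Grid1D`.

    ``values`` has shape (len(times), grid.n_nodes) and is non-negative,
    bounded by u_hat up to solver tolerance.
    """

    times: np.ndarray
    values: np.ndarray
    grid: Grid1D

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (self.times.size, self.grid.n_nodes):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.times.size} times x {self.grid.n_nodes} nodes"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    def total_mass(self) -> np.ndarray:
        """Trapezoidal integral of u over x at each time (cells/µm of wound length)."""
        return np.trapezoid(self.values, self.x, axis=1)


def make_scratch_initial_condition(params: FKParameters, grid: Grid1D) -> DensityField:
    """Confluent monolayer with a centered cell-free band of width ``params.b``.

    u = u_hat outside the band, 0 inside; the band is centered on the domain
    midpoint.  Raises ``ValueError`` if the wound is wider than the domain.
    """
    if params.b >= grid.length:
        raise ValueError(
            f"wound width b={params.b} does not fit in domain of length {grid.length}"
        )
    x = grid.x
    center = 0.5 * (grid.x_min + grid.x_max)
    inside = np.abs(x - center) < params.b / 2
    u0 = np.full(grid.n_nodes, params.u_hat)
    u0[inside] = 0.0
    return DensityField(times=np.array([0.0]), values=u0[None, :], grid=grid)


def _stability_check(params: FKParameters, grid: Grid1D) -> None:
    dx = grid.dx
    if params.D > 0:
        dt_max = dx * dx / (2.0 * params.D)
        if grid.dt > dt_max:
            raise StabilityError(
                f"dt={grid.dt:g} violates FTCS diffusion stability bound "
                f"dx^2/(2D)={dt_max:g} (dx={dx:g}, D={params.D:g}); reduce dt "
                "or coarsen the grid"
            )
    if params.k > 0 and grid.dt * params.k > 0.25:
        raise StabilityError(
            f"dt={grid.dt:g} too large for growth constant k={params.k:g} "
            f"(require dt*k <= 0.25, got {grid.dt * params.k:g})"
        )


def simulate_fk_1d(
    init: DensityField,
    params: FKParameters,
    grid: Grid1D,
    save_times: np.ndarray | None = None,
) -> DensityField:
    """Integrate the Fisher–KPP equation from ``init`` up to ``grid.t_end``.

    Explicit FTCS stepping with no-flux boundaries (mirror ghost nodes);
    refuses to run if ``grid.dt`` violates the stability bound.  Density is
    returned at ``save_times`` (snapped to the nearest step; default 201
    evenly spaced times including t = 0).

    With k = 0 and no-flux boundaries the scheme conserves total mass to
    machine precision; with k > 0 the solution stays within [0, u_hat].
    """
    if init.grid is not grid and (
        init.grid.n_nodes != grid.n_nodes
        or init.grid.x_min != grid.x_min
        or init.grid.x_max != grid.x_max
    ):
        raise ValueError("initial condition is not defined on the simulation grid")
    _stability_check(params, grid)

    n_steps = int(round(grid.t_end / grid.dt))
    if save_times is None:
        save_times = np.linspace(0.0, grid.t_end, 201)
    save_times = np.asarray(save_times, dtype=float)
    save_steps = np.unique(np.clip(np.round(save_times / grid.dt).astype(int), 0, n_steps))

    u = init.values[-1].copy()
    dx2 = grid.dx * grid.dx
    r = params.D * grid.dt / dx2
    dt_k = grid.dt * params.k
    u_hat = params.u_hat

    out_times = []
    out_values = []
    save_set = set(save_steps.tolist())
    if 0 in save_set:
        out_times.append(0.0)
        out_values.append(u.copy())

    lap = np.empty_like(u)
    for step in range(1, n_steps + 1):
        # no-flux: mirror ghost nodes u[-1] := u[1], u[n] := u[n-2]
        lap[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
        lap[0] = 2.0 * (u[1] - u[0])
        lap[-1] = 2.0 * (u[-2] - u[-1])
        u = u + r * lap + dt_k * u * (1.0 - u / u_hat)
        if step in save_set:
            out_times.append(step * grid.dt)
            out_values.append(u.copy())

    return DensityField(times=np.array(out_times), values=np.array(out_values), grid=grid)


def front_positions(field: DensityField, level: float = 0.5, side: str = "left") -> np.ndarray:
    """Position of the u = level·u_max crossing of a single invading front.

    For a monotone front profile, finds the sub-grid (linearly interpolated)
    x where u crosses ``level`` times the field's maximum density, scanning
    from the chosen ``side`` ("left": rightmost crossing of a front that
    invades rightward, i.e. u decreasing with x).  Returns NaN for frames
    with no crossing.
    """
    u_ref = float(field.values.max())
    if u_ref <= 0:
        return np.full(field.times.shape, np.nan)
    thr = level * u_ref
    x = field.x
    out = np.full(field.times.size, np.nan)
    for i, u in enumerate(field.values):
        if side == "left":
            above = u >= thr
            if not above.any() or above.all():
                continue
            j = int(np.max(np.nonzero(above)[0]))
            if j + 1 >= u.size:
                continue
            u0, u1 = u[j], u[j + 1]
        else:
            above = u >= thr
            if not above.any() or above.all():
                continue
            j = int(np.min(np.nonzero(above)[0]))
            if j == 0:
                continue
            j -= 1
            u0, u1 = u[j], u[j + 1]
        if u1 == u0:
            out[i] = x[j]
        else:
            out[i] = x[j] + (thr - u0) / (u1 - u0) * (x[j + 1] - x[j])
    return out


def measure_front_speed(
    field: DensityField,
    level: float = 0.5,
    fit_window: tuple[float, float] = (0.6, 1.0),
    side: str = "left",
) -> float:
    """Front speed from a linear fit of front position over a late time window.

    ``fit_window`` is a fraction of the record, defaulting to the last 40%,
    which excludes the early transient during which a Fisher–KPP front
    accelerates toward its asymptotic speed 2·sqrt(D·k).
    """
    pos = front_positions(field, level=level, side=side)
    t = field.times
    ok = np.isfinite(pos)
    t, pos = t[ok], pos[ok]
    if t.size < 3:
        raise ValueError("too few frames with a detectable front to fit a speed")
    t0 = t[0] + fit_window[0] * (t[-1] - t[0])
    t1 = t[0] + fit_window[1] * (t[-1] - t[0])
    sel = (t >= t0) & (t <= t1)
    if sel.sum() < 3:
        raise ValueError("fit window contains fewer than 3 front positions")
    slope = np.polyfit(t[sel], pos[sel], 1)[0]
    return float(abs(slope))
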