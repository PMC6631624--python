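"""Closure kinetics and the algebraic motility/proliferation decomposition.

The normalized wound area A/A0 of a scratch assay stays flat for a lag time
t_L, then declines at a constant rate; the magnitude of that slope is the
closure velocity α (1/h).  Each wound edge advances at v = α·b/2, where b
is the initial wound width.  Under the Fisher–KPP model the front speed
obeys v = sqrt(4 D ln2 / τ) = 2 sqrt(D k), so the random motility
coefficient follows from measured v and an independently fitted doubling
time τ:

    D = τ v² / (4 ln 2),      k = ln 2 / τ.

The Thiele modulus φ = b sqrt(k / D) compares proliferation to motility
over the wound width and diagnoses which mechanism dominates closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .growth import GrowthCurve
from .segmentation import WoundTimeSeries

__all__ = [
    "ClosureFit",
    "LogisticFit",
    "MotilityEstimate",
    "fit_closure_velocity",
    "edge_speed",
    "fit_doubling_time",
    "growth_rate",
    "motility_from_speed",
    "forward_speed",
    "thiele_modulus",
    "estimate_motility",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ClosureFit:
    """Lag time and closure velocity of one A/A0 series.

    ``alpha`` is the magnitude (1/h) of the least-squares slope over the
    detected linear window; ``t_lag`` is the window's start time relative
    to the first frame; ``window`` the (start, end) indices of the linear
    range; ``no_closure`` flags series that never decline.
    """

    t_lag: float
    alpha: float
    r_squared: float
    window: tuple[int, int]
    no_closure: bool = False


@dataclass(frozen=True)
class LogisticFit:
    """Single-parameter doubling-time fit of n(t) = n0 · 2^(t/τ)."""

    n0: float
    tau: float
    residual: float


@dataclass(frozen=True)
class MotilityEstimate:
    """Derived kinetic quantities for one condition (µm / h units)."""

    v: float
    k: float
    D: float
    phi: float


def fit_closure_velocity(series: WoundTimeSeries) -> ClosureFit:
    """Fit the lag-then-linear closure model to a normalized area series.

    The model is a continuous two-segment curve — a flat plateau up to the
    breakpoint t_L followed by a straight decline — fitted by least squares
    with the breakpoint scanned over the sample times (the declining
    segment must keep at least 5 points).  A series whose best-fit slope is
    non-negative gets ``alpha = 0`` and the no-closure flag.
    """
    t = series.times
    y = series.a_over_a0
    n = t.size
    if n < 5:
        raise ValueError(f"need at least 5 points to fit a closure velocity, got {n}")

    best = None
    for ib in range(0, n - 4):  # breakpoint index; >= 5 declining points
        g = np.clip(t - t[ib], 0.0, None)
        A = np.column_stack([np.ones(n), -g])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, ib, coef)
    sse, ib, (c, a) = best

    if a <= 0:
        return ClosureFit(t_lag=0.0, alpha=0.0, r_squared=0.0, window=(0, n - 1), no_closure=True)

    t_lag = float(t[ib] - t[0])
    win = (ib, n - 1)
    yw = y[ib:]
    sst = float(((yw - yw.mean()) ** 2).sum())
    ssew = float(((yw - (c - a * (t[ib:] - t[ib]))) ** 2).sum())
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssew / sst)
    if t_lag > 0.5 * (t[-1] - t[0]):
        warnings.warn(
            f"lag time {t_lag:g} h exceeds half the record; closure velocity "
            "rests on few late points",
            stacklevel=2,
        )
    return ClosureFit(t_lag=t_lag, alpha=float(a), r_squared=r2, window=win)


def edge_speed(fit: ClosureFit | float, b: float) -> float:
    """Edge propagation speed v = α·b/2 for initial wound width b (µm)."""
    if b <= 0:
        raise ValueError(f"wound width b must be > 0, got {b}")
    alpha = fit.alpha if isinstance(fit, ClosureFit) else float(fit)
    return alpha * b / 2.0


def fit_doubling_time(growth: GrowthCurve) -> LogisticFit:
    """Doubling time τ of n(t) = n0 · 2^(t/τ) with n0 pinned to the first count.

    τ is the only adjustable parameter: least squares on log2(n/n0) versus
    elapsed time, through the origin.  Exact on noiseless data.  Raises if
    the counts show no growth (non-increasing, or a non-positive fitted
    rate).
    """
    if growth.times.size < 3:
        raise ValueError("need at least 3 time points to fit a doubling time")
    if growth.counts[-1] <= growth.counts[0]:
        raise ValueError("counts do not increase over the record; no growth to fit")
    n0 = float(growth.counts[0])
    dt = growth.times - growth.times[0]
    ylog = np.log2(growth.counts / n0)
    denom = float(dt @ dt)
    if denom == 0:
        raise ValueError("degenerate time axis")
    rate = float(dt @ ylog) / denom  # 1/τ
    if rate <= 0:
        raise ValueError("fitted growth rate is non-positive; no growth to fit")
    tau = 1.0 / rate
    residual = float(((ylog - rate * dt) ** 2).sum())
    return LogisticFit(n0=n0, tau=tau, residual=residual)


def growth_rate(tau: float) -> float:
    """Growth kinetic constant k = ln2/τ (1/h)."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return LN2 / tau


def motility_from_speed(v: float, tau: float) -> float:
    """Random motility coefficient D = τ·v²/(4·ln2) from edge speed and τ."""
    if v < 0:
        raise ValueError(f"edge speed v must be >= 0, got {v}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return tau * v * v / (4.0 * LN2)


def forward_speed(D: float, tau: float) -> float:
    """Fisher–KPP front speed v = sqrt(4·D·ln2/τ) = 2·sqrt(D·k)."""
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return float(np.sqrt(4.0 * D * LN2 / tau))


def thiele_modulus(b: float, k: float, D: float, convention: str = "sqrt") -> float:
    """Thiele modulus comparing proliferation to motility over the wound width.

    ``convention="sqrt"`` (default) is the standard dimensionless first-order
    form φ = b·sqrt(k/D); ``convention="literal"`` gives b²·k/D (its square).
    φ ≫ 1: proliferation-dominated closure; φ ≪ 1: migration-dominated.
    """
    if b <= 0 or k <= 0 or D <= 0:
        raise ValueError("b, k, D must all be > 0 for the Thiele modulus")
    if convention == "sqrt":
        return float(b * np.sqrt(k / D))
    if convention == "literal":
        return float(b * b * k / D)
    raise ValueError(f"unknown Thiele convention {convention!r}")


def estimate_motility(alpha: float, b: float, tau: float) -> MotilityEstimate:
    """Full algebraic chain α, b, τ → (v, k, D, φ) for one condition."""
    v = edge_speed(alpha, b)
    k = growth_rate(tau)
    D = motility_from_speed(v, tau)
    phi = thiele_modulus(b, k, D) if D > 0 else float("inf")
    return MotilityEstimate(v=v, k=k, D=D, phi=phi)
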