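"""Cell-count growth curves: exponential doubling with multiplicative noise.

A proliferating population with doubling time τ follows n(t) = n0 · 2^(t/τ).
Counts from an automated cell counter scatter multiplicatively around that
curve; the generator applies lognormal noise with a chosen coefficient of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GrowthCurve", "simulate_growth_curve"]


@dataclass
class GrowthCurve:
    """Cell counts over time (times in hours, strictly increasing; counts > 0)."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have the same length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_h": self.times, "count": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthCurve":
        df = pd.read_csv(path)
        return cls(times=df["time_h"].to_numpy(), counts=df["count"].to_numpy())


def simulate_growth_curve(
    n0: float,
    tau: float,
    times: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Simulate counter readings of an exponentially doubling population.

    Noiseless mode (``noise_cv = 0``) returns exactly n0 · 2^(t/τ); otherwise
    each count is multiplied by a lognormal factor with unit median and
    coefficient of variation ``noise_cv``.
    """
    if n0 <= 0:
        raise ValueError(f"n0 must be > 0, got {n0}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    times = np.asarray(times, dtype=float)
    counts = n0 * np.exp2(times / tau)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        counts = counts * rng.lognormal(mean=0.0, sigma=sigma, size=times.shape)
    return GrowthCurve(times=times, counts=counts)
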