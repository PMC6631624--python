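"""Replicate-level aggregation and condition comparisons.

Replicates are summarized as mean ± SEM; treated-vs-control effects are the
ratio of condition means plus a paired two-tailed t-test across replicates
(paired by replicate index).  Degenerate t-test inputs (zero-variance
differences) are flagged rather than raised so batch pipelines complete.

Two-way ANOVA with Bonferroni post-tests (as used for plate-viability
figures) is routine and out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "TTestResult",
    "summarize",
    "paired_t_test",
    "treatment_ratio",
    "viability_percent",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Mean ± SEM of one statistic over the replicates of one condition."""

    label: str
    statistic: str
    values: tuple[float, ...]
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    """Paired two-tailed t-test outcome; ``degenerate`` marks zero-variance differences."""

    p_value: float
    t_statistic: float
    degenerate: bool = False


def summarize(values, label: str = "", statistic: str = "") -> ConditionSummary:
    """Mean and standard error of the mean (SEM = sd/√n, sd with n−1 dof).

    Requires n ≥ 2: a single replicate has no defined SEM.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 replicates to report a SEM, got {arr.size}")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return ConditionSummary(
        label=label,
        statistic=statistic,
        values=tuple(arr.tolist()),
        mean=mean,
        sem=sem,
        n=int(arr.size),
    )


def paired_t_test(a, b) -> TTestResult:
    """Paired two-tailed t-test of replicate measurements a vs b.

    Pairs are matched by index.  When the paired differences have zero
    variance the t statistic is undefined: identical samples return p = 1
    and a constant non-zero shift returns p = 0, both flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return TTestResult(p_value=1.0, t_statistic=0.0, degenerate=True)
        return TTestResult(
            p_value=0.0, t_statistic=float(np.sign(diff[0]) * np.inf), degenerate=True
        )
    res = sps.ttest_rel(a, b)
    return TTestResult(p_value=float(res.pvalue), t_statistic=float(res.statistic))


def treatment_ratio(treated: ConditionSummary | float, control: ConditionSummary | float) -> float:
    """Ratio of condition means (treated / control), e.g. α_treated/α_control."""
    t_mean = treated.mean if isinstance(treated, ConditionSummary) else float(treated)
    c_mean = control.mean if isinstance(control, ConditionSummary) else float(control)
    if c_mean == 0:
        raise ValueError("control mean is zero; ratio undefined")
    return t_mean / c_mean


def viability_percent(abs_test: float, abs_control: float) -> float:
    """Cell viability CV(%) = (absorbance of test / absorbance of control) × 100."""
    if abs_control <= 0:
        raise ValueError(f"control absorbance must be > 0, got {abs_control}")
    return abs_test / abs_control * 100.0
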