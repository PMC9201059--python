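"""Parametric survival curves and partitioned-survival state membership.

Event-free survival (EFS) and overall survival (OS) are modelled with
Weibull laws ``S(t) = exp(-(t/scale)^shape)`` parameterized from reported
medians; shape 1 is the exponential special case, which is the base case
because a median alone identifies only a one-parameter family.  State
occupancy follows the partitioned-survival convention: the event-free
fraction is S_EFS, the dead fraction is 1 − S_OS, and progressed disease is
the area between the curves (floored at zero, with EFS truncated to S_OS if
the curves cross).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalCurve",
    "StateMembership",
    "ZeroSurvivalError",
    "curve_from_median",
    "survival_at",
    "cycle_event_prob",
    "partition_membership",
]

_LN2 = math.log(2.0)


class ZeroSurvivalError(ZeroDivisionError):
    """Conditional event probability is undefined: no survivors remain."""


@dataclass(frozen=True)
class SurvivalCurve:
    """A Weibull/exponential time-to-event law, time in months."""

    family: str
    scale: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "weibull"):
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.family == "exponential" and self.shape != 1.0:
            raise ValueError("exponential curves require shape 1")

    @property
    def rate(self) -> float:
        """Hazard rate (1/months) — constant only for shape 1."""
        return 1.0 / self.scale

    @property
    def median(self) -> float:
        """Time at which survival reaches one half."""
        return self.scale * _LN2 ** (1.0 / self.shape)


def curve_from_median(median: float, shape: float = 1.0) -> SurvivalCurve:
    """Build the curve whose survival at ``median`` months is exactly 1/2.

    For shape 1 this is the exponential with hazard ln(2)/median.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    scale = median / _LN2 ** (1.0 / shape)
    family = "exponential" if shape == 1.0 else "weibull"
    return SurvivalCurve(family=family, scale=scale, shape=shape)


def survival_at(curve: SurvivalCurve, t):
    """Survival probability S(t) = exp(-(t/scale)^shape); t in months."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.exp(-((t / curve.scale) ** curve.shape))
    return float(out) if out.ndim == 0 else out


def cycle_event_prob(curve: SurvivalCurve, cycle: int) -> float:
    """Conditional probability of the event during cycle ``cycle``.

    Equals 1 − S(k+1)/S(k) for the cycle spanning months [k, k+1); for
    shape 1 this is the same for every cycle (memorylessness).
    """
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    s0 = survival_at(curve, float(cycle))
    if s0 <= 0.0:
        raise ZeroSurvivalError(
            f"no survivors at cycle {cycle}; conditional probability undefined")
    s1 = survival_at(curve, float(cycle) + 1.0)
    return 1.0 - s1 / s0


@dataclass(frozen=True)
class StateMembership:
    """Cohort fractions in each health state at one cycle start."""

    cycle: int
    efs: float
    pd: float
    dead: float


def partition_membership(efs_curve: SurvivalCurve, os_curve: SurvivalCurve,
                         cycle: int) -> StateMembership:
    """Partitioned-survival occupancy at the start of ``cycle``.

    If the EFS curve lies above the OS curve (incoherent inputs), PD is
    floored at 0 and EFS truncated to S_OS so the three fractions still
    sum to one.
    """
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    t = float(cycle)
    s_efs = survival_at(efs_curve, t)
    s_os = survival_at(os_curve, t)
    efs = min(s_efs, s_os)
    return StateMembership(cycle=cycle, efs=efs, pd=s_os - efs, dead=1.0 - s_os)
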