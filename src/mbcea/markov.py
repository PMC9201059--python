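"""Monthly-cycle cohort trace with horizon and absorption termination.

The cohort enters event-free at cycle 0.  Occupancy is recorded at cycle
starts; the trace stops at the earlier of the time horizon (default 120
monthly cycles = 10 years) and the first cycle at which the dead fraction
reaches the termination threshold (default 99%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EconomicSettings
from .survival import SurvivalCurve, StateMembership, survival_at

__all__ = ["MarkovTrace", "run_trace", "run_transition_trace", "person_months"]


@dataclass(frozen=True)
class MarkovTrace:
    """State occupancy at the start of each simulated cycle.

    ``end_state`` is the occupancy at the boundary one cycle past the last
    simulated cycle; it is used only by the half-cycle (trapezoid) accrual
    convention.
    """

    cycles: np.ndarray
    efs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    terminal_cycle: int
    termination_reason: str  # "horizon" | "absorption"
    end_state: StateMembership

    def __len__(self) -> int:
        return len(self.cycles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": self.cycles, "efs": self.efs,
            "pd": self.pd, "dead": self.dead,
        })


def run_trace(efs_curve: SurvivalCurve, os_curve: SurvivalCurve,
              settings: EconomicSettings) -> MarkovTrace:
    """Run the cohort simulation and return the occupancy trace.

    Each row is one monthly cycle; cycle k spans months [k, k+1) and its
    occupancy is the partitioned-survival membership at month k.
    """
    horizon = settings.horizon_cycles
    t = np.arange(horizon + 1, dtype=float)
    s_efs = survival_at(efs_curve, t)
    s_os = survival_at(os_curve, t)
    efs = np.minimum(s_efs, s_os)
    pd_ = s_os - efs
    dead = 1.0 - s_os
    return _finalize(efs, pd_, dead, settings)


def _finalize(efs: np.ndarray, pd_: np.ndarray, dead: np.ndarray,
              settings: EconomicSettings) -> MarkovTrace:
    """Apply the termination rule to full-horizon occupancy arrays."""
    horizon = settings.horizon_cycles
    absorbed = np.nonzero(dead[:horizon] >= settings.termination_fraction)[0]
    if absorbed.size:
        last = int(absorbed[0])
        reason = "absorption"
    else:
        last = horizon - 1
        reason = "horizon"
    end = StateMembership(cycle=last + 1, efs=float(efs[last + 1]),
                          pd=float(pd_[last + 1]), dead=float(dead[last + 1]))
    sl = slice(0, last + 1)
    return MarkovTrace(
        cycles=np.arange(last + 1), efs=efs[sl], pd=pd_[sl], dead=dead[sl],
        terminal_cycle=last, termination_reason=reason, end_state=end,
    )


def run_transition_trace(efs_curve: SurvivalCurve, os_curve: SurvivalCurve,
                         pps_median: float,
                         settings: EconomicSettings) -> MarkovTrace:
    """Cohort trace under the explicit three-state transition model.

    Each cycle, patients in the event-free state die with the OS curve's
    conditional death probability and otherwise progress with the EFS
    curve's conditional event probability; progressed patients die at a
    constant post-progression hazard whose exponential law has median
    ``pps_median`` months (zero months means immediate death on
    progression).  This is the transition-probability reading of deriving
    a Markov model from published EFS and OS curves, as opposed to the
    partitioned-survival reading of :func:`run_trace`.
    """
    if pps_median < 0:
        raise ValueError("pps_median must be non-negative")
    horizon = settings.horizon_cycles
    t = np.arange(horizon + 2, dtype=float)
    s_efs = survival_at(efs_curve, t)
    s_os = survival_at(os_curve, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_exit = 1.0 - np.where(s_efs[:-1] > 0, s_efs[1:] / s_efs[:-1], 1.0)
        p_death = 1.0 - np.where(s_os[:-1] > 0, s_os[1:] / s_os[:-1], 1.0)
    p_pd_death = 1.0 if pps_median == 0 else 1.0 - 0.5 ** (1.0 / pps_median)

    n = horizon + 1
    efs = np.zeros(n)
    pd_ = np.zeros(n)
    dead = np.zeros(n)
    efs[0] = 1.0
    for k in range(n - 1):
        died_efs = efs[k] * p_death[k]
        progressed = efs[k] * (1.0 - p_death[k]) * p_exit[k]
        died_pd = pd_[k] * p_pd_death
        efs[k + 1] = efs[k] - died_efs - progressed
        pd_[k + 1] = pd_[k] + progressed - died_pd
        dead[k + 1] = dead[k] + died_efs + died_pd
    return _finalize(efs, pd_, dead, settings)


def person_months(trace: MarkovTrace, state: str,
                  half_cycle: bool = False) -> float:
    """Undiscounted person-months spent in ``state`` over the trace.

    With ``half_cycle`` the occupancy of each cycle is the average of its
    start and end values (trapezoid rule); otherwise the state-at-entry
    convention is used.
    """
    if state not in ("efs", "pd", "dead"):
        raise ValueError(f"unknown state {state!r}")
    occ = getattr(trace, state)
    if half_cycle:
        nxt = np.append(occ[1:], getattr(trace.end_state, state))
        occ = 0.5 * (occ + nxt)
    return float(np.sum(occ))
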