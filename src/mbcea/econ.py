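"""Costing, discounting, QALY accrual, and incremental cost-effectiveness.

Per-cycle costs attach to the occupancy with which each cycle starts.  The
event-free state carries drug + tests + hospitalization + adverse-event
management costs while treatment lasts (the first ``max_treatment_cycles``
cycles, 12 courses in the base case) and tests + hospitalization thereafter;
progressed disease carries the second-line treatment cost; death costs
nothing.  Utilities are annual weights, so one cycle in a state contributes
weight/12 QALYs before discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArmParameters, EconomicSettings, ModelConfig, UtilitySet
from .markov import MarkovTrace, run_trace, run_transition_trace
from .survival import curve_from_median

__all__ = [
    "ArmOutcome",
    "CEAResult",
    "discount_factor",
    "state_cycle_cost",
    "accumulate",
    "compute_icer",
    "evaluate",
    "cea_table",
    "trace_table",
]


def discount_factor(annual_rate: float, cycle) -> float | np.ndarray:
    """Discount multiplier (1+r)^(−cycle/12) for a monthly cycle index."""
    if annual_rate <= -1.0:
        raise ValueError("annual_rate must exceed -1")
    cycle = np.asarray(cycle, dtype=float)
    if np.any(cycle < 0):
        raise ValueError("cycle must be non-negative")
    out = (1.0 + annual_rate) ** (-cycle / 12.0)
    return float(out) if out.ndim == 0 else out


def state_cycle_cost(arm: ArmParameters, state: str, cycle: int) -> float:
    """Undiscounted cost (USD) of one cycle spent in ``state``."""
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    if state == "efs":
        if cycle < arm.max_treatment_cycles:
            return arm.efs_on_treatment_cost
        return arm.efs_off_treatment_cost
    if state == "pd":
        return arm.second_line_cost_per_cycle
    if state == "dead":
        return 0.0
    raise ValueError(f"unknown state {state!r}")


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm, broken down by health state."""

    c_efs: float
    c_pd: float
    u_efs_total: float
    u_pd_total: float

    @property
    def total_cost(self) -> float:
        return self.c_efs + self.c_pd

    @property
    def total_qaly(self) -> float:
        return self.u_efs_total + self.u_pd_total

    @property
    def ce_ratio(self) -> float:
        """Average cost per QALY for this arm alone."""
        if self.total_qaly == 0:
            return math.nan
        return self.total_cost / self.total_qaly


def accumulate(trace: MarkovTrace, arm: ArmParameters, utilities: UtilitySet,
               settings: EconomicSettings) -> ArmOutcome:
    """Sum discounted costs and QALYs over the trace for one arm."""
    k = trace.cycles
    efs_occ = trace.efs
    pd_occ = trace.pd
    if settings.half_cycle_correction:
        efs_next = np.append(efs_occ[1:], trace.end_state.efs)
        pd_next = np.append(pd_occ[1:], trace.end_state.pd)
        efs_occ = 0.5 * (efs_occ + efs_next)
        pd_occ = 0.5 * (pd_occ + pd_next)
    disc = discount_factor(settings.annual_discount_rate, k)
    efs_cost = np.where(k < arm.max_treatment_cycles,
                        arm.efs_on_treatment_cost, arm.efs_off_treatment_cost)
    return ArmOutcome(
        c_efs=float(np.sum(efs_occ * efs_cost * disc)),
        c_pd=float(np.sum(pd_occ * arm.second_line_cost_per_cycle * disc)),
        u_efs_total=float(np.sum(efs_occ * (utilities.u_efs / 12.0) * disc)),
        u_pd_total=float(np.sum(pd_occ * (utilities.u_pd / 12.0) * disc)),
    )


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: ArmOutcome
    comparator: ArmOutcome
    intervention_name: str = "T+I+B"
    comparator_name: str = "T+I"

    @property
    def incremental_cost(self) -> float:
        return self.intervention.total_cost - self.comparator.total_cost

    @property
    def incremental_qaly(self) -> float:
        return self.intervention.total_qaly - self.comparator.total_qaly

    @property
    def dominance(self) -> str:
        dc, dq = self.incremental_cost, self.incremental_qaly
        if dc < 0 and dq > 0:
            return "intervention_dominant"
        if dc > 0 and dq < 0:
            return "intervention_dominated"
        return "none"

    @property
    def icer(self) -> float | None:
        """Incremental cost per QALY; None when undefined or dominated."""
        if self.incremental_qaly == 0 or self.dominance != "none":
            return None
        return self.incremental_cost / self.incremental_qaly


def compute_icer(intervention: ArmOutcome, comparator: ArmOutcome,
                 intervention_name: str = "T+I+B",
                 comparator_name: str = "T+I") -> CEAResult:
    """Incremental cost, incremental QALYs and ICER of two arm outcomes."""
    return CEAResult(intervention=intervention, comparator=comparator,
                     intervention_name=intervention_name,
                     comparator_name=comparator_name)


def build_trace(arm: ArmParameters, config: ModelConfig) -> MarkovTrace:
    """Cohort trace for one arm under the configured structural mode.

    ``transition`` runs the explicit three-state Markov model with
    post-progression survival at median (OS − EFS); ``partitioned`` derives
    occupancy directly from the areas between the EFS and OS curves.
    """
    shape = config.survival_shape
    efs_curve = curve_from_median(arm.median_efs, shape)
    os_curve = curve_from_median(arm.median_os, shape)
    if config.structural_mode == "partitioned":
        return run_trace(efs_curve, os_curve, config.settings)
    return run_transition_trace(efs_curve, os_curve,
                                arm.median_os - arm.median_efs,
                                config.settings)


def evaluate(config: ModelConfig) -> CEAResult:
    """Run the full base-case pipeline for both arms of a configuration."""
    outcomes = {}
    for key in ("tib", "ti"):
        arm = getattr(config, key)
        trace = build_trace(arm, config)
        outcomes[key] = accumulate(trace, arm, config.utilities, config.settings)
    return compute_icer(outcomes["tib"], outcomes["ti"],
                        config.tib.name, config.ti.name)


def trace_table(trace: MarkovTrace, arm: ArmParameters, utilities: UtilitySet,
                settings: EconomicSettings) -> pd.DataFrame:
    """Per-cycle trace with discounted cost and QALY increments."""
    k = trace.cycles
    efs_occ, pd_occ = trace.efs, trace.pd
    if settings.half_cycle_correction:
        efs_occ = 0.5 * (efs_occ + np.append(efs_occ[1:], trace.end_state.efs))
        pd_occ = 0.5 * (pd_occ + np.append(pd_occ[1:], trace.end_state.pd))
    disc = discount_factor(settings.annual_discount_rate, k)
    efs_cost = np.where(k < arm.max_treatment_cycles,
                        arm.efs_on_treatment_cost, arm.efs_off_treatment_cost)
    cost = (efs_occ * efs_cost + pd_occ * arm.second_line_cost_per_cycle) * disc
    qaly = (efs_occ * utilities.u_efs + pd_occ * utilities.u_pd) / 12.0 * disc
    df = trace.to_frame()
    df["discounted_cost"] = cost
    df["discounted_qaly"] = qaly
    return df


def cea_table(result: CEAResult, decimals: int = 3) -> pd.DataFrame:
    """Result table: per-arm breakdown, totals, increments and the ICER."""
    a, b = result.intervention, result.comparator
    icer = result.icer
    rows = {
        "cEFS": (a.c_efs, b.c_efs),
        "cPD": (a.c_pd, b.c_pd),
        "uEFS": (a.u_efs_total, b.u_efs_total),
        "uPD": (a.u_pd_total, b.u_pd_total),
        "Total costs": (a.total_cost, b.total_cost),
        "Total effectiveness": (a.total_qaly, b.total_qaly),
        "Incremental costs": (result.incremental_cost, math.nan),
        "Incremental effectiveness": (result.incremental_qaly, math.nan),
        "Total C/E": (a.ce_ratio, b.ce_ratio),
        "ICER $/QALY": (icer if icer is not None else math.nan, math.nan),
    }
    df = pd.DataFrame(rows, index=[result.intervention_name,
                                   result.comparator_name]).T
    df.index.name = "Parameters"
    if result.icer is None:
        df.attrs["icer_note"] = result.dominance if result.dominance != "none" \
            else "undefined (zero incremental QALY)"
    return df.round(decimals)
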