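"""Pseudo individual-patient data from published Kaplan–Meier curves.

Published survival figures report only the curve and a numbers-at-risk
table.  To refit parametric models one first recovers approximate
patient-level event and censoring times.  This module implements the
standard interval-wise allocation scheme: within each risk-table interval
it finds the event count behind every curve drop and a censor count,
censoring spread uniformly over the interval, such that re-running the
product-limit estimator reproduces the curve and the at-risk trajectory.
The procedure is deterministic.

`km_estimate` wraps lifelines' product-limit estimator; `fit_parametric`
uses the closed-form censored MLE for the exponential family (rate =
events / total follow-up) and lifelines' Weibull fitter otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter, WeibullFitter

from .survival import SurvivalCurve

__all__ = [
    "KMCurveInput",
    "PseudoIPD",
    "FitError",
    "km_estimate",
    "reconstruct_ipd",
    "fit_parametric",
]


class FitError(ValueError):
    """Parametric fitting is impossible (e.g. no events observed)."""


@dataclass(frozen=True)
class KMCurveInput:
    """Digitized curve coordinates plus the numbers-at-risk table."""

    times: np.ndarray       # months, non-decreasing
    survival: np.ndarray    # probabilities, non-increasing
    risk_times: np.ndarray  # months
    n_at_risk: np.ndarray   # counts, non-increasing

    def __post_init__(self) -> None:
        for name in ("times", "survival", "risk_times", "n_at_risk"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.times) != len(self.survival) or len(self.times) == 0:
            raise ValueError("times and survival must be equal-length, nonempty")
        if len(self.risk_times) != len(self.n_at_risk) or len(self.risk_times) == 0:
            raise ValueError("risk table must be nonempty and consistent")
        if np.any(np.diff(self.times) < 0) or np.any(np.diff(self.risk_times) < 0):
            raise ValueError("time grids must be non-decreasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("inconsistent risk table: n_at_risk increases")


@dataclass(frozen=True)
class PseudoIPD:
    """Per-pseudo-patient follow-up time and event indicator."""

    time: np.ndarray
    event: np.ndarray  # 1 event, 0 censored

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        if len(self.time) != len(self.event) or len(self.time) == 0:
            raise ValueError("time and event must be equal-length, nonempty")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)


def km_estimate(ipd: PseudoIPD) -> KMCurveInput:
    """Product-limit survival estimate with a risk table at the step grid."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    grid = np.unique(np.concatenate(([0.0], ipd.time)))
    surv = kmf.survival_function_at_times(grid).to_numpy()
    n_at_risk = np.array([(ipd.time >= t).sum() for t in grid], dtype=float)
    return KMCurveInput(times=grid, survival=surv,
                        risk_times=grid, n_at_risk=n_at_risk)


def _simulate_interval(n_start: float, s_entry: float, click_t: np.ndarray,
                       click_s: np.ndarray, censor_times: np.ndarray):
    """Process one risk interval: events from drops, censors interleaved.

    Returns (events per click, n remaining, KM value at exit).
    """
    n_cur = int(n_start)
    s_run = s_entry
    used = np.zeros(len(censor_times), dtype=bool)
    events = np.zeros(len(click_t), dtype=int)
    for i, (t, s) in enumerate(zip(click_t, click_s)):
        before = (~used) & (censor_times < t)
        n_cur -= int(before.sum())
        used |= before
        if n_cur > 0 and s_run > 0 and s < s_run:
            d = int(np.floor(n_cur * (1.0 - s / s_run) + 0.5))
            d = min(max(d, 0), n_cur)
        else:
            d = 0
        if d > 0:
            s_run *= 1.0 - d / n_cur
            n_cur -= d
        events[i] = d
    n_cur -= int((~used).sum())
    return events, n_cur, s_run


def reconstruct_ipd(curve: KMCurveInput) -> PseudoIPD:
    """Recover pseudo patient-level data from curve + risk table.

    Within each interval between consecutive risk-table times, the censor
    count is found by fixed-point iteration so the reconstructed number at
    risk matches the table; censoring times are spread uniformly over the
    interval.  Patients still at risk after the last interval are censored
    at the end of follow-up.
    """
    times = curve.times
    surv = curve.survival
    rt = curve.risk_times
    n_tab = curve.n_at_risk

    t_end = max(times[-1], rt[-1])
    out_t: list[float] = []
    out_e: list[int] = []

    n_cur = int(n_tab[0])
    s_km = 1.0
    for j in range(len(rt)):
        lo = rt[j]
        hi = rt[j + 1] if j + 1 < len(rt) else np.inf
        mask = (times >= lo) & (times < hi) if np.isfinite(hi) else (times >= lo)
        click_t = times[mask]
        click_s = surv[mask]

        if not np.isfinite(hi):
            events, n_after, s_km = _simulate_interval(
                n_cur, s_km, click_t, click_s, np.array([]))
            for t, d in zip(click_t, events):
                out_t.extend([t] * d)
                out_e.extend([1] * d)
            if n_after > 0:  # administratively censored at end of follow-up
                out_t.extend([t_end] * n_after)
                out_e.extend([0] * n_after)
            n_cur = 0
            break

        target = int(n_tab[j + 1])
        width = hi - lo
        c = max(0, n_cur - target)  # initial guess: all exits censored
        best = None
        seen: set[int] = set()
        for _ in range(200):
            censor_times = lo + width * (np.arange(1, c + 1) / (c + 1))
            events, n_after, s_exit = _simulate_interval(
                n_cur, s_km, click_t, click_s, censor_times)
            gap = n_after - target
            if best is None or abs(gap) < abs(best[0]):
                best = (gap, c, events, censor_times, s_exit)
            if gap == 0 or c in seen:
                break
            seen.add(c)
            c = max(0, c + gap)
        gap, c, events, censor_times, s_exit = best
        for t, d in zip(click_t, events):
            out_t.extend([t] * d)
            out_e.extend([1] * d)
        out_t.extend(censor_times.tolist())
        out_e.extend([0] * len(censor_times))
        if gap > 0:  # residual exits censored at the interval boundary
            out_t.extend([np.nextafter(hi, lo)] * gap)
            out_e.extend([0] * gap)
            n_cur = target
        else:
            n_cur = n_after
        s_km = s_exit

    order = np.lexsort((np.asarray(out_e), np.asarray(out_t)))
    return PseudoIPD(time=np.asarray(out_t)[order], event=np.asarray(out_e)[order])


def fit_parametric(ipd: PseudoIPD, family: str = "exponential") -> SurvivalCurve:
    """Maximum-likelihood parametric fit under right censoring."""
    events = int(ipd.event.sum())
    if events == 0:
        raise FitError("cannot fit a parametric model with zero events")
    if family == "exponential":
        exposure = float(ipd.time.sum())
        rate = events / exposure
        return SurvivalCurve(family="exponential", scale=1.0 / rate, shape=1.0)
    if family == "weibull":
        wf = WeibullFitter()
        t = np.clip(ipd.time, 1e-9, None)  # lifelines requires positive durations
        wf.fit(t, ipd.event)
        return SurvivalCurve(family="weibull", scale=float(wf.lambda_),
                             shape=float(wf.rho_))
    raise ValueError(f"unknown family {family!r}")
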