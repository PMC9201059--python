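"""Synthetic two-arm trial generator for testing the reconstruction path.

Emulates a small randomized screening trial: per-patient event-free
survival (EFS) times drawn from a Weibull law at a target median, overall
survival (OS) generated as EFS plus an exponential post-progression
survival whose rate is solved numerically so the marginal OS median hits
its target — guaranteeing the per-patient coherence OS >= EFS that the
partitioned-survival model assumes.  Administrative censoring truncates
follow-up at a fixed calendar time.

`km_inputs_from_trial` turns simulated records into the digitized-curve
stand-in (survival sampled on a regular grid plus numbers at risk) consumed
by :mod:`mbcea.ipd`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import integrate, optimize

from .ipd import KMCurveInput
from .survival import curve_from_median, survival_at

__all__ = ["TrialSpec", "simulate_trial", "km_inputs_from_trial", "pps_rate"]


@dataclass(frozen=True)
class TrialSpec:
    """One arm's generative parameters.

    Defaults mirror a small phase-II screening-trial scale (50 patients per
    arm) with two years of administrative follow-up.
    """

    n_per_arm: int = 50
    efs_median: float = 9.0
    os_median: float = 19.0
    shape: float = 1.0
    admin_censor_time: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.efs_median <= 0 or self.os_median <= 0:
            raise ValueError("medians must be positive")
        if self.efs_median > self.os_median:
            raise ValueError("efs_median must not exceed os_median")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")


def _marginal_os_survival(t: float, efs_median: float, shape: float,
                          lam_pps: float) -> float:
    """P(EFS + PPS > t) with Weibull EFS and exponential post-progression."""
    curve = curve_from_median(efs_median, shape)
    s_efs = survival_at(curve, t)
    if shape == 1.0:
        lam_e = curve.rate
        if abs(lam_e - lam_pps) < 1e-12 * lam_e:
            return float((1.0 + lam_e * t) * np.exp(-lam_e * t))
        return float((lam_e * np.exp(-lam_pps * t) - lam_pps * np.exp(-lam_e * t))
                     / (lam_e - lam_pps))

    def integrand(u: float) -> float:
        k, lam = curve.shape, curve.scale
        dens = (k / lam) * (u / lam) ** (k - 1.0) * np.exp(-((u / lam) ** k))
        return dens * np.exp(-lam_pps * (t - u))

    tail, _ = integrate.quad(integrand, 0.0, t, limit=200)
    return float(s_efs + tail)


def pps_rate(efs_median: float, os_median: float, shape: float = 1.0) -> float:
    """Post-progression hazard giving the requested marginal OS median.

    Returns ``inf`` when the two medians coincide (progression and death
    simultaneous).
    """
    if os_median <= efs_median * (1.0 + 1e-12):
        return np.inf

    def objective(lam: float) -> float:
        return _marginal_os_survival(os_median, efs_median, shape, lam) - 0.5

    return optimize.brentq(objective, 1e-8, 1e3, xtol=1e-10)


def simulate_trial(spec: TrialSpec) -> pd.DataFrame:
    """Draw one arm of per-patient (efs_time, efs_event, os_time, os_event).

    Times are administratively censored at ``spec.admin_censor_time``
    (event indicator 0 and follow-up truncated).  Fixed seed gives
    bit-reproducible records.
    """
    rng = np.random.default_rng(spec.seed)
    curve = curve_from_median(spec.efs_median, spec.shape)
    efs = curve.scale * rng.weibull(spec.shape, spec.n_per_arm)
    lam_pps = pps_rate(spec.efs_median, spec.os_median, spec.shape)
    if np.isinf(lam_pps):
        pps = np.zeros(spec.n_per_arm)
    else:
        pps = rng.exponential(1.0 / lam_pps, spec.n_per_arm)
    os_ = efs + pps

    cens = spec.admin_censor_time
    return pd.DataFrame({
        "efs_time": np.minimum(efs, cens),
        "efs_event": (efs < cens).astype(int),
        "os_time": np.minimum(os_, cens),
        "os_event": (os_ < cens).astype(int),
    })


def km_inputs_from_trial(records: pd.DataFrame,
                         grid_step: float = 1.0) -> dict[str, KMCurveInput]:
    """Digitized-curve stand-ins for both endpoints on a regular grid."""
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    out: dict[str, KMCurveInput] = {}
    for endpoint in ("efs", "os"):
        time = records[f"{endpoint}_time"].to_numpy()
        event = records[f"{endpoint}_event"].to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time, event)
        n_steps = int(np.ceil(time.max() / grid_step))
        grid = grid_step * np.arange(n_steps + 1)
        surv = kmf.survival_function_at_times(grid).to_numpy()
        n_at_risk = np.array([(time >= t).sum() for t in grid], dtype=float)
        out[endpoint] = KMCurveInput(times=grid, survival=surv,
                                     risk_times=grid, n_at_risk=n_at_risk)
    return out
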