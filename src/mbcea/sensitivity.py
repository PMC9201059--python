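"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the model with each parameter at the ends of its range
(default ±20% of base; discount rate 0–5%; utility ranges clipped so the
ordering u_pd <= u_efs is preserved) and ranks parameters by the ICER span
they induce (tornado order).  `threshold_search` bisects a single monotone
parameter to the value at which the ICER meets a target such as the
willingness-to-pay threshold.

The PSA draws costs from Gamma laws (moment-matched, SE 20% of the mean),
utilities from Beta laws (SE 10%, comonotone across states — both utilities
share one quantile draw, which keeps the Beta marginals exact while
preserving the ordering u_pd <= u_efs) and survival medians from Gamma laws
(SE 10%, per-arm EFS <= OS enforced by redraw),
re-evaluates the model each iteration, and summarizes the incremental
cost-effectiveness plane and the cost-effectiveness acceptability curve
(CEAC) under the net-monetary-benefit rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ArmParameters, ConfigError, ModelConfig
from .econ import evaluate

__all__ = [
    "DSAEntry",
    "PSAResult",
    "parameter_names",
    "get_parameter",
    "set_parameter",
    "default_ranges",
    "one_way_dsa",
    "dsa_table",
    "threshold_search",
    "run_psa",
    "ceac_curve",
    "median_icer",
    "gamma_params",
    "beta_params",
    "percent_reduction",
]


# ---------------------------------------------------------------------------
# Parameter registry: uniform get/set access for DSA and PSA


def _replace_arm(config: ModelConfig, key: str, **changes) -> ModelConfig:
    arm = dataclasses.replace(getattr(config, key), **changes)
    return dataclasses.replace(config, **{key: arm})


def _set_component(config: ModelConfig, key: str, comp: str,
                   value: float) -> ModelConfig:
    comps = dict(getattr(config, key).drug_components)
    comps[comp] = value
    return _replace_arm(config, key, drug_components=comps,
                        drug_cost_per_cycle=None)


def _set_efs_state_cost(config: ModelConfig, key: str, value: float) -> ModelConfig:
    """Scale every event-free-state cost component by a common factor."""
    arm = getattr(config, key)
    factor = value / arm.efs_on_treatment_cost
    comps = {k: v * factor for k, v in (arm.drug_components or {}).items()}
    return _replace_arm(
        config, key,
        drug_components=comps or None,
        drug_cost_per_cycle=None if comps else arm.drug_cost_per_cycle * factor,
        tests_cost_per_cycle=arm.tests_cost_per_cycle * factor,
        hospitalization_cost_per_cycle=arm.hospitalization_cost_per_cycle * factor,
        ae_cost_per_cycle=arm.ae_cost_per_cycle * factor,
    )


def _registry() -> dict[str, tuple[Callable, Callable]]:
    reg: dict[str, tuple[Callable, Callable]] = {}
    for key in ("tib", "ti"):
        arm_comps = ("tmz", "irt", "bev") if key == "tib" else ("tmz", "irt")
        for comp in arm_comps:
            reg[f"drug_cost_{comp}_{key}"] = (
                lambda c, key=key, comp=comp: getattr(c, key).drug_components[comp],
                lambda c, v, key=key, comp=comp: _set_component(c, key, comp, v),
            )
        for fname, label in (
            ("second_line_cost_per_cycle", "second_line_cost"),
            ("hospitalization_cost_per_cycle", "hospitalization_cost"),
            ("ae_cost_per_cycle", "ae_cost"),
            ("tests_cost_per_cycle", "tests_cost"),
        ):
            reg[f"{label}_{key}"] = (
                lambda c, key=key, fname=fname: getattr(getattr(c, key), fname),
                lambda c, v, key=key, fname=fname: _replace_arm(c, key, **{fname: v}),
            )
        reg[f"efs_state_cost_{key}"] = (
            lambda c, key=key: getattr(c, key).efs_on_treatment_cost,
            lambda c, v, key=key: _set_efs_state_cost(c, key, v),
        )
        for fname in ("median_efs", "median_os"):
            reg[f"{fname}_{key}"] = (
                lambda c, key=key, fname=fname: getattr(getattr(c, key), fname),
                lambda c, v, key=key, fname=fname: _replace_arm(c, key, **{fname: v}),
            )
    for uname in ("u_efs", "u_pd"):
        reg[uname] = (
            lambda c, uname=uname: getattr(c.utilities, uname),
            lambda c, v, uname=uname: dataclasses.replace(
                c, utilities=dataclasses.replace(c.utilities, **{uname: v})),
        )
    reg["discount_rate"] = (
        lambda c: c.settings.annual_discount_rate,
        lambda c, v: dataclasses.replace(
            c, settings=dataclasses.replace(c.settings, annual_discount_rate=v)),
    )
    # inert internally (all model costs are already USD); kept in the tornado
    # so the ranking shows the conversion assumption carries no leverage
    reg["exchange_rate"] = (
        lambda c: c.settings.exchange_rate,
        lambda c, v: dataclasses.replace(
            c, settings=dataclasses.replace(c.settings, exchange_rate=v)),
    )
    return reg


_REGISTRY = _registry()

# Cost parameters varied in the PSA (Gamma draws).
_COST_PARAMS = [n for n in _REGISTRY
                if n.startswith(("drug_cost_", "second_line_cost_",
                                 "hospitalization_cost_", "ae_cost_",
                                 "tests_cost_"))]
_MEDIAN_PARAMS = [n for n in _REGISTRY if n.startswith("median_")]

# The deterministic tornado covers prices, utilities and the discount rate;
# survival uncertainty is handled probabilistically in the PSA.
_DSA_PARAMS = ([n for n in _COST_PARAMS] +
               [n for n in _REGISTRY if n.startswith("efs_state_cost_")] +
               ["u_efs", "u_pd", "discount_rate", "exchange_rate"])


def parameter_names() -> list[str]:
    """All registered parameter names."""
    return list(_REGISTRY)


def get_parameter(config: ModelConfig, name: str) -> float:
    try:
        getter, _ = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown parameter {name!r}") from None
    return getter(config)


def set_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a new config with one named parameter replaced."""
    try:
        _, setter = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown parameter {name!r}") from None
    return setter(config, value)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis


@dataclass(frozen=True)
class DSAEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float
    base_icer: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def default_ranges(config: ModelConfig,
                   rel: float = 0.20) -> dict[str, tuple[float, float]]:
    """±`rel` ranges for the default DSA set, with coherence clipping."""
    ranges: dict[str, tuple[float, float]] = {}
    for name in _DSA_PARAMS:
        base = get_parameter(config, name)
        if name == "discount_rate":
            ranges[name] = (0.0, 0.05)
        elif name == "u_efs":
            ranges[name] = (max(base * (1 - rel), config.utilities.u_pd),
                            min(base * (1 + rel), 1.0))
        elif name == "u_pd":
            ranges[name] = (max(base * (1 - rel), config.utilities.u_death),
                            min(base * (1 + rel), config.utilities.u_efs))
        else:
            ranges[name] = (base * (1 - rel), base * (1 + rel))
    return ranges


def _icer_at(config: ModelConfig, name: str, value: float) -> float:
    result = evaluate(set_parameter(config, name, value))
    return np.nan if result.icer is None else result.icer


def one_way_dsa(config: ModelConfig,
                ranges: Mapping[str, tuple[float, float]] | None = None
                ) -> list[DSAEntry]:
    """Re-run the model at each parameter's range ends; tornado-ordered."""
    if ranges is None:
        ranges = default_ranges(config)
    base_result = evaluate(config)
    if base_result.icer is None:
        raise ConfigError("base configuration has no defined ICER")
    base_icer = base_result.icer
    entries = []
    for name, (low, high) in ranges.items():
        base = get_parameter(config, name)
        if not (low <= base <= high):
            raise ConfigError(
                f"range for {name} does not bracket its base value {base}")
        entries.append(DSAEntry(
            parameter=name, low_value=low, high_value=high,
            icer_low=_icer_at(config, name, low),
            icer_high=_icer_at(config, name, high),
            base_icer=base_icer,
        ))
    entries.sort(key=lambda e: -e.span)
    return entries


def dsa_table(entries: Sequence[DSAEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low_value": e.low_value,
        "high_value": e.high_value, "icer_low": e.icer_low,
        "icer_high": e.icer_high, "span": e.span, "base_icer": e.base_icer,
    } for e in entries])


def threshold_search(config: ModelConfig, parameter: str, target_icer: float,
                     bounds: tuple[float, float], tol: float = 1.0,
                     max_iter: int = 100) -> float | None:
    """Bisect one parameter to the value where the ICER meets a target.

    Returns None when the ICER does not cross the target on ``bounds``
    (no threshold in range).  Assumes the ICER is monotone in the
    parameter over the bounds.
    """
    lo, hi = bounds
    f_lo = _icer_at(config, parameter, lo) - target_icer
    f_hi = _icer_at(config, parameter, hi) - target_icer
    if np.isnan(f_lo) or np.isnan(f_hi) or f_lo * f_hi > 0:
        return None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _icer_at(config, parameter, mid) - target_icer
        if abs(f_mid) <= tol:
            return mid
        if f_mid * f_lo <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def percent_reduction(old: float, new: float) -> float:
    """Percent decrease from ``old`` to ``new`` (positive = reduction)."""
    if old <= 0:
        raise ValueError("old must be positive")
    return (old - new) / old * 100.0


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


def gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Gamma (shape k, scale theta) for a given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


def beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta (alpha, beta) for a given mean and SD."""
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    if sd ** 2 >= mean * (1 - mean):
        raise ConfigError(
            f"no Beta distribution has mean {mean} and sd {sd}")
    total = mean * (1 - mean) / sd ** 2 - 1.0
    return mean * total, (1 - mean) * total


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo parameter draws, CE-plane points, and the CEAC."""

    draws: pd.DataFrame   # one column per varied parameter
    points: pd.DataFrame  # inc_cost, inc_qaly, icer (NaN when undefined)
    ceac: pd.DataFrame    # wtp, probability
    seed: int

    def __len__(self) -> int:
        return len(self.points)


def _draw_cost(rng: np.random.Generator, mean: float, rel_se: float) -> float:
    if mean == 0:
        return 0.0
    shape, scale = gamma_params(mean, rel_se * mean)
    return float(rng.gamma(shape, scale))


def run_psa(config: ModelConfig, seed: int, iterations: int | None = None,
            cost_rel_se: float = 0.20, utility_rel_se: float = 0.10,
            median_rel_se: float = 0.10,
            wtp_grid: np.ndarray | None = None) -> PSAResult:
    """Monte-Carlo PSA: draw parameters, re-run the model each iteration.

    A fixed seed makes the draws bit-reproducible.  The discount rate is
    held fixed (it is examined deterministically in the DSA).
    """
    n = config.settings.psa_iterations if iterations is None else iterations
    rng = np.random.default_rng(seed)
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 2.0 * config.settings.wtp_threshold, 41)
    ab_efs = beta_params(config.utilities.u_efs,
                         utility_rel_se * config.utilities.u_efs)
    ab_pd = beta_params(config.utilities.u_pd,
                        utility_rel_se * config.utilities.u_pd)

    draw_rows = []
    point_rows = []
    for _ in range(n):
        draws: dict[str, float] = {}
        cfg = config
        for name in _COST_PARAMS:
            value = _draw_cost(rng, get_parameter(config, name), cost_rel_se)
            draws[name] = value
            cfg = set_parameter(cfg, name, value)
        # utilities: one shared quantile through both Beta laws keeps the
        # marginals exact; the ordering can only break in the extreme lower
        # tail (~0.1% of draws), where u_pd is clamped to u_efs
        q = rng.random()
        u_efs = float(stats.beta.ppf(q, *ab_efs))
        u_pd = float(stats.beta.ppf(q, *ab_pd))
        u_pd = min(u_pd, u_efs)
        draws["u_efs"], draws["u_pd"] = u_efs, u_pd
        cfg = dataclasses.replace(cfg, utilities=dataclasses.replace(
            config.utilities, u_efs=u_efs, u_pd=u_pd))
        # medians: redraw per arm until EFS <= OS
        for key in ("tib", "ti"):
            arm: ArmParameters = getattr(config, key)
            for _ in range(1000):
                m_efs = float(rng.gamma(*gamma_params(
                    arm.median_efs, median_rel_se * arm.median_efs)))
                m_os = float(rng.gamma(*gamma_params(
                    arm.median_os, median_rel_se * arm.median_os)))
                if m_efs <= m_os:
                    break
            else:  # pragma: no cover
                m_os = m_efs
            draws[f"median_efs_{key}"] = m_efs
            draws[f"median_os_{key}"] = m_os
            cfg = _replace_arm(cfg, key, median_efs=m_efs, median_os=m_os)

        result = evaluate(cfg)
        dq = result.incremental_qaly
        dc = result.incremental_cost
        icer = dc / dq if dq > 0 else np.nan
        draw_rows.append(draws)
        point_rows.append({"inc_cost": dc, "inc_qaly": dq, "icer": icer})

    points = pd.DataFrame(point_rows)
    probs = ceac_curve(points, wtp_grid)
    ceac = pd.DataFrame({"wtp": wtp_grid, "probability": probs})
    return PSAResult(draws=pd.DataFrame(draw_rows), points=points,
                     ceac=ceac, seed=seed)


def ceac_curve(points: pd.DataFrame, wtp_grid) -> np.ndarray:
    """P(intervention cost-effective) vs WTP, by net monetary benefit.

    For each threshold lambda the probability is the fraction of
    iterations with lambda * dQALY − dCost > 0.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        return np.array([])
    if len(points) == 0:
        raise ValueError("points must be nonempty")
    dq = points["inc_qaly"].to_numpy()
    dc = points["inc_cost"].to_numpy()
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    return (nmb > 0).mean(axis=1)


def median_icer(result: PSAResult) -> float:
    """Median per-iteration ICER, excluding non-positive incremental QALYs."""
    icers = result.points["icer"].to_numpy()
    valid = icers[np.isfinite(icers)]
    if valid.size == 0:
        raise ValueError("no iterations with positive incremental QALYs")
    return float(np.median(valid))
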