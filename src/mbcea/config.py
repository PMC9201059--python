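"""Model parameters: loading, validation, currency conversion, and dosing.

All monetary quantities are carried internally in USD; renminbi amounts are
converted once at the configuration boundary with :func:`cny_to_usd`.
The bundled fixture ``data/table1.yaml`` holds the base-case parameter set
for the two regimens compared by the model: temozolomide + irinotecan +
bevacizumab (the triplet, ``tib``) versus temozolomide + irinotecan (the
doublet, ``ti``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "EconomicSettings",
    "ArmParameters",
    "UtilitySet",
    "RegimenDosing",
    "ModelConfig",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "default_config_path",
    "load_default_config",
    "cny_to_usd",
    "body_surface_area",
    "doses_per_cycle",
]


class ConfigError(ValueError):
    """A configuration value is missing or violates a model invariant."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


@dataclass(frozen=True)
class EconomicSettings:
    """Global model settings.

    Parameters
    ----------
    annual_discount_rate
        Annual discount rate applied to both costs and QALYs (fraction/year).
    wtp_threshold
        Willingness-to-pay threshold in USD per QALY (three times China's
        per-capita GDP in the base case).
    exchange_rate
        CNY per USD used at the configuration boundary.
    cycle_length
        Model cycle length in months; the model is built around monthly
        cycles and this is fixed at 1.
    horizon_cycles
        Time horizon in cycles (120 = 10 years of monthly cycles).
    termination_fraction
        The cohort trace stops early once this fraction of the cohort has
        been absorbed into the death state.
    psa_iterations
        Monte-Carlo repetitions for the probabilistic sensitivity analysis.
    half_cycle_correction
        If True, costs and QALYs accrue on mid-cycle (trapezoid) occupancy
        instead of the default state-at-cycle-entry occupancy.
    """

    annual_discount_rate: float = 0.03
    wtp_threshold: float = 38136.26
    exchange_rate: float = 6.437
    cycle_length: float = 1.0
    horizon_cycles: int = 120
    termination_fraction: float = 0.99
    psa_iterations: int = 1000
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        _require(0.0 <= self.annual_discount_rate < 1.0,
                 "annual_discount_rate must satisfy 0 <= rate < 1")
        _require(self.wtp_threshold > 0, "wtp_threshold must be positive")
        _require(self.exchange_rate > 0, "exchange_rate must be positive")
        _require(self.cycle_length == 1.0,
                 "cycle_length is fixed at 1 month in this model")
        _require(self.horizon_cycles >= 1, "horizon_cycles must be >= 1")
        _require(0.0 < self.termination_fraction <= 1.0,
                 "termination_fraction must lie in (0, 1]")
        _require(self.psa_iterations >= 1, "psa_iterations must be >= 1")


@dataclass(frozen=True)
class ArmParameters:
    """All per-arm quantities: survival medians and per-cycle costs (USD).

    ``drug_components`` optionally itemizes the per-cycle drug cost by agent
    (keys such as ``tmz``, ``irt``, ``bev``).  When present, the total
    ``drug_cost_per_cycle`` is derived as the component sum; if both are
    supplied they must agree to within one cent.
    """

    name: str
    median_efs: float
    median_os: float
    second_line_cost_per_cycle: float
    hospitalization_cost_per_cycle: float
    ae_cost_per_cycle: float
    tests_cost_per_cycle: float
    drug_cost_per_cycle: float | None = None
    max_treatment_cycles: int = 12
    drug_components: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        _require(self.median_efs > 0, f"{self.name}: median_efs must be > 0")
        _require(self.median_efs <= self.median_os,
                 f"{self.name}: median_efs must not exceed median_os")
        _require(self.max_treatment_cycles >= 0,
                 f"{self.name}: max_treatment_cycles must be >= 0")
        if self.drug_components is not None:
            components = dict(self.drug_components)
            for key, value in components.items():
                _require(value >= 0, f"{self.name}: drug component {key} must be >= 0")
            total = sum(components.values())
            if self.drug_cost_per_cycle is None:
                object.__setattr__(self, "drug_cost_per_cycle", total)
            else:
                _require(abs(self.drug_cost_per_cycle - total) <= 0.01,
                         f"{self.name}: drug_cost_per_cycle does not match "
                         f"the sum of drug_components ({total:.2f})")
            object.__setattr__(self, "drug_components", components)
        _require(self.drug_cost_per_cycle is not None,
                 f"{self.name}: drug_cost_per_cycle or drug_components required")
        for fname in ("drug_cost_per_cycle", "second_line_cost_per_cycle",
                      "hospitalization_cost_per_cycle", "ae_cost_per_cycle",
                      "tests_cost_per_cycle"):
            _require(getattr(self, fname) >= 0, f"{self.name}: {fname} must be >= 0")

    @property
    def efs_on_treatment_cost(self) -> float:
        """Per-cycle cost of the event-free state during treatment."""
        return (self.drug_cost_per_cycle + self.tests_cost_per_cycle
                + self.hospitalization_cost_per_cycle + self.ae_cost_per_cycle)

    @property
    def efs_off_treatment_cost(self) -> float:
        """Per-cycle cost of the event-free state beyond the treatment cap."""
        return self.tests_cost_per_cycle + self.hospitalization_cost_per_cycle


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utility weights (QALY weights per year)."""

    u_efs: float = 0.89
    u_pd: float = 0.73
    u_death: float = 0.0

    def __post_init__(self) -> None:
        _require(0.0 <= self.u_death <= self.u_pd <= self.u_efs <= 1.0,
                 "utilities must satisfy 0 <= u_death <= u_pd <= u_efs <= 1")


@dataclass(frozen=True)
class RegimenDosing:
    """Dose schedule of the triplet regimen for a 28-day course.

    Temozolomide and irinotecan dose by body surface area (mg/m² per day for
    a number of days); bevacizumab doses by weight (mg/kg per administration,
    given on days 1 and 15 of each course).
    """

    tmz_dose: float = 50.0
    tmz_days: int = 5
    irt_dose: float = 50.0
    irt_days: int = 5
    bev_dose: float = 10.0
    bev_administrations_per_cycle: int = 2

    def __post_init__(self) -> None:
        for fname in ("tmz_dose", "irt_dose", "bev_dose"):
            _require(getattr(self, fname) >= 0, f"{fname} must be >= 0")
        for fname in ("tmz_days", "irt_days", "bev_administrations_per_cycle"):
            _require(getattr(self, fname) >= 0, f"{fname} must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """A complete, validated parameter set for one model run."""

    settings: EconomicSettings
    tib: ArmParameters
    ti: ArmParameters
    utilities: UtilitySet
    dosing: RegimenDosing = field(default_factory=RegimenDosing)
    patient_weight_kg: float = 40.0
    survival_shape: float = 1.0
    structural_mode: str = "transition"

    def __post_init__(self) -> None:
        _require(self.patient_weight_kg > 0, "patient_weight_kg must be > 0")
        _require(self.survival_shape > 0, "survival_shape must be > 0")
        _require(self.structural_mode in ("transition", "partitioned"),
                 "structural_mode must be 'transition' or 'partitioned'")


# ---------------------------------------------------------------------------
# Serialization


def _build(cls, section: str, data: Mapping[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    _require(not unknown, f"{section}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:  # missing required field
        raise ConfigError(f"{section}: {exc}") from None


def config_from_dict(data: Mapping[str, Any]) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a plain mapping."""
    _require(isinstance(data, Mapping), "configuration root must be a mapping")
    for section in ("arms",):
        _require(section in data, f"missing required section '{section}'")
    arms = data["arms"]
    for key in ("tib", "ti"):
        _require(key in arms, f"arms: missing required arm block '{key}'")
    settings = _build(EconomicSettings, "economic", dict(data.get("economic", {})))
    tib = _build(ArmParameters, "arms.tib", dict(arms["tib"]))
    ti = _build(ArmParameters, "arms.ti", dict(arms["ti"]))
    utilities = _build(UtilitySet, "utilities", dict(data.get("utilities", {})))
    dosing = _build(RegimenDosing, "dosing", dict(data.get("dosing", {})))
    extras = {}
    for key in ("patient_weight_kg", "survival_shape", "structural_mode"):
        if key in data:
            extras[key] = data[key]
    return ModelConfig(settings=settings, tib=tib, ti=ti, utilities=utilities,
                       dosing=dosing, **extras)


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Serialize a config to the same mapping shape ``load_config`` accepts."""

    def arm_dict(arm: ArmParameters) -> dict[str, Any]:
        d = dataclasses.asdict(arm)
        if d.get("drug_components") is not None:
            d["drug_components"] = dict(d["drug_components"])
        else:
            del d["drug_components"]
        return d

    return {
        "economic": dataclasses.asdict(config.settings),
        "arms": {"tib": arm_dict(config.tib), "ti": arm_dict(config.ti)},
        "utilities": dataclasses.asdict(config.utilities),
        "dosing": dataclasses.asdict(config.dosing),
        "patient_weight_kg": config.patient_weight_kg,
        "survival_shape": config.survival_shape,
        "structural_mode": config.structural_mode,
    }


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML or JSON configuration file and validate every invariant.

    Defaults are filled for any optional field absent from the file; a
    missing required field or an invariant violation raises
    :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def default_config_path() -> Path:
    """Path of the bundled base-case parameter fixture."""
    return Path(resources.files("mbcea").joinpath("data/table1.yaml"))


def load_default_config() -> ModelConfig:
    """Load the bundled base-case parameter set."""
    return load_config(default_config_path())


# ---------------------------------------------------------------------------
# Currency and dosing


def cny_to_usd(amount: float, exchange_rate: float = 6.437) -> float:
    """Convert a renminbi amount to USD at ``exchange_rate`` CNY per USD."""
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if exchange_rate <= 0:
        raise ValueError("exchange_rate must be positive")
    return amount / exchange_rate


def body_surface_area(weight_kg: float) -> float:
    """Pediatric body surface area (m²) from weight.

    Uses the linear anthropometric rule BSA = 1.05 + (weight − 30) × 0.02,
    anchored at 1.05 m² for a 30-kg child.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return 1.05 + (weight_kg - 30.0) * 0.02


def doses_per_cycle(dosing: RegimenDosing, weight_kg: float) -> dict[str, float]:
    """Total mg of each agent administered per 28-day course.

    TMZ and IRT scale with body surface area and the number of dosing days;
    bevacizumab scales with body weight and administrations per course.
    """
    bsa = body_surface_area(weight_kg)
    return {
        "tmz_mg": dosing.tmz_dose * bsa * dosing.tmz_days,
        "irt_mg": dosing.irt_dose * bsa * dosing.irt_days,
        "bev_mg": dosing.bev_dose * weight_kg * dosing.bev_administrations_per_cycle,
    }
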