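"""Model configuration: schema, validation, reference inputs, overrides.

Every number the analysis consumes — trial summary statistics used by the
synthetic-trial generator, unit costs, utilities, sensitivity-analysis
ranges and distributions — lives in a single validated configuration object.
A reference configuration reproducing the published French model inputs
ships with the package (``data/reference_config.yaml``).
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .engine import ModelSettings

__all__ = [
    "ArmProfile",
    "DrugSpec",
    "CostInputs",
    "UtilitySet",
    "EventSettings",
    "ExtrapolationSettings",
    "DsaParameter",
    "PsaParameter",
    "PsaSettings",
    "ScenarioSettings",
    "ModelConfig",
    "load_config",
    "save_config",
    "reference_config",
    "apply_overrides",
    "config_hash",
]


class ArmProfile(BaseModel):
    """Trial-level summary statistics characterising one treatment arm."""

    model_config = ConfigDict(extra="forbid")

    name: str
    n_patients: int = Field(ge=2)
    pfs_median_months: float = Field(gt=0)
    os_rate_at_end: float = Field(ge=0, le=1)
    trial_end_months: float = Field(gt=0)
    censor_time_months: float = Field(gt=0)
    bm_baseline: float = Field(ge=0, le=1)
    bm_cumulative: float = Field(ge=0, le=1)
    ae_incidences: dict[str, float] = Field(default_factory=dict)
    duration_mean_months: float = Field(gt=0)
    duration_median_months: float | None = Field(default=None, gt=0)

    @field_validator("ae_incidences")
    @classmethod
    def _ae_in_unit_interval(cls, v):
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"AE incidence {k!r} = {p} outside [0, 1]")
        return v


class DrugSpec(BaseModel):
    """A drug's acquisition cost model: oral (monthly) or IV (per session)."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["oral", "iv"]
    monthly_cost: float | None = Field(default=None, ge=0)
    session_cost: float | None = Field(default=None, ge=0)
    session_interval_days: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _kind_fields(self):
        if self.kind == "oral" and self.monthly_cost is None:
            raise ValueError("oral drug needs monthly_cost")
        if self.kind == "iv" and (self.session_cost is None or self.session_interval_days is None):
            raise ValueError("iv drug needs session_cost and session_interval_days")
        return self


def _mix_sums_to_one(mix: dict[str, float], what: str) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} proportions sum to {total}, expected 1")
    for drug, p in mix.items():
        if p < 0:
            raise ValueError(f"{what}: negative proportion for {drug!r}")


class CostInputs(BaseModel):
    """Unit costs (2017 euros) and treatment-pathway cost structure."""

    model_config = ConfigDict(extra="forbid")

    chemo_admin_per_session: float = Field(ge=0)
    monitoring_first_line: dict[str, float]
    monitoring_second_line: float = Field(ge=0)
    monitoring_third_line: float = Field(ge=0)
    management_weekly_pfs: float = Field(ge=0)
    management_weekly_pps: float = Field(ge=0)
    bm_weekly: float = Field(ge=0)
    transport_round_trip: float = Field(ge=0)
    ae_event_costs: dict[str, float]
    ae_cost_multiplier: dict[str, float]
    ae_reweighting: dict[str, float]
    second_line_duration_weeks: float = Field(gt=0)
    first_line_drug: dict[str, str]
    second_line_mix: dict[str, dict[str, float]]
    third_line_mix: dict[str, dict[str, float]]

    @field_validator("ae_event_costs", "monitoring_first_line")
    @classmethod
    def _non_negative(cls, v):
        for k, c in v.items():
            if c < 0:
                raise ValueError(f"negative cost for {k!r}")
        return v

    @model_validator(mode="after")
    def _mixes(self):
        for arm, mix in self.second_line_mix.items():
            _mix_sums_to_one(mix, f"second-line mix for {arm!r}")
        for arm, mix in self.third_line_mix.items():
            _mix_sums_to_one(mix, f"third-line mix for {arm!r}")
        return self


class UtilitySet(BaseModel):
    """Health-state utilities and per-event adverse-event disutilities."""

    model_config = ConfigDict(extra="forbid")

    pfs: float = Field(ge=0, le=1)
    pps_second_line: float = Field(ge=0, le=1)
    pps_third_line: float = Field(ge=0, le=1)
    ae_disutilities: dict[str, float] = Field(default_factory=dict)
    default_ae_disutility: float = Field(default=-0.061, le=0)
    ae_disutility_duration_weeks: float = Field(default=4.0, gt=0)

    @field_validator("ae_disutilities")
    @classmethod
    def _non_positive(cls, v):
        for k, d in v.items():
            if d > 0:
                raise ValueError(f"disutility for {k!r} must be <= 0, got {d}")
        return v

    def disutility(self, ae: str) -> float:
        return self.ae_disutilities.get(ae, self.default_ae_disutility)


class EventSettings(BaseModel):
    """Intercurrent-event settings shared across arms."""

    model_config = ConfigDict(extra="forbid")

    bm_baseline: float = Field(0.25, ge=0, le=1)


class ExtrapolationSettings(BaseModel):
    """Which parametric family continues each endpoint beyond the trial."""

    model_config = ConfigDict(extra="forbid")

    cutover_weeks: int = Field(78, ge=0)
    pfs_family: str = "exponential"
    duration_family: str = "exponential"
    os_family: str = "gamma"
    os_reference_arm: str = "crizotinib"
    bm_tail_family: str = "exponential"
    candidate_families: list[str] = Field(
        default_factory=lambda: [
            "exponential",
            "weibull",
            "gamma",
            "log-normal",
            "log-logistic",
            "gompertz",
        ]
    )


class DsaParameter(BaseModel):
    """One row of the one-way (tornado) sensitivity analysis."""

    model_config = ConfigDict(extra="forbid")

    name: str
    path: str
    base: float
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: require low <= base <= high")
        return self


class PsaParameter(BaseModel):
    """One independently sampled scalar in the probabilistic analysis."""

    model_config = ConfigDict(extra="forbid")

    name: str
    path: str
    distribution: Literal["gamma", "log-normal"]
    mean: float = Field(gt=0)
    sd: float = Field(gt=0)


class PsaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    iterations: int = Field(1000, ge=1)
    parameters: list[PsaParameter] = Field(default_factory=list)
    include_survival: bool = True
    wtp_grid_max: float = Field(300_000.0, gt=0)
    wtp_grid_step: float = Field(5_000.0, gt=0)


class ScenarioSettings(BaseModel):
    """Alternative treatment-pathway definition (second-line mixes per arm)."""

    model_config = ConfigDict(extra="forbid")

    name: str = "real-world pathway"
    second_line_mix: dict[str, dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _mixes(self):
        for arm, mix in self.second_line_mix.items():
            _mix_sums_to_one(mix, f"scenario second-line mix for {arm!r}")
        return self


class ModelConfig(BaseModel):
    """Complete, validated model configuration."""

    model_config = ConfigDict(extra="forbid")

    settings: ModelSettings = Field(default_factory=ModelSettings)
    intervention: str = "alectinib"
    comparator: str = "crizotinib"
    arms: dict[str, ArmProfile]
    drugs: dict[str, DrugSpec]
    costs: CostInputs
    utilities: UtilitySet
    events: EventSettings = Field(default_factory=EventSettings)
    extrapolation: ExtrapolationSettings = Field(default_factory=ExtrapolationSettings)
    dsa: list[DsaParameter] = Field(default_factory=list)
    psa: PsaSettings = Field(default_factory=PsaSettings)
    scenario: ScenarioSettings = Field(default_factory=ScenarioSettings)
    seeds: dict[str, int] = Field(default_factory=lambda: {"trial": 12345, "psa": 67890})

    @model_validator(mode="after")
    def _consistent(self):
        for arm in (self.intervention, self.comparator):
            if arm not in self.arms:
                raise ValueError(f"arm {arm!r} missing from arms")
        for arm in self.arms:
            if arm not in self.costs.first_line_drug:
                raise ValueError(f"no first-line drug configured for arm {arm!r}")
        for arm, drug in self.costs.first_line_drug.items():
            if drug not in self.drugs:
                raise ValueError(f"unknown first-line drug {drug!r} for arm {arm!r}")
        for mixes in (self.costs.second_line_mix, self.costs.third_line_mix):
            for arm, mix in mixes.items():
                for drug in mix:
                    if drug not in self.drugs:
                        raise ValueError(f"unknown drug {drug!r} in mix for arm {arm!r}")
        if self.extrapolation.os_reference_arm not in self.arms:
            raise ValueError("os_reference_arm is not a configured arm")
        return self


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return ModelConfig.model_validate(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def reference_config() -> ModelConfig:
    """The shipped configuration holding the published model inputs."""
    text = resources.files("psmcea").joinpath("data/reference_config.yaml").read_text()
    return ModelConfig.model_validate(yaml.safe_load(text))


def _set_path(tree: dict, path: str, value) -> None:
    keys = path.split(".")
    node = tree
    for k in keys[:-1]:
        if not isinstance(node, dict) or k not in node:
            raise KeyError(f"parameter path {path!r} not found at {k!r}")
        node = node[k]
    if not isinstance(node, dict) or keys[-1] not in node:
        raise KeyError(f"parameter path {path!r} not found at {keys[-1]!r}")
    node[keys[-1]] = value


def apply_overrides(config: ModelConfig, overrides: dict[str, object] | None) -> ModelConfig:
    """Return a new validated config with dotted-path overrides applied.

    The input config is never mutated.
    """
    if not overrides:
        return config
    tree = copy.deepcopy(config.model_dump(mode="python"))
    for path, value in overrides.items():
        _set_path(tree, path, value)
    return ModelConfig.model_validate(tree)


def config_hash(config: ModelConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
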