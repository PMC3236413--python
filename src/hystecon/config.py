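"""Run configuration: parsing, validation and parameter resolution.

A run is configured by one YAML (or JSON) document with blocks ``cohort``
(synthetic generator), ``cost`` (fee schedule or its calibration inputs,
wages, nonoperative charges), ``model`` (point parameters or cohort
estimation with overrides), ``sensitivity`` and ``psa``.  The shipped
``paper_defaults.yaml`` reproduces the study's published parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cohort import CohortGeneratorConfig
from .costs import (
    CalibrationResult,
    FeeSchedule,
    WageParameters,
    calibrate_fee_schedule,
)
from .errors import ConfigurationError
from .methods import METHOD_ORDER, SurgicalMethod
from .psa import PSAConfig
from .tree import MethodParameters, ModelParameters

DEFAULT_CONFIG_RESOURCE = "paper_defaults.yaml"


class CalibrationInputs(BaseModel):
    """Per-method mean OR times and mean operative charges to fit the fee
    schedule against, plus the equipment policy."""

    model_config = ConfigDict(frozen=True)

    or_time_means: dict[SurgicalMethod, float]
    operative_charge_means: dict[SurgicalMethod, float]
    time_to_equipment_ratio: float = Field(default=190.0, gt=0)
    increment_length: float = Field(default=15.0, gt=0)

    def run(self) -> CalibrationResult:
        return calibrate_fee_schedule(
            self.or_time_means,
            self.operative_charge_means,
            increment_length=self.increment_length,
            time_to_equipment_ratio=self.time_to_equipment_ratio,
        )


class CostConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    fee_schedule: Optional[FeeSchedule] = None
    calibration: Optional[CalibrationInputs] = None
    wages: WageParameters = Field(default_factory=WageParameters)
    nonoperative_charges: dict[SurgicalMethod, float]
    cost_to_charge_ratio: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "CostConfig":
        if self.fee_schedule is None and self.calibration is None:
            raise ValueError("either an explicit fee_schedule or calibration inputs required")
        for m in METHOD_ORDER:
            if m not in self.nonoperative_charges:
                raise ValueError(f"missing nonoperative charge for {m.value}")
            if self.nonoperative_charges[m] < 0:
                raise ValueError(f"nonoperative charge for {m.value} must be >= 0")
        if self.cost_to_charge_ratio is not None and not (
            0.5 <= self.cost_to_charge_ratio <= 0.7
        ):
            raise ValueError("cost_to_charge_ratio must lie in [0.5, 0.7]")
        return self

    def resolve_fee_schedule(self) -> tuple[FeeSchedule, Optional[CalibrationResult]]:
        if self.fee_schedule is not None:
            return self.fee_schedule, None
        result = self.calibration.run()
        return result.schedule, result


class MethodPointParameters(BaseModel):
    """Point estimates for one method when ``model.source == "config"``."""

    model_config = ConfigDict(frozen=True)

    p_lnd: float = Field(ge=0, le=1)
    p_conversion: float = Field(default=0.0, ge=0, le=1)
    p_hemorrhage: float = Field(ge=0, le=1)
    or_time_mean: float = Field(gt=0)
    or_time_sd: float = Field(default=0.0, ge=0)
    n: Optional[int] = Field(default=None, ge=1)


class ModelConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    source: Literal["cohort", "config"] = "cohort"
    parameters: Optional[dict[SurgicalMethod, MethodPointParameters]] = None
    overrides: dict[SurgicalMethod, dict[str, float]] = Field(default_factory=dict)
    literature_required: list[tuple[SurgicalMethod, str]] = Field(
        default_factory=lambda: [(SurgicalMethod.TRH, "p_conversion")]
    )
    added_times: dict[str, float] = Field(
        default_factory=lambda: {"lnd": 30.0, "conversion": 60.0, "hemorrhage": 30.0}
    )

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.source == "config":
            if self.parameters is None:
                raise ValueError("model.source == 'config' requires model.parameters")
            for m in METHOD_ORDER:
                if m not in self.parameters:
                    raise ValueError(f"missing model parameters for {m.value}")
            if self.parameters[SurgicalMethod.TAH].p_conversion != 0.0:
                raise ValueError("TAH p_conversion must be 0")
        for k in self.added_times:
            if k not in {"lnd", "conversion", "hemorrhage"}:
                raise ValueError(f"unknown added-time key '{k}'")
            if self.added_times[k] < 0:
                raise ValueError(f"added time '{k}' must be >= 0")
        return self


class SensitivityConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    step: float = Field(default=1.0, gt=0)
    threshold_range: tuple[float, float] = (15.0, 900.0)
    sweep_percentiles: tuple[float, float] = (25.0, 75.0)
    threshold_pairs: list[tuple[SurgicalMethod, SurgicalMethod]] = Field(
        default_factory=lambda: [(SurgicalMethod.TRH, SurgicalMethod.TAH)]
    )

    @model_validator(mode="after")
    def _check(self) -> "SensitivityConfig":
        lo, hi = self.threshold_range
        if not (0 < lo < hi):
            raise ValueError(f"threshold_range out of order: [{lo}, {hi}]")
        return self


class RunConfig(BaseModel):
    """Top-level configuration of an end-to-end run."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    cohort: CohortGeneratorConfig
    cost: CostConfig
    model: ModelConfig = Field(default_factory=ModelConfig)
    sensitivity: SensitivityConfig = Field(default_factory=SensitivityConfig)
    psa: PSAConfig = Field(default_factory=PSAConfig)

    def model_parameters_from_config(self) -> ModelParameters:
        """Build decision-model parameters from the ``model.parameters`` block
        (bypassing cohort estimation)."""
        if self.model.parameters is None:
            raise ConfigurationError("config carries no model.parameters block")
        schedule, _ = self.cost.resolve_fee_schedule()
        added = self.model.added_times
        methods = {}
        for m in METHOD_ORDER:
            pp = self.model.parameters[m]
            ov = self.model.overrides.get(m, {})
            methods[m] = MethodParameters(
                p_lnd=ov.get("p_lnd", pp.p_lnd),
                p_conversion=ov.get("p_conversion", pp.p_conversion),
                p_hemorrhage=ov.get("p_hemorrhage", pp.p_hemorrhage),
                base_or_time=pp.or_time_mean,
                or_time_sd=pp.or_time_sd,
                added_time_lnd=added["lnd"],
                added_time_conversion=added["conversion"],
                added_time_hemorrhage=added["hemorrhage"],
                nonoperative_encounter_charge=self.cost.nonoperative_charges[m],
                n=pp.n,
                provenance={k: "override" for k in ov} | {"base": "config"},
            )
        return ModelParameters(
            methods=methods,
            fee_schedule=schedule,
            wages=self.cost.wages,
            cost_to_charge_ratio=self.cost.cost_to_charge_ratio,
        )


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    errors: tuple[tuple[str, str], ...]  # (dotted config path, message)

    def __str__(self) -> str:
        if self.valid:
            return "configuration valid"
        lines = [f"{path}: {msg}" for path, msg in self.errors]
        return "invalid configuration:\n  " + "\n  ".join(lines)


def _load_document(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    try:
        return RunConfig.model_validate(_load_document(path))
    except ValidationError as exc:
        report = _report_from_error(exc)
        raise ConfigurationError(str(report)) from exc


def load_default_config() -> RunConfig:
    """The shipped configuration carrying the published study parameters."""
    text = resources.files("hystecon.data").joinpath(DEFAULT_CONFIG_RESOURCE).read_text()
    return RunConfig.model_validate(yaml.safe_load(text))


def _report_from_error(exc: ValidationError) -> ValidationReport:
    errors = tuple(
        (".".join(str(part) for part in err["loc"]), err["msg"]) for err in exc.errors()
    )
    return ValidationReport(valid=False, errors=errors)


def validate_config(path) -> ValidationReport:
    """Validate a config file; list every violated invariant with its path."""
    try:
        document = _load_document(path)
    except (OSError, yaml.YAMLError, json.JSONDecodeError) as exc:
        return ValidationReport(valid=False, errors=((str(path), str(exc)),))
    try:
        RunConfig.model_validate(document)
    except ValidationError as exc:
        return _report_from_error(exc)
    return ValidationReport(valid=True, errors=())
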