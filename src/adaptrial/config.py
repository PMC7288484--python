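"""YAML run-configuration schema and validation.

A run configuration couples one design (time-to-event or binary endpoint)
with a list of true-effect scenarios, a replication count and a master
seed.  Validation is schema-based (pydantic, unknown keys rejected) and
every violation in a file is reported at once.  Defaults match the
package's reference case studies: a 200-event log-HR trial with a 100-event
interim and 0.9/0.5 bars, and a 1334-patient binary trial with 0.99/0.10
predictive stopping bars and a 0.98 final bar under 44%/35% rates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .binary import BinaryDesign, Scenario, build_even_schedule
from .posteriors import NormalPosterior
from .tte import HazardScenario, TTEDesign

__all__ = [
    "ConfigError",
    "TTEDesignConfig",
    "BinaryDesignConfig",
    "ScenarioConfig",
    "RunConfig",
    "parse_config",
]

Probability = Annotated[float, Field(gt=0.0, lt=1.0)]
# stopping bars admit the closed endpoints as degenerate never-firing rules
StoppingBar = Annotated[float, Field(ge=0.0, le=1.0)]


class ConfigError(ValueError):
    """Aggregated configuration-validation failure."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TTEDesignConfig(_StrictModel):
    endpoint: Literal["tte"] = "tte"
    total_events: int = Field(200, gt=0)
    interim_events: Optional[int] = Field(100, gt=0)
    interim_rule: Literal["none", "futility", "efficacy"] = "none"
    interim_threshold: Optional[Probability] = None
    final_success_threshold: Probability = 0.9
    prior_mean: float = 0.0
    prior_variance: float = Field(10_000.0, gt=0)
    look_dependence: Literal["independent", "correlated-increments"] = "independent"
    variance_factor: float = Field(4.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "TTEDesignConfig":
        if self.interim_events is not None and self.interim_events >= self.total_events:
            raise ValueError("interim_events must be smaller than total_events")
        return self

    def build(self) -> TTEDesign:
        return TTEDesign(
            total_events=self.total_events,
            interim_events=self.interim_events,
            interim_rule=self.interim_rule,
            interim_threshold=self.interim_threshold,
            final_success_threshold=self.final_success_threshold,
            prior=NormalPosterior(self.prior_mean, self.prior_variance),
            look_dependence=self.look_dependence,
            variance_factor=self.variance_factor,
        )


class BinaryDesignConfig(_StrictModel):
    endpoint: Literal["binary"] = "binary"
    n_max: int = Field(1334, gt=0)
    n_interims: Optional[int] = Field(None, ge=0)
    schedule: Optional[list[int]] = None
    efficacy_threshold: Optional[StoppingBar] = 0.99
    futility_threshold: Optional[StoppingBar] = 0.10
    final_success_threshold: Probability = 0.98
    prior_alpha: float = Field(1.0, gt=0)
    prior_beta: float = Field(1.0, gt=0)
    followup_days: float = Field(28.0, ge=0)
    accrual_rate: float = Field(2.0, gt=0)
    n_imputations: int = Field(500, ge=1)
    dropout_rate: float = Field(0.0, ge=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "BinaryDesignConfig":
        if self.schedule is not None and self.n_interims is not None:
            raise ValueError("give either n_interims or an explicit schedule, not both")
        if self.schedule is not None:
            if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])):
                raise ValueError("schedule must be strictly increasing")
            if self.schedule and (self.schedule[0] < 1 or self.schedule[-1] >= self.n_max):
                raise ValueError("schedule entries must lie in [1, n_max)")
        return self

    def build(self) -> BinaryDesign:
        if self.schedule is not None:
            schedule = tuple(self.schedule)
        elif self.n_interims:
            schedule = tuple(build_even_schedule(self.n_max, self.n_interims))
        else:
            schedule = ()
        return BinaryDesign(
            n_max=self.n_max,
            schedule=schedule,
            efficacy_threshold=self.efficacy_threshold,
            futility_threshold=self.futility_threshold,
            final_success_threshold=self.final_success_threshold,
            prior_alpha=self.prior_alpha,
            prior_beta=self.prior_beta,
            followup_days=self.followup_days,
            accrual_rate=self.accrual_rate,
            n_imputations=self.n_imputations,
            dropout_rate=self.dropout_rate,
        )


class ScenarioConfig(_StrictModel):
    label: str = ""
    hr: Optional[float] = Field(None, gt=0)
    control_rate: Optional[Probability] = None
    intervention_rate: Optional[Probability] = None

    def build(self, endpoint: str):
        if endpoint == "tte":
            if self.hr is None:
                raise ConfigError("a tte scenario needs an 'hr'")
            return HazardScenario(self.hr, self.label)
        if self.control_rate is None or self.intervention_rate is None:
            raise ConfigError("a binary scenario needs control_rate and intervention_rate")
        return Scenario(self.control_rate, self.intervention_rate, self.label)


class RunConfig(_StrictModel):
    """Fully validated description of one simulation run."""

    design: Union[TTEDesignConfig, BinaryDesignConfig] = Field(discriminator="endpoint")
    scenarios: list[ScenarioConfig] = Field(min_length=1)
    n_sims: int = Field(10_000, ge=1)
    seed: int = Field(0, ge=0)
    output: Optional[str] = None
    common_random_numbers: bool = True

    @model_validator(mode="after")
    def _scenarios_match_endpoint(self) -> "RunConfig":
        endpoint = self.design.endpoint
        for sc in self.scenarios:
            if endpoint == "tte" and sc.hr is None:
                raise ValueError(f"scenario {sc.label!r}: tte runs need 'hr'")
            if endpoint == "binary" and (
                sc.control_rate is None or sc.intervention_rate is None
            ):
                raise ValueError(
                    f"scenario {sc.label!r}: binary runs need control_rate and intervention_rate"
                )
        return self

    def built_design(self):
        return self.design.build()

    def built_scenarios(self):
        return [sc.build(self.design.endpoint) for sc in self.scenarios]

    def to_dict(self) -> dict:
        # None is meaningful (a disabled stopping rule), so nothing is elided
        return self.model_dump()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Raises :class:`ConfigError` listing *all* schema violations found, or
    ``FileNotFoundError`` if the path does not exist.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{path}: {exc.error_count()} configuration error(s):"]
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"  - {loc}: {err['msg']}")
        raise ConfigError("\n".join(lines)) from exc
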