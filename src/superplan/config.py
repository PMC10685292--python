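"""Run configuration: schema, validation, and (de)serialization.

A single YAML/JSON file describes an entire reproducible run: where the
problem comes from (generated phantom/toy or a problem directory), the
per-VOI prescription table, the objective list, the solver block, the output
directory and the seed.  Unknown keys are rejected and every field is
range-checked before any computation starts.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .objectives import canonical_kind

__all__ = ["PlanSpecConfig", "ConfigError", "parse_and_validate"]


class ConfigError(ValueError):
    """Configuration file failed validation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSource(_Model):
    type: Literal["phantom"] = "phantom"
    nx: int = Field(64, ge=1)
    ny: int = Field(64, ge=1)
    nz: int = Field(1, ge=1)
    spacing_mm: float = Field(2.5, gt=0)
    witness_bounds: bool = True  # widen bounds to cover the witness fluence


class ToySource(_Model):
    type: Literal["toy"] = "toy"
    n: int = Field(200, ge=1)
    m: int = Field(30, ge=1)
    density: float = Field(0.1, gt=0, le=1)
    feasible: bool = True
    slack: float = Field(0.5, gt=0)


class LoadSource(_Model):
    type: Literal["load"] = "load"
    path: str


class PrescriptionRow(_Model):
    voi: str
    lower: float = Field(0.0, ge=0)
    upper: float = math.inf
    weight: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.lower > self.upper:
            raise ValueError(
                f"VOI {self.voi!r}: lower bound {self.lower} exceeds upper {self.upper}")
        return self


class ObjectiveRow(_Model):
    voi: str
    kind: str
    weight: float = Field(1.0, ge=0)
    d_ref: float | None = Field(None, ge=0)
    volume: float | None = Field(None, gt=0, lt=1)

    @model_validator(mode="after")
    def _kind_ok(self):
        k = canonical_kind(self.kind)
        if k != "mean_dose" and self.d_ref is None:
            raise ValueError(f"objective {self.kind!r} on {self.voi!r} needs d_ref")
        if k in ("max_dvh", "min_dvh") and self.volume is None:
            raise ValueError(f"objective {self.kind!r} on {self.voi!r} needs volume")
        object.__setattr__(self, "kind", k)
        return self


class SolverBlock(_Model):
    mode: Literal["feasibility", "superiorize"] = "superiorize"
    alpha: float = Field(0.99, gt=0, lt=1)
    n_perturbations: int = Field(5, ge=0)
    lam: float = Field(1.0, gt=0, le=2)
    eta: float = Field(1.0, gt=0, le=1)
    warm_start_increment: int = Field(25, ge=1)
    max_iterations: int = Field(500, ge=1)
    max_time: float = Field(3000.0, gt=0)
    tol_f: float = 1e-4
    tol_V: float = 1e-3
    consecutive: int = Field(3, ge=1)
    control: Literal["cyclic", "random", "weight_ascending",
                     "weight_descending"] = "cyclic"


class PlanSpecConfig(_Model):
    problem: Union[PhantomSource, ToySource, LoadSource] = \
        Field(default_factory=PhantomSource, discriminator="type")
    prescription: list[PrescriptionRow] = Field(default_factory=list)
    objectives: list[ObjectiveRow] = Field(default_factory=list)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    output_dir: str = "plan_output"
    seed: int = 0

    @model_validator(mode="after")
    def _cross_checks(self):
        vois = {p.voi for p in self.prescription}
        if len(vois) != len(self.prescription):
            raise ValueError("duplicate VOI in prescription table")
        for obj in self.objectives:
            if self.prescription and obj.voi not in vois:
                raise ValueError(
                    f"objective references VOI {obj.voi!r} absent from the prescription")
        if self.solver.mode == "superiorize" and not self.objectives \
                and self.solver.n_perturbations > 0:
            # legal (reduces to bare feasibility) but worth flagging loudly
            pass
        return self

    def echo(self, path) -> None:
        """Write the fully resolved config next to the run artifacts."""
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)


def parse_and_validate(path) -> PlanSpecConfig:
    """Load and schema-validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return PlanSpecConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}:\n{exc}") from exc
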