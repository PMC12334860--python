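"""Planning configuration: a versioned, fail-fast schema.

Configs live in YAML; unknown keys are rejected.  Exactly one objective must
target the PTV — it anchors the prescription scaling of the initial weights.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .lens import LensSpec, builtin_lens
from .optimize import ConstraintSpec, ObjectiveSpec

__all__ = ["PlanningConfig", "SamplingConfig", "OptimizerConfig", "load_config"]

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SamplingConfig(_Strict):
    spacing_factor: float = Field(default=1.2, ge=1.0)
    n_candidates: int = Field(default=256, ge=8)
    n_segments: int = Field(default=8, ge=1)
    seed: int = 0
    max_depth_mm: float | None = Field(default=None, gt=0.0)


class OptimizerConfig(_Strict):
    max_iter: int = Field(default=500, ge=0)
    tol: float = Field(default=1e-6, gt=0.0)


class ObjectiveConfig(_Strict):
    structure: str
    kind: str
    dose_gy: float = Field(gt=0.0)
    penalty: float = Field(ge=0.0)

    def to_spec(self) -> ObjectiveSpec:
        return ObjectiveSpec(self.structure, self.kind, self.dose_gy, self.penalty)


class ConstraintConfig(_Strict):
    structure: str
    kind: str
    lower_gy: float = float("-inf")
    upper_gy: float = float("inf")

    def to_spec(self) -> ConstraintSpec:
        return ConstraintSpec(self.structure, self.kind, self.lower_gy, self.upper_gy)


class PlanningConfig(_Strict):
    """Full planning problem description."""

    version: int = SCHEMA_VERSION
    lens: str | dict = "B"
    prescription_gy: float = Field(gt=0.0)
    fractions: int = Field(default=1, ge=1)
    sampling: SamplingConfig = SamplingConfig()
    objectives: list[ObjectiveConfig]
    constraints: list[ConstraintConfig] = []
    optimizer: OptimizerConfig = OptimizerConfig()

    @field_validator("version")
    @classmethod
    def _known_version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {v}")
        return v

    @model_validator(mode="after")
    def _one_ptv_objective(self) -> "PlanningConfig":
        n_ptv = sum(1 for o in self.objectives if o.structure == "PTV")
        if n_ptv < 1:
            raise ValueError("exactly one objective must target 'PTV' (found none)")
        dose_set = {o.dose_gy for o in self.objectives if o.structure == "PTV"}
        if len(dose_set) > 1:
            raise ValueError("PTV objectives must share one prescribed dose")
        return self

    def lens_spec(self) -> LensSpec:
        spec = builtin_lens(self.lens) if isinstance(self.lens, str) else LensSpec(**self.lens)
        if self.sampling.max_depth_mm is not None:
            spec = LensSpec(**{**spec.to_dict(), "max_depth": self.sampling.max_depth_mm})
        return spec

    def objective_specs(self) -> list[ObjectiveSpec]:
        return [o.to_spec() for o in self.objectives]

    def constraint_specs(self) -> list[ConstraintSpec]:
        return [c.to_spec() for c in self.constraints]

    @classmethod
    def default(cls, prescription_gy: float, lens: str = "B", **overrides) -> "PlanningConfig":
        """The package's default planning problem for a given prescription.

        Squared under- and over-dose objectives on the PTV at the
        prescription, plus a squared-overdose objective at half prescription
        on the auto-derived NORMAL (= BODY minus PTV) structure for
        conformity.
        """
        objectives = [
            ObjectiveConfig(
                structure="PTV", kind="squared_underdose",
                dose_gy=prescription_gy, penalty=1000.0,
            ),
            ObjectiveConfig(
                structure="PTV", kind="squared_overdose",
                dose_gy=prescription_gy, penalty=1000.0,
            ),
            ObjectiveConfig(
                structure="NORMAL", kind="squared_overdose",
                dose_gy=0.5 * prescription_gy, penalty=100.0,
            ),
        ]
        return cls(
            prescription_gy=prescription_gy, lens=lens, objectives=objectives, **overrides
        )


def load_config(path: str | Path) -> PlanningConfig:
    """Load and validate a YAML planning config (unknown keys rejected)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return PlanningConfig.model_validate(data)
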