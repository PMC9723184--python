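"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LandscapeSection(_Strict):
    n_rows: int = 75
    n_cols: int = 75
    cell_size: float = 1.0
    n_predictors_per_group: int = 6
    spatial_autocorrelation_range: float = 6.0


class LearnerSection(_Strict):
    names: list[str] = Field(
        default_factory=lambda: [
            "MAXENT", "GLM", "MARS", "GAM", "RF", "GBM", "CTA", "ANN", "FDA", "SRE",
        ]
    )
    hyperparameters: dict[str, dict] = Field(default_factory=dict)


class GateSection(_Strict):
    threshold: float = 0.75
    on_no_qualifier: str = "best"  # best | skip | error


class ClassSection(_Strict):
    cutpoints: tuple[float, float, float] = (0.25, 0.50, 0.75)


class OverlapSection(_Strict):
    n_perm: int = 99
    surrogate: str = "SRE"
    significance: bool = True
    alpha: float = 0.05


class PrioritizationSection(_Strict):
    cover_max: float = 80.0
    hdr_max: float = 75.0
    accretion_max: float = 75.0
    degradation_min: float = 75.0
    rule: str = "default"


class PipelineConfig(_Strict):
    """Top-level configuration for the end-to-end synthetic pipeline."""

    landscape: LandscapeSection = Field(default_factory=LandscapeSection)
    learners: LearnerSection = Field(default_factory=LearnerSection)
    gates: GateSection = Field(default_factory=GateSection)
    classes: ClassSection = Field(default_factory=ClassSection)
    overlap: OverlapSection = Field(default_factory=OverlapSection)
    prioritization: PrioritizationSection = Field(default_factory=PrioritizationSection)
    seed: int = 0
    output_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
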