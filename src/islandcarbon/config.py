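"""Validated pipeline configuration (YAML-backed, strict keys)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GroundFilterConfig(_Strict):
    kernel_size: float = 10.0
    vertical_tolerance: float = 1.5
    dsm_resolution: float = 1.12
    tch_cell: float = 30.0
    min_valid_fraction: float = 0.5
    plane: str = "fitted"


class ForestConfig(_Strict):
    n_trees: int = 250
    holdout_size: int = 250
    max_features: str | int = "third"
    min_samples_leaf: int = 5
    max_depth: int | None = None


class CalibrationConfig(_Strict):
    a: float = 3.744
    b: float = 1.391


class UncertaintyConfig(_Strict):
    n_bins: int = 30
    degree: int = 2
    binning: str = "width"


class MaskConfig(_Strict):
    rule: str = "veg_classes"
    classes: list[int] = [1, 2, 3, 4]
    tch_threshold: float = 2.0


class SeedsConfig(_Strict):
    """Every stochastic stage draws from an explicit named seed."""

    train: int
    importance: int
    simulate: int | None = None


class PipelineConfig(_Strict):
    """End-to-end run description: inputs, parameters, seeds, outputs."""

    point_cloud: str
    stack_dir: str
    out_dir: str
    inventory_trees: str | None = None
    inventory_plots: str | None = None
    zones: str | None = None
    tenure: str | None = None
    ground: GroundFilterConfig = GroundFilterConfig()
    forest: ForestConfig = ForestConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    carbon_fraction: float = 0.48
    uncertainty: UncertaintyConfig = UncertaintyConfig()
    mask: MaskConfig = MaskConfig()
    seeds: SeedsConfig

    @field_validator("carbon_fraction")
    @classmethod
    def _frac(cls, v):
        if not 0 < v < 1:
            raise ValueError("carbon_fraction must be in (0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
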