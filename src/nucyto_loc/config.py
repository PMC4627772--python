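"""Run configuration schema (validated before any computation).

A single YAML/JSON document configures both pipelines; CLI flags override
file values.  Every run writes the resolved config next to its results
together with the package version and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class SegmentationConfig(BaseModel):
    min_area_px: int = Field(20, ge=1)
    max_displacement_px: float = Field(10.0, gt=0)
    background_dilation_px: int = Field(3, ge=0)


class ConditionConfig(BaseModel):
    """One synthetic condition: kinetics + cell count."""

    label: str
    reporter_group: str = "reporter"
    n_cells: int = Field(4, ge=1)
    k_in_base: float = Field(0.05, ge=0)
    k_in_stim: float = Field(0.05, ge=0)
    k_out: float = Field(0.1, ge=0)
    t_stim_s: float = 600.0
    n_frames: int = Field(12, ge=2)
    frame_interval_s: float = Field(120.0, gt=0)


class SceneConfig(BaseModel):
    gain: float = Field(100.0, gt=0)
    background: float = Field(10.0, ge=0)
    poisson_scale: float = Field(0.0, ge=0)
    gaussian_sd: float = Field(0.0, ge=0)
    blur_sigma: float = Field(0.0, ge=0)
    pixel_size_um: float = Field(0.5, gt=0)
    cell_radius_px: float = Field(16.0, gt=0)
    nucleus_radius_px: float = Field(9.0, gt=0)

    @model_validator(mode="after")
    def _nucleus_inside(self):
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ValueError("nucleus_radius_px must be < cell_radius_px")
        return self


class TranslocationRunConfig(BaseModel):
    conditions: list[ConditionConfig]
    baseline_label: str
    reference_group: str | None = None
    scene: SceneConfig = SceneConfig()
    segmentation: SegmentationConfig = SegmentationConfig()

    @model_validator(mode="after")
    def _baseline_everywhere(self):
        if not self.conditions:
            raise ValueError("at least one condition is required")
        by_group: dict[str, set[str]] = {}
        for c in self.conditions:
            by_group.setdefault(c.reporter_group, set()).add(c.label)
        for grp, labels in by_group.items():
            if self.baseline_label not in labels:
                raise ValueError(
                    f"baseline label {self.baseline_label!r} missing from "
                    f"reporter group {grp!r}"
                )
        return self


class FRAPGroupConfig(BaseModel):
    label: str
    n_records: int = Field(5, ge=1)
    mobile_fraction: float = Field(..., ge=0, le=1)
    k_true: float = Field(..., gt=0)
    bleach_depth: float = Field(1.0, ge=0, le=1)
    pre_s: float = Field(1.0, gt=0)
    bleach_s: float = Field(0.15, gt=0)
    post_s: float = Field(3.0, gt=0)
    line_rate_hz: float = Field(1000.0, gt=0)
    line_len_px: int = Field(256, ge=16)
    acq_bleach_rate: float = Field(0.0, ge=0)
    noise_sd: float = Field(0.0, ge=0)


class FRAPRunConfig(BaseModel):
    groups: list[FRAPGroupConfig]

    @field_validator("groups")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("at least one FRAP group is required")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    outdir: str = "results"
    translocation: TranslocationRunConfig | None = None
    frap: FRAPRunConfig | None = None


class ConfigError(ValueError):
    """Raised for schema violations, before any computation."""


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    return parse_config(raw or {})


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(str(exc)) from exc


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
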