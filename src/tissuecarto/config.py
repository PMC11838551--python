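"""Project configuration for pipeline runs.

A validated schema (unknown keys rejected) describing one cartography
project: voxel spacing, channels, unwrap method, projection grid and
layer offsets, alignment method for sequences, and input/output path
templates with a ``{frame}`` placeholder.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    channel: int = 0
    threshold: float = 0.5
    closing_radius: int = 0
    smooth_sigma: float = 0.0
    levelset_iterations: int = 0


class MeshingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    level: float = 0.5
    smooth_sigma: float = 1.0
    taubin_iterations: int = 0


class UnwrapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["axis", "spherical", "cylindrical", "harmonic", "reuse"] = (
        "spherical"
    )
    axis: list[float] = Field(default_factory=lambda: [0.0, 0.0, 1.0])
    center: list[float] | None = None
    meridian_axis: list[float] = Field(default_factory=lambda: [1.0, 0.0, 0.0])
    axis_point: list[float] | None = None


class AlignmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["rigid", "shrinkwrap", "moebius"] = "shrinkwrap"
    iterations: int = 10
    smooth_per_iter: int = 2
    rotation_grid: int = 128
    allow_scale: bool = True


class ProjectConfig(BaseModel):
    """Schema-validated pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    spacing: list[float]
    channels: list[int] | None = None
    grid_shape: list[int] = Field(default_factory=lambda: [256, 256])
    offsets: list[float] = Field(default_factory=lambda: [0.0])
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    meshing: MeshingConfig = Field(default_factory=MeshingConfig)
    unwrap: UnwrapConfig = Field(default_factory=UnwrapConfig)
    alignment: AlignmentConfig = Field(default_factory=AlignmentConfig)
    image_template: str = "frame_{frame:04d}.tif"
    mesh_template: str = "frame_{frame:04d}.obj"
    output_dir: str = "output"
    project_root: str = "."
    frames: list[int] = Field(default_factory=lambda: [0])
    reference_frame: int | None = None
    seed: int = 0

    @field_validator("spacing")
    @classmethod
    def _spacing_positive(cls, v: list[float]) -> list[float]:
        if len(v) != 3 or any(s <= 0 for s in v):
            raise ValueError("spacing must be 3 positive numbers (dz, dy, dx)")
        return v

    @field_validator("grid_shape")
    @classmethod
    def _grid_ok(cls, v: list[int]) -> list[int]:
        if len(v) != 2 or any(s < 1 for s in v):
            raise ValueError("grid_shape must be two positive integers")
        return v

    @model_validator(mode="after")
    def _reference_in_range(self) -> "ProjectConfig":
        if self.reference_frame is not None and self.reference_frame not in self.frames:
            raise ValueError(
                f"reference_frame {self.reference_frame} not in frames {self.frames}"
            )
        return self


def load_config(path: str | Path) -> ProjectConfig:
    """Load and validate a YAML project configuration."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return ProjectConfig(**data)
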