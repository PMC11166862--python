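"""Validated run configuration (YAML/JSON).

A :class:`RunConfig` collects everything a command-line run needs: the
noise ROI, the ray-casting setup, the fixed model constants, an optional
phantom description for simulation, and the seed. Validation is strict —
unknown keys are rejected so a typo in a config file fails loudly instead
of silently using a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .sde_model import LAMBDA_DEFAULT

__all__ = ["RoiConfig", "RadialSection", "ModelConstants", "PhantomSection", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RoiConfig(_Strict):
    """Square noise ROI; center defaults to the image center."""

    center: Optional[tuple[float, float]] = None
    side: int = Field(40, ge=1)


class RadialSection(_Strict):
    n_angles: int = Field(360, ge=1)
    ray_length: int = Field(50, ge=2)
    interpolation: Literal["bilinear", "nearest"] = "bilinear"


class ModelConstants(_Strict):
    """Fixed constants of the edge model (profile length T, lambda, dt)."""

    t_total: float = Field(50.0, ge=2)
    lambda_const: float = Field(LAMBDA_DEFAULT, lt=0)
    dt: float = Field(0.10, gt=0, lt=1)


class PhantomSection(_Strict):
    shape: tuple[int, int] = (128, 128)
    background_hu: float = 0.0
    insert_contrast_hu: float = 60.0
    insert_center: Optional[tuple[float, float]] = None
    insert_radius: float = Field(12.0, gt=0)
    edge_blur_sigma: float = Field(0.0, ge=0)
    noise_sd_hu: float = Field(0.0, ge=0)
    noise_corr_sigma: float = Field(0.0, ge=0)
    preset: Optional[Literal["fbp_like", "ir_like", "dlr_like"]] = None


class RunConfig(_Strict):
    """Top-level configuration; all sections optional with field defaults."""

    seed: int = 0
    noise_roi: RoiConfig = Field(default_factory=RoiConfig)
    radial: RadialSection = Field(default_factory=RadialSection)
    model: ModelConstants = Field(default_factory=ModelConstants)
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    output_dir: Optional[Path] = None

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=1))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
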