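"""Validated run configuration loaded from YAML or JSON.

Unknown keys are rejected so that typos in a config file fail loudly
instead of silently running with defaults.  A single top-level seed feeds
every stage's randomness.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fixtures import PopulationSpec, RosetteSpec
from .segment import SegmentConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationConfig(_Strict):
    n_plants: int = Field(50, ge=1)
    timeline: tuple[int, int] = (12, 32)
    a_mean: float = Field(0.9, gt=0)
    a_sd: float = Field(0.05, ge=0)
    b_mean: float = Field(0.085, gt=0)
    b_sd: float = Field(0.002, ge=0)
    shift_dist: tuple = ("uniform", -3, 3)
    leaf_noise_sd: float = Field(0.0, ge=0)
    leaf_noise_cv: float = Field(0.05, ge=0)
    area_noise_cv: float = Field(0.05, ge=0)
    diurnal_amplitude: float = Field(0.08, ge=0)
    missing_rate: float = Field(0.15, ge=0, le=1)
    frames_per_day: int = Field(48, ge=1)

    def to_spec(self, seed: int) -> PopulationSpec:
        return PopulationSpec(
            n_plants=self.n_plants, timeline=self.timeline,
            a_dist=(self.a_mean, self.a_sd), b_dist=(self.b_mean, self.b_sd),
            shift_dist=tuple(self.shift_dist),
            leaf_noise_sd=self.leaf_noise_sd, leaf_noise_cv=self.leaf_noise_cv,
            area_noise_cv=self.area_noise_cv,
            diurnal_amplitude=self.diurnal_amplitude,
            missing_rate=self.missing_rate, frames_per_day=self.frames_per_day,
            seed=seed)


class RosetteConfig(_Strict):
    n_images: int = Field(20, ge=1)
    n_leaves_range: tuple[int, int] = (2, 12)
    overlap_fraction: float = Field(0.2, ge=0, le=1)
    backgrounds: list[str] = ["plain", "soil"]
    image_size: tuple[int, int] = (256, 256)

    def specs(self):
        lo, hi = self.n_leaves_range
        for i in range(self.n_images):
            yield RosetteSpec(
                n_leaves=lo + i % (hi - lo + 1),
                overlap_fraction=self.overlap_fraction,
                background=self.backgrounds[i % len(self.backgrounds)],
                image_size=self.image_size)


class SegmentationConfig(_Strict):
    n_gamma_iters: int = Field(7, ge=1)
    gamma_range: tuple[float, float] = (0.6, 1.6)
    fg_low: float = 0.01
    fg_high: float = 0.25
    green_excess_cutoff: float = 20.0
    savgol_window: int = 11
    savgol_order: int = 3
    spatial_dilation_radius: int = 5
    kmeans_k: int = Field(3, ge=2)
    repair_sigma: float = Field(3.0, gt=0)
    min_object_px: int = Field(30, ge=0)
    apply_clahe: bool = True

    def to_config(self) -> SegmentConfig:
        return SegmentConfig(**self.model_dump())


class DapdConfig(_Strict):
    k_range: tuple[int, int] = (-7, 7)
    delta_range: tuple[int, int] = (-2, 2)
    leaf_range: tuple[float, float] = (2.0, 12.0)
    min_overlap: int = Field(5, ge=1)
    n_refine: int = Field(3, ge=1)
    impute_method: str = "spline"
    score: str = "msd"


class EvaluationConfig(_Strict):
    mad_threshold: float = Field(3.5, gt=0)
    persist_days: int = Field(3, ge=1)


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "dapd_out"
    population: PopulationConfig = PopulationConfig()
    rosettes: RosetteConfig = RosetteConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    dapd: DapdConfig = DapdConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})
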