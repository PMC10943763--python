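"""Run configuration: every tunable threshold with its published default.

The configuration is a strict schema (unknown keys are rejected) serialized
to/from YAML or JSON, so a run manifest plus a config file reproduces a run
exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .behavior import BehaviorParams
from .segmentation import SegmentationParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegConfig(_Strict):
    threshold: float | None = None      # None -> automatic (two-stage Otsu)
    wing_divisor: float = 80.0
    bg_window_px: int = 61
    min_object_px: int = 20
    open_radius: int = 1
    close_radius: int = 2

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class BehaviorConfig(_Strict):
    singing_deg: float = 30.0
    orient_ext: float = 2.5
    orient_halfangle: float = 10.0
    contact_mm: float = 1.0
    ecc_factor: float = 0.9
    cop_seconds: float = 30.0
    skel_branch_px: int = 5
    erode_radius: int = 2
    denoise_px: int = 10

    def to_params(self, filt: "FilterConfig") -> BehaviorParams:
        return BehaviorParams(**self.model_dump(),
                              filter_window=filt.window,
                              filter_min_hits=filt.min_hits,
                              none_gap=filt.none_gap)


class FilterConfig(_Strict):
    window: int = 12
    min_hits: int = 5   # certified when hits exceed this within the window
    none_gap: int = 12


class IdentityConfig(_Strict):
    reference_refresh_frames: int = 24
    watershed_h_fraction: float = 0.25
    min_fly_area_px: int = 120
    spectral_max_samples: int = 700


class CalibrationConfig(_Strict):
    mode: str = "auto"              # "auto" | "manual"
    manual_frame: int | None = None


class PipelineConfig(_Strict):
    """Full pipeline configuration with published defaults."""

    seed: int = 0
    arena_count: int = 1
    fps_override: float | None = None
    radius_range_px: tuple[int, int] | None = None
    window_mode: str = "full"       # full | to-copulation | seconds
    window_seconds: float | None = None
    seg: SegConfig = SegConfig()
    behavior: BehaviorConfig = BehaviorConfig()
    filter: FilterConfig = FilterConfig()
    identity: IdentityConfig = IdentityConfig()
    calibration: CalibrationConfig = CalibrationConfig()

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        return cls.model_validate(data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.model_dump()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=1))
        else:
            path.write_text(yaml.safe_dump(data))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]
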