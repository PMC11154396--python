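"""Pipeline configuration: the constants of the method in one validated record.

Every numeric default is the published operating point of the method —
256 px tiles, 65% background exclusion, candidate threshold 0.1, 12 px NMS
distance, 8 px match radius, 12 px annotation boxes, FP budgets
[10, 20, 50, 100, 200, 300], and the 16 x 16 px lymphocyte footprint implied
by an 8 µm cell at 0.5 µm/px.  Overriding any of them is recorded in the run
log and in the output metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants as C
from .scoring import lymphocyte_area_px

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    tile_side: int = C.TILE_SIDE
    max_bg: float = C.MAX_BACKGROUND_FRACTION
    tau: float = C.CANDIDATE_THRESHOLD
    nms_distance: float = C.NMS_DISTANCE
    match_radius: float = C.MATCH_RADIUS
    fp_targets: tuple[float, ...] = C.FP_TARGETS
    box_side: int = C.BOX_SIDE
    resolution_um_per_px: float = C.RESOLUTION_UM_PER_PX
    lymphocyte_diameter_um: float = C.LYMPHOCYTE_DIAMETER_UM
    seed: int = 0
    # synthetic-cohort knobs (simulate stage)
    n_slides: int = 20
    slide_width: int = 1024
    slide_height: int = 1024
    noise_sigma: float = 0.0
    # paths
    input_dir: str | None = None
    output_dir: str | None = None

    @property
    def lymphocyte_area(self) -> int:
        """Pixel footprint of one lymphocyte at the configured resolution."""
        return lymphocyte_area_px(self.lymphocyte_diameter_um, self.resolution_um_per_px)

    def validate(self) -> "PipelineConfig":
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must be a probability in [0, 1], got {self.tau}")
        if not (0.0 <= self.max_bg <= 1.0):
            raise ValueError(f"max_bg must be in [0, 1], got {self.max_bg}")
        if self.tile_side < 1 or self.box_side < 1:
            raise ValueError("tile_side and box_side must be >= 1")
        if self.nms_distance < 0 or self.match_radius < 0:
            raise ValueError("nms_distance and match_radius must be >= 0")
        if any(t < 0 for t in self.fp_targets):
            raise ValueError("fp_targets must be non-negative")
        if self.resolution_um_per_px <= 0 or self.lymphocyte_diameter_um <= 0:
            raise ValueError("resolution and lymphocyte diameter must be positive")
        if self.n_slides < 1 or self.slide_width < 1 or self.slide_height < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fp_targets"] = list(self.fp_targets)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, stamped on outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fp_targets" in data:
            data = {**data, "fp_targets": tuple(float(t) for t in data["fp_targets"])}
        cfg = cls(**data).validate()
        defaults = cls()
        for f in dataclasses.fields(cls):
            if f.name in data and getattr(cfg, f.name) != getattr(defaults, f.name):
                logger.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
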