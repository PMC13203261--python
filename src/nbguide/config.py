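"""Run configuration: every pipeline constant in one serialisable record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from . import phantom


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Serialises losslessly to/from YAML; every run should persist its
    resolved copy (plus the seed) next to its outputs for reproducibility.
    """

    overlap_threshold: float = 0.75
    overlap_measure: str = "iou"            # or "iomin"
    persistence_window: int = 5
    persistence_aggregate: str = "mean"     # or "last"
    initial_depth_cm: int = 6
    depth_buffer_cm: float = 1.0
    depth_bounds_cm: tuple[int, int] = (3, 10)
    depth_max_iterations: int = 5
    contact_sd_floor: float = 4.0
    safety_margin_mm: float = 1.0
    alignment_tolerance_mm: float = 1.0
    dwell_frames: int = 15
    eval_iou: float = 0.5
    dice_match_threshold: float = 0.90
    ap_interpolation: str = "envelope"      # or "trapezoid"
    frame_rate_hz: float = 30.0
    time_cap_ex_vivo_s: float = 600.0
    time_cap_in_vivo_s: float = 180.0
    scene: dict = field(default_factory=dict)      # SceneParams overrides
    noise_profile: str = "low"
    operator: dict = field(default_factory=dict)   # OperatorModel overrides
    seed: int = 0

    def scene_params(self) -> phantom.SceneParams:
        overrides = dict(self.scene)
        for key in ("fa_center_mm", "fv_center_mm", "fv_axes_mm"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        if "fi_band_points_mm" in overrides:
            overrides["fi_band_points_mm"] = tuple(
                tuple(p) for p in overrides["fi_band_points_mm"])
        return phantom.SceneParams(**overrides)

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        data["depth_bounds_cm"] = list(data["depth_bounds_cm"])
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "depth_bounds_cm" in data:
            data["depth_bounds_cm"] = tuple(data["depth_bounds_cm"])
        return cls(**data)
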