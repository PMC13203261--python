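"""Core value types shared across the guidance pipeline.

Conventions
-----------
* Images are 2-D ``uint8`` arrays indexed ``[row, col]`` with row = axial
  (down = deeper into tissue) and col = lateral (the mediolateral scan axis).
* Bounding boxes are half-open pixel intervals ``[row_min, row_max) x
  [col_min, col_max)`` so that integer boxes have exact integer areas.
* Physical scaling: axial mm/px = ``10 * depth_cm / image_height`` and
  lateral mm/px = ``10 * probe_width_cm / image_width``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

#: Landmark class vocabulary: femoral artery, femoral vein, fascia iliaca,
#: sciatic nerve (reserved for future models; carried but unused downstream).
CLASSES = ("FA", "FV", "FI", "SN")


class Box(NamedTuple):
    """Axis-aligned half-open box in pixel coordinates."""

    row_min: float
    col_min: float
    row_max: float
    col_max: float

    @property
    def height(self) -> float:
        return self.row_max - self.row_min

    @property
    def width(self) -> float:
        return self.col_max - self.col_min

    @property
    def area(self) -> float:
        return max(self.height, 0.0) * max(self.width, 0.0)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row_min + self.row_max) / 2.0,
                (self.col_min + self.col_max) / 2.0)

    def is_degenerate(self) -> bool:
        return self.height <= 0 or self.width <= 0

    def clipped(self, height: int, width: int) -> "Box":
        return Box(
            max(self.row_min, 0.0), max(self.col_min, 0.0),
            min(self.row_max, float(height)), min(self.col_max, float(width)),
        )


@dataclass(frozen=True)
class PixelCalibration:
    """Pixel to millimetre scaling for one acquisition setting."""

    mm_per_px_axial: float
    mm_per_px_lateral: float

    @classmethod
    def from_settings(cls, depth_cm: float, probe_width_cm: float,
                      height_px: int, width_px: int) -> "PixelCalibration":
        return cls(10.0 * depth_cm / height_px, 10.0 * probe_width_cm / width_px)

    def px_to_mm(self, point_px: tuple[float, float]) -> tuple[float, float]:
        return (point_px[0] * self.mm_per_px_axial,
                point_px[1] * self.mm_per_px_lateral)

    def mm_to_px(self, point_mm: tuple[float, float]) -> tuple[float, float]:
        return (point_mm[0] / self.mm_per_px_axial,
                point_mm[1] / self.mm_per_px_lateral)


@dataclass
class UltrasoundFrame:
    """One grayscale B-mode frame plus its acquisition metadata."""

    pixels: np.ndarray  # (H, W) uint8
    depth_cm: float
    probe_width_cm: float
    index: int = 0
    subject: Optional[str] = None
    condition: Optional[str] = None

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration.from_settings(
            self.depth_cm, self.probe_width_cm, self.height, self.width)


@dataclass
class Detection:
    """A class-labelled bounding box (optionally with a binary mask)."""

    label: str
    box: Box
    confidence: float
    mask: Optional[np.ndarray] = None  # frame-shaped bool array (FI only)

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class TrialRecord:
    """Outcome of one closed-loop guidance trial."""

    success: bool
    elapsed_s: Optional[float]  # cap value recorded on failure; None if unknown
    condition: str = "normovolemic"
    round_label: str = ""
    subject: str = ""
    aimpoint_method: str = "mask_centroid"
    aimpoint_error_mm: Optional[float] = None  # vs. true fascia centroid
    transcript: list = field(default_factory=list)
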