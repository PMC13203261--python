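"""Probe-contact confirmation and imaging-depth calibration.

Depth is set so that the deepest visible vessel sits about 1 cm above the
image bottom: starting from a 6 cm survey depth, the physical depth of the
deepest vessel box bottom is measured, a 1 cm buffer is added, and the
result is rounded up to the nearest integer centimetre.  The controller
iterates propose -> set -> re-detect until the proposal equals the current
depth (a fixed point of the ceil arithmetic), which for any static scene
with visible vessels happens within a few iterations.

The contact check is a deliberately simple stand-in: frames acquired
without skin contact are nearly uniform (no speckle), so the standard
deviation of the near-field rows separates coupled from air frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .types import Box, Detection, UltrasoundFrame

INITIAL_DEPTH_CM = 6
DEPTH_BUFFER_CM = 1.0
DEPTH_BOUNDS_CM = (3, 10)
DEFAULT_MAX_ITERATIONS = 5
CONTACT_SD_FLOOR = 4.0

VESSEL_CLASSES = ("FA", "FV")


@dataclass
class DepthState:
    """Outcome of a depth-calibration run."""

    current_depth_cm: int
    calibrated: bool
    proposals: list = field(default_factory=list)  # full proposal history
    iterations: int = 0          # acquisition cycles used
    depth_changes: int = 0       # number of times the depth setting moved


def contact_check(frame: UltrasoundFrame,
                  intensity_sd_floor: float = CONTACT_SD_FLOOR) -> bool:
    """True iff the near field (top 10% of rows) shows speckle texture."""
    top = frame.pixels[: max(1, frame.height // 10)]
    return float(np.std(top.astype(np.float64))) > intensity_sd_floor


def propose_depth(frame_height_px: int, current_depth_cm: float,
                  vessel_boxes: Iterable[Box],
                  buffer_cm: float = DEPTH_BUFFER_CM,
                  bounds_cm: tuple[int, int] = DEPTH_BOUNDS_CM,
                  ) -> Optional[int]:
    """Depth (integer cm) placing the deepest vessel ~buffer above the bottom.

    Returns ``None`` ("not ready") when no vessel box is available.
    """
    boxes = list(vessel_boxes)
    if not boxes:
        return None
    deepest_bottom_cm = max(b.row_max for b in boxes) / frame_height_px \
        * current_depth_cm
    proposal = math.ceil(deepest_bottom_cm + buffer_cm)
    return int(min(max(proposal, bounds_cm[0]), bounds_cm[1]))


def vessel_boxes_of(detections: Iterable[Detection]) -> list[Box]:
    return [d.box for d in detections if d.label in VESSEL_CLASSES]


def run_depth_calibration(
        acquire: Callable[[int], tuple[UltrasoundFrame, list[Detection]]],
        initial_depth_cm: int = INITIAL_DEPTH_CM,
        buffer_cm: float = DEPTH_BUFFER_CM,
        bounds_cm: tuple[int, int] = DEPTH_BOUNDS_CM,
        max_iterations: int = DEFAULT_MAX_ITERATIONS) -> DepthState:
    """Iterate propose/set/re-detect to the depth fixed point.

    ``acquire(depth_cm)`` must image the scene at the requested depth and
    return the frame with its (post-processed) detections.  Acquisition
    cycles where no vessel is detected count against ``max_iterations``;
    if the fixed point is not confirmed within the budget the state is
    returned uncalibrated with the proposal history attached.
    """
    depth = int(initial_depth_cm)
    state = DepthState(current_depth_cm=depth, calibrated=False)
    for _ in range(max_iterations):
        state.iterations += 1
        frame, detections = acquire(depth)
        proposal = propose_depth(frame.height, depth, vessel_boxes_of(detections),
                                 buffer_cm, bounds_cm)
        if proposal is None:
            continue  # keep scanning at the current depth
        state.proposals.append(proposal)
        if proposal == depth:
            state.calibrated = True
            break
        depth = proposal
        state.depth_changes += 1
        state.current_depth_cm = depth
    state.current_depth_cm = depth
    return state
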