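"""Aimpoint computation, artery safety margin, and operator guidance.

The needle target for a fascia iliaca block is the centroid of the fascia
iliaca (FI) segmentation mask; when no reliable mask is available the
centre of the FI bounding box is used instead.  Before the aligned state
is declared, the aimpoint must clear a safety margin (1 mm by default)
from the edge of the femoral artery (FA), taken as its bounding box since
the artery carries no mask.  Guidance is expressed as lateral move
instructions that steer a fixed needle path (an image column) onto the
aimpoint; once aligned, an insufficient margin triggers a cranial/caudal
reposition request, and an aligned, safe aimpoint yields the "green box"
state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import calibration as cal_mod
from . import phantom, postprocess
from .types import Box, PixelCalibration, TrialRecord

SAFETY_MARGIN_MM = 1.0
ALIGNMENT_TOLERANCE_MM = 1.0
DWELL_FRAMES = 15  # 0.5 s at 30 Hz of held alignment before success


class EmptyMaskError(ValueError):
    """Raised when a centroid is requested from an empty mask."""


class InstructionKind(str, enum.Enum):
    NO_CONTACT = "NO_CONTACT"
    SCANNING = "SCANNING"
    MOVE_MEDIAL = "MOVE_MEDIAL"       # toward increasing column by default
    MOVE_LATERAL = "MOVE_LATERAL"     # toward decreasing column
    REPOSITION_CRANIAL_CAUDAL = "REPOSITION_CRANIAL_CAUDAL"
    ALIGNED_SAFE = "ALIGNED_SAFE"


@dataclass(frozen=True)
class GuidanceInstruction:
    kind: InstructionKind
    lateral_error_mm: float = 0.0

    @property
    def display_green(self) -> bool:
        return self.kind is InstructionKind.ALIGNED_SAFE


@dataclass(frozen=True)
class Aimpoint:
    """Needle target in pixel and physical coordinates."""

    pixel: tuple[float, float]          # (row, col), continuous
    physical_mm: tuple[float, float]    # (axial, lateral)
    method: str                         # "mask_centroid" | "bbox_centroid"
    fa_margin_mm: Optional[float] = None
    safe: bool = False


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean of the (row, col) indices of the true pixels."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("cannot take the centroid of an empty mask")
    return float(rows.mean()), float(cols.mean())


def compute_aimpoint(fi_mask: Optional[np.ndarray], fi_box: Optional[Box],
                     calib: PixelCalibration,
                     method_override: Optional[str] = None,
                     ) -> Optional[Aimpoint]:
    """Aimpoint from the FI estimate: mask centroid, box-centre fallback.

    ``method_override="bbox_centroid"`` forces the bounding-box route (the
    operator switch for unreliable segmentations).  Returns ``None`` when
    no FI estimate exists at all.
    """
    use_mask = (fi_mask is not None and fi_mask.any()
                and method_override != "bbox_centroid")
    if use_mask:
        pixel = mask_centroid(fi_mask)
        method = "mask_centroid"
    elif fi_box is not None:
        pixel = Box(*fi_box).center
        method = "bbox_centroid"
    else:
        return None
    return Aimpoint(pixel=pixel, physical_mm=calib.px_to_mm(pixel),
                    method=method)


def fa_safety_margin(aimpoint: Aimpoint, fa_box: Box,
                     calib: PixelCalibration) -> float:
    """Euclidean mm distance from the aimpoint to the FA box (0 if inside).

    Anisotropic pixel scaling is applied before the distance, so the margin
    is physical regardless of the depth setting.
    """
    ar, ac = aimpoint.physical_mm
    r0 = fa_box.row_min * calib.mm_per_px_axial
    r1 = fa_box.row_max * calib.mm_per_px_axial
    c0 = fa_box.col_min * calib.mm_per_px_lateral
    c1 = fa_box.col_max * calib.mm_per_px_lateral
    dr = max(r0 - ar, 0.0, ar - r1)
    dc = max(c0 - ac, 0.0, ac - c1)
    return math.hypot(dr, dc)


def with_safety(aimpoint: Aimpoint, fa_box: Optional[Box],
                calib: PixelCalibration,
                margin_mm: float = SAFETY_MARGIN_MM) -> Aimpoint:
    """Attach the FA margin and safety verdict to an aimpoint.

    An absent FA estimate leaves the margin unknown and the aimpoint
    unsafe (the pipeline keeps scanning rather than risking the artery).
    """
    if fa_box is None:
        return replace(aimpoint, fa_margin_mm=None, safe=False)
    margin = fa_safety_margin(aimpoint, fa_box, calib)
    return replace(aimpoint, fa_margin_mm=margin, safe=margin >= margin_mm)


def guidance_step(aimpoint: Optional[Aimpoint], needle_path_col: float,
                  calib: PixelCalibration,
                  contact: bool = True, calibrated: bool = True,
                  tolerance_mm: float = ALIGNMENT_TOLERANCE_MM,
                  ) -> GuidanceInstruction:
    """One guidance decision for the current frame.

    The lateral error is signed toward increasing column; the MOVE
    instruction tells the operator to slide the probe so the needle path
    closes on the aimpoint.  Alignment without a known margin keeps
    scanning; alignment with a known but insufficient margin asks for a
    cranial/caudal reposition; alignment with a sufficient margin is the
    green-box state.
    """
    if not contact:
        return GuidanceInstruction(InstructionKind.NO_CONTACT)
    if not calibrated or aimpoint is None:
        return GuidanceInstruction(InstructionKind.SCANNING)
    error_mm = (aimpoint.pixel[1] - needle_path_col) * calib.mm_per_px_lateral
    if abs(error_mm) > tolerance_mm:
        kind = (InstructionKind.MOVE_MEDIAL if error_mm > 0
                else InstructionKind.MOVE_LATERAL)
        return GuidanceInstruction(kind, error_mm)
    if aimpoint.fa_margin_mm is None:
        return GuidanceInstruction(InstructionKind.SCANNING, error_mm)
    if not aimpoint.safe:
        return GuidanceInstruction(
            InstructionKind.REPOSITION_CRANIAL_CAUDAL, error_mm)
    return GuidanceInstruction(InstructionKind.ALIGNED_SAFE, error_mm)


@dataclass(frozen=True)
class OperatorModel:
    """Simulated device operator.

    Before following instructions the operator spends a seeded
    ``search_time_s`` interval sweeping the probe mediolaterally, emulating
    the acoustic-window search that dominates real trial times.  After the
    search phase the operator reacts to MOVE instructions after
    ``latency_frames`` by translating the probe ``compliance_gain`` of the
    commanded error, with Gaussian motion noise, and reacts to reposition
    requests by shifting the scan site (the scene is re-jittered,
    emulating out-of-plane cranial/caudal motion).
    """

    compliance_gain: float = 0.5
    latency_frames: int = 20
    motion_noise_sd_mm: float = 0.4
    initial_offset_mm: tuple[float, float] = (4.0, 12.0)  # |offset| range
    search_time_s: tuple[float, float] = (5.0, 35.0)      # sweep duration range
    sweep_amplitude_mm: float = 8.0
    sweep_period_s: float = 4.0


@dataclass
class TranscriptEntry:
    frame: int
    kind: str
    lateral_error_mm: float
    margin_mm: Optional[float]
    green: bool


def run_trial(phantom_config: Optional[phantom.SceneParams] = None,
              operator: Optional[OperatorModel] = None,
              noise: Optional[phantom.OracleNoise] = None,
              time_cap_s: float = 180.0,
              seed: int = 0,
              safety_margin_mm: float = SAFETY_MARGIN_MM,
              tolerance_mm: float = ALIGNMENT_TOLERANCE_MM,
              dwell_frames: int = DWELL_FRAMES,
              overlap_threshold: float = postprocess.DEFAULT_OVERLAP_THRESHOLD,
              persistence_window: int = postprocess.DEFAULT_PERSISTENCE_WINDOW,
              method_override: Optional[str] = None,
              round_label: str = "", subject: str = "") -> TrialRecord:
    """Run one closed-loop guidance trial against the phantom at 30 Hz.

    Contact confirmation and depth calibration consume frames first; the
    guidance loop then runs until ALIGNED_SAFE has been held for
    ``dwell_frames`` consecutive frames (success) or the time cap expires
    (failure, with the cap recorded as the trial time).
    """
    operator = operator or OperatorModel()
    noise = noise or phantom.OracleNoise()
    rng = np.random.default_rng(seed)
    scene = phantom.make_scene(phantom_config, seed=int(rng.integers(2**31)))
    lo, hi = operator.initial_offset_mm
    offset0 = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
    scene = phantom.step_scene(scene, offset0, 0)

    max_frames = int(round(time_cap_s * phantom.FRAME_RATE_HZ))
    frames_used = 0
    transcript: list[TranscriptEntry] = []
    tracker = postprocess.LandmarkTracker(window=persistence_window)

    def detect(current_scene):
        frame, truth = phantom.render_frame(current_scene)
        dets, fi_mask = phantom.oracle_detect(
            truth, noise, seed=int(rng.integers(2**31)),
            frame_shape=frame.pixels.shape)
        return frame, truth, dets, fi_mask

    # --- contact confirmation -------------------------------------------
    frame, truth, dets, fi_mask = detect(scene)
    frames_used += 1
    contact = cal_mod.contact_check(frame)
    if not contact:
        transcript.append(TranscriptEntry(0, "NO_CONTACT", 0.0, None, False))
    # the phantom is always coupled; a failed check would simply stall below

    # --- depth calibration ----------------------------------------------
    def acquire(depth_cm):
        nonlocal scene, frames_used
        scene = phantom.set_depth(scene, depth_cm)
        frames_used += 1
        frame, _, raw, mask = detect(scene)
        states = postprocess.process_frame(
            tracker, raw, mask, overlap_threshold=overlap_threshold)
        current = [postprocess.Detection(s.label, s.box, s.confidence)
                   for s in states.values() if s.source == "current"]
        return frame, current

    depth_state = cal_mod.run_depth_calibration(acquire)
    calibrated = depth_state.calibrated
    scene = phantom.set_depth(scene, depth_state.current_depth_cm)

    # --- guidance loop ---------------------------------------------------
    aligned_run = 0
    success = False
    final_aimpoint: Optional[Aimpoint] = None
    pending_move: Optional[tuple[int, float]] = None  # (due_frame, move_mm)
    needle_col = None
    search_frames = int(round(
        rng.uniform(*operator.search_time_s) * phantom.FRAME_RATE_HZ))
    search_end = frames_used + search_frames
    sweep_omega = 2.0 * np.pi / (operator.sweep_period_s
                                 * phantom.FRAME_RATE_HZ)
    base_offset = scene.lateral_offset_mm

    while frames_used < max_frames:
        if frames_used < search_end:
            # exploratory mediolateral sweep; instructions not yet followed
            target = base_offset + operator.sweep_amplitude_mm \
                * float(np.sin(sweep_omega * (search_end - frames_used)))
            scene = phantom.step_scene(
                scene, target - scene.lateral_offset_mm, frames_used)
            frame, truth, dets, fi_mask = detect(scene)
            frames_used += 1
            postprocess.process_frame(tracker, dets, fi_mask,
                                      overlap_threshold=overlap_threshold)
            continue
        scene = phantom.step_scene(scene, 0.0, frames_used)
        frame, truth, dets, fi_mask = detect(scene)
        frames_used += 1
        calib = frame.calibration
        needle_col = frame.width / 2.0

        states = postprocess.process_frame(
            tracker, dets, fi_mask, overlap_threshold=overlap_threshold)
        fi_state = states.get("FI")
        fa_state = states.get("FA")
        aim = None
        if fi_state is not None:
            aim = compute_aimpoint(fi_state.mask, fi_state.box, calib,
                                   method_override)
        if aim is not None:
            aim = with_safety(aim, fa_state.box if fa_state else None,
                              calib, safety_margin_mm)
        instr = guidance_step(aim, needle_col, calib,
                              contact=contact, calibrated=calibrated,
                              tolerance_mm=tolerance_mm)
        transcript.append(TranscriptEntry(
            frames_used - 1, instr.kind.value, instr.lateral_error_mm,
            aim.fa_margin_mm if aim else None, instr.display_green))

        if instr.kind is InstructionKind.ALIGNED_SAFE:
            aligned_run += 1
            final_aimpoint = aim
            if aligned_run >= dwell_frames:
                success = True
                break
        else:
            aligned_run = 0

        # operator response
        if instr.kind in (InstructionKind.MOVE_MEDIAL,
                          InstructionKind.MOVE_LATERAL):
            if pending_move is None:
                move = operator.compliance_gain * instr.lateral_error_mm \
                    + float(rng.normal(0.0, operator.motion_noise_sd_mm))
                pending_move = (frames_used + operator.latency_frames, move)
        elif instr.kind is InstructionKind.REPOSITION_CRANIAL_CAUDAL:
            if pending_move is None:
                # shift the scan site: new anatomy jitter, same condition
                scene = phantom.make_scene(
                    replace(scene, lateral_offset_mm=scene.lateral_offset_mm),
                    seed=int(rng.integers(2**31)))
                pending_move = (frames_used + operator.latency_frames, 0.0)
        if pending_move is not None and frames_used >= pending_move[0]:
            scene = phantom.step_scene(scene, pending_move[1], frames_used)
            pending_move = None

    elapsed = frames_used / phantom.FRAME_RATE_HZ if success else time_cap_s
    error_mm = None
    if final_aimpoint is not None:
        _, truth = phantom.render_frame(scene)
        if truth.fi_centroid_px is not None:
            calib = scene.calibration
            true_mm = calib.px_to_mm(truth.fi_centroid_px)
            error_mm = math.hypot(
                final_aimpoint.physical_mm[0] - true_mm[0],
                final_aimpoint.physical_mm[1] - true_mm[1])
    return TrialRecord(
        success=success, elapsed_s=round(elapsed, 3),
        condition=scene.condition, round_label=round_label, subject=subject,
        aimpoint_method=(final_aimpoint.method if final_aimpoint
                         else (method_override or "mask_centroid")),
        aimpoint_error_mm=error_mm, transcript=transcript)
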