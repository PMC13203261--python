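"""Detection post-processing: top-1 per class, vessel overlap arbitration,
and short-horizon temporal persistence.

The raw detector output for a frame may contain several boxes per class,
spurious vessel duplicates, and dropped frames.  This module reduces it to
at most one validated landmark estimate per class:

1. keep only the highest-confidence detection per class (runners-up are
   retained as alternates);
2. if the artery and vein boxes overlap by more than a threshold (75% by
   default) they cannot both be right -- keep the higher-confidence one and
   fall back to the losing class's next candidate if that candidate clears
   the threshold;
3. if a class is missing on the current frame, estimate it from the
   detections accepted over the most recent few frames (window of 5), and
   report nothing once the class has been absent longer than the window.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .types import Box, Detection

DEFAULT_OVERLAP_THRESHOLD = 0.75
DEFAULT_PERSISTENCE_WINDOW = 5


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two half-open boxes."""
    box_a, box_b = Box(*box_a), Box(*box_b)
    if box_a.is_degenerate() or box_b.is_degenerate():
        raise ValueError("IOU undefined for zero-area box")
    ih = min(box_a.row_max, box_b.row_max) - max(box_a.row_min, box_b.row_min)
    iw = min(box_a.col_max, box_b.col_max) - max(box_a.col_min, box_b.col_min)
    inter = max(ih, 0.0) * max(iw, 0.0)
    union = box_a.area + box_b.area - inter
    return inter / union


def intersection_over_min(box_a: Box, box_b: Box) -> float:
    """Fraction of the smaller box covered by the intersection."""
    box_a, box_b = Box(*box_a), Box(*box_b)
    if box_a.is_degenerate() or box_b.is_degenerate():
        raise ValueError("overlap undefined for zero-area box")
    ih = min(box_a.row_max, box_b.row_max) - max(box_a.row_min, box_b.row_min)
    iw = min(box_a.col_max, box_b.col_max) - max(box_a.col_min, box_b.col_min)
    inter = max(ih, 0.0) * max(iw, 0.0)
    return inter / min(box_a.area, box_b.area)


_OVERLAP_FN = {"iou": iou, "iomin": intersection_over_min}


def _rank_key(det: Detection) -> tuple:
    # confidence desc, then larger area, then shallower box: deterministic
    return (-det.confidence, -det.box.area, det.box.row_min)


def top1_per_class(detections: Iterable[Detection],
                   ) -> tuple[dict[str, Detection], dict[str, list[Detection]]]:
    """Keep the highest-confidence detection per class.

    Returns ``(best, alternates)`` where ``alternates[label]`` holds the
    runners-up sorted by descending confidence, for overlap arbitration.
    """
    best: dict[str, Detection] = {}
    alternates: dict[str, list[Detection]] = {}
    by_class: dict[str, list[Detection]] = {}
    for det in detections:
        by_class.setdefault(det.label, []).append(det)
    for label, dets in by_class.items():
        dets.sort(key=_rank_key)
        best[label] = dets[0]
        if len(dets) > 1:
            alternates[label] = dets[1:]
    return best, alternates


def resolve_vessel_overlap(
        fa_candidates: list[Detection], fv_candidates: list[Detection],
        overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
        overlap_measure: str = "iou",
) -> tuple[Optional[Detection], Optional[Detection]]:
    """Arbitrate overlapping artery/vein detections.

    Candidates must be sorted by descending confidence.  If the top FA and
    FV boxes overlap above the threshold, the higher-confidence one wins
    and the losing class falls back to its next candidate whose overlap
    with the winner is at or below the threshold (possibly none).
    """
    overlap = _OVERLAP_FN[overlap_measure]
    fa = fa_candidates[0] if fa_candidates else None
    fv = fv_candidates[0] if fv_candidates else None
    if fa is None or fv is None:
        return fa, fv
    if overlap(fa.box, fv.box) <= overlap_threshold:
        return fa, fv
    if (fa.confidence, -_rank_key(fa)[1]) >= (fv.confidence, -_rank_key(fv)[1]):
        winner, losers, lost_first = fa, fv_candidates[1:], "FV"
    else:
        winner, losers, lost_first = fv, fa_candidates[1:], "FA"
    replacement = None
    for cand in losers:
        if overlap(winner.box, cand.box) <= overlap_threshold:
            replacement = cand
            break
    if lost_first == "FV":
        return winner, replacement
    return replacement, winner


@dataclass
class LandmarkState:
    """Per-class tracked estimate with provenance."""

    label: str
    box: Box
    confidence: float
    source: str  # "current" | "persisted"
    age_frames: int
    mask: Optional[np.ndarray] = None  # last accepted mask (FI)


@dataclass
class LandmarkTracker:
    """Temporal persistence over a sliding window of accepted detections.

    A class detected on the current frame is reported as-is (age 0).  A
    class missing on the current frame is reported as the corner-wise mean
    of its accepted boxes from the last ``window`` frames (``aggregate =
    "mean"``; ``"last"`` reports the most recent box instead) until it has
    been missing for more than ``window`` consecutive frames, after which
    nothing is reported.  Masks are not averaged; the most recent accepted
    mask is carried while the estimate persists.
    """

    window: int = DEFAULT_PERSISTENCE_WINDOW
    aggregate: str = "mean"
    _frame: int = field(default=-1, repr=False)
    _buffers: dict = field(default_factory=dict, repr=False)
    _last_masks: dict = field(default_factory=dict, repr=False)

    def update(self, detections: Iterable[Detection],
               ) -> dict[str, LandmarkState]:
        """Advance one frame and return the per-class landmark estimates."""
        self._frame += 1
        current = {d.label: d for d in detections}
        states: dict[str, LandmarkState] = {}
        for det in current.values():
            buf = self._buffers.setdefault(det.label, deque())
            buf.append((self._frame, det))
            if det.mask is not None:
                self._last_masks[det.label] = det.mask
        for label, buf in self._buffers.items():
            while buf and buf[0][0] < self._frame - self.window:
                buf.popleft()
                if not buf:
                    self._last_masks.pop(label, None)
        for label, det in current.items():
            states[label] = LandmarkState(
                label, det.box, det.confidence, "current", 0, det.mask)
        for label, buf in self._buffers.items():
            if label in current or not buf:
                continue
            age = self._frame - buf[-1][0]
            if age > self.window:
                continue
            dets = [d for _, d in buf]
            if self.aggregate == "mean":
                corners = np.mean([list(d.box) for d in dets], axis=0)
                box = Box(*corners)
            else:
                box = dets[-1].box
            conf = float(np.mean([d.confidence for d in dets]))
            states[label] = LandmarkState(
                label, box, conf, "persisted", age, self._last_masks.get(label))
        return states


def process_frame(tracker: LandmarkTracker, detections: Iterable[Detection],
                  fi_mask: Optional[np.ndarray] = None,
                  overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
                  overlap_measure: str = "iou") -> dict[str, LandmarkState]:
    """Full per-frame post-processing chain.

    Applies top-1 selection, vessel arbitration and persistence, attaching
    ``fi_mask`` (the segmentation output) to the accepted FI detection.
    """
    best, alternates = top1_per_class(detections)
    fa_list = [best["FA"]] + alternates.get("FA", []) if "FA" in best else []
    fv_list = [best["FV"]] + alternates.get("FV", []) if "FV" in best else []
    fa, fv = resolve_vessel_overlap(fa_list, fv_list,
                                    overlap_threshold, overlap_measure)
    accepted = [d for d in (fa, fv) if d is not None]
    if "FI" in best:
        fi = best["FI"]
        if fi_mask is not None:
            fi = Detection(fi.label, fi.box, fi.confidence, mask=fi_mask)
        accepted.append(fi)
    return tracker.update(accepted)
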