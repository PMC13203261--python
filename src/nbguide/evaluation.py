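"""Detection and segmentation evaluation protocol.

Implements the metric suite used to characterise the landmark models:
confidence-ranked one-to-one box matching at IOU 0.5, per-class
precision-recall curves with average precision (AUPRC) by the monotone
precision-envelope rule, Dice-coefficient summaries for segmentation,
subject-level dataset splitting (70:10:20), letterbox resizing with exact
box back-projection, and trial-outcome statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .postprocess import iou
from .types import Box, Detection, TrialRecord

EVAL_IOU_THRESHOLD = 0.5
DICE_MATCH_THRESHOLD = 0.90


@dataclass
class MatchResult:
    """Ranked detection outcomes for one class."""

    scored: list  # [(confidence, is_true_positive), ...] any order
    n_truth: int

    def extend(self, other: "MatchResult") -> None:
        self.scored.extend(other.scored)
        self.n_truth += other.n_truth


def match_detections(predictions: Sequence[Sequence[Detection]],
                     ground_truth: Sequence[Sequence[Detection]],
                     iou_threshold: float = EVAL_IOU_THRESHOLD,
                     ) -> dict[str, MatchResult]:
    """Greedy one-to-one matching of predictions to truths, per frame/class.

    Within a frame and class, predictions are taken in descending
    confidence; each claims the unmatched ground-truth box with the
    highest IOU at or above the threshold.  Unclaimed predictions are
    false positives; unclaimed truths are false negatives.
    """
    if len(predictions) != len(ground_truth):
        raise ValueError("predictions and ground truth must align per frame")
    results: dict[str, MatchResult] = {}
    for preds, truths in zip(predictions, ground_truth):
        labels = {d.label for d in preds} | {t.label for t in truths}
        for label in labels:
            res = results.setdefault(label, MatchResult([], 0))
            p = sorted((d for d in preds if d.label == label),
                       key=lambda d: -d.confidence)
            t_boxes = [t.box for t in truths if t.label == label]
            res.n_truth += len(t_boxes)
            unmatched = list(range(len(t_boxes)))
            for det in p:
                best_j, best_val = None, -1.0
                for j in unmatched:
                    val = iou(det.box, t_boxes[j])
                    if val >= iou_threshold and val > best_val:
                        best_j, best_val = j, val
                if best_j is not None:
                    unmatched.remove(best_j)
                    res.scored.append((det.confidence, True))
                else:
                    res.scored.append((det.confidence, False))
    return results


def pr_curve_and_auprc(match: MatchResult, interpolation: str = "envelope",
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and its area for one class.

    ``interpolation="envelope"`` (default) uses the monotone precision
    envelope (all-points average precision); ``"trapezoid"`` integrates
    the raw curve instead.
    """
    if match.n_truth == 0:
        raise ValueError("AUPRC undefined with zero ground-truth instances")
    if not match.scored:
        return np.array([0.0]), np.array([1.0]), 0.0
    order = sorted(match.scored, key=lambda s: -s[0])
    tp = np.cumsum([1.0 if hit else 0.0 for _, hit in order])
    fp = np.cumsum([0.0 if hit else 1.0 for _, hit in order])
    recall = tp / match.n_truth
    precision = tp / (tp + fp)
    if interpolation == "envelope":
        env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev = np.concatenate(([0.0], recall[:-1]))
        area = float(np.sum((recall - r_prev) * env))
        return recall, env, area
    if interpolation == "trapezoid":
        r = np.concatenate(([0.0], recall))
        p = np.concatenate(([precision[0]], precision))
        area = float(np.trapezoid(p, r))
        return recall, precision, area
    raise ValueError(f"unknown interpolation {interpolation!r}")


def macro_auprc(matches: dict[str, MatchResult],
                interpolation: str = "envelope") -> float:
    """All-classes score: unweighted mean of the per-class areas."""
    if not matches:
        raise ValueError("no classes to average")
    return float(np.mean([pr_curve_and_auprc(m, interpolation)[2]
                          for m in matches.values()]))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binary masks."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def dice_summary(values: Iterable[float],
                 threshold: float = DICE_MATCH_THRESHOLD,
                 bins: int = 10) -> dict:
    """Mean, median, histogram and the fraction above a match threshold."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no Dice values to summarise")
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return {
        "n": int(vals.size),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        "threshold": threshold,
        "fraction_above_threshold": float((vals > threshold).mean()),
    }


@dataclass(frozen=True)
class SplitAssignment:
    """Subject-level train/validation/test partition."""

    assignment: dict  # subject -> "train" | "validation" | "test"
    ratios: tuple[float, float, float]

    def subjects(self, split: str) -> list:
        return sorted(s for s, g in self.assignment.items() if g == split)


SPLIT_NAMES = ("train", "validation", "test")


def subject_split(subject_ids: Sequence, ratios=(0.7, 0.1, 0.2),
                  seed: int = 0,
                  pinned: Optional[dict] = None) -> SplitAssignment:
    """Assign whole subjects to splits by largest-remainder rounding.

    Splitting at the subject level keeps all images of one animal in the
    same partition, so training data cannot leak into validation or test.
    ``pinned`` forces specific subjects into specific splits before the
    remainder are shuffled and assigned.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) < len(SPLIT_NAMES):
        raise ValueError("need at least one subject per split")
    total = float(sum(ratios))
    ratios = tuple(r / total for r in ratios)
    pinned = dict(pinned or {})
    for subj, split in pinned.items():
        if subj not in ids:
            raise ValueError(f"pinned subject {subj!r} not in subject list")
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")

    n = len(ids)
    assignment = dict(pinned)
    free = [s for s in ids if s not in pinned]
    pinned_counts = [sum(1 for s in pinned.values() if s == name)
                     for name in SPLIT_NAMES]
    # allocate the unpinned subjects against the residual quotas
    residual = [max(ratios[i] * n - pinned_counts[i], 0.0) for i in range(3)]
    total_residual = sum(residual)
    if total_residual > 0:
        quota = [r * len(free) / total_residual for r in residual]
    else:
        quota = [len(free) / 3.0] * 3
    counts = [math.floor(q) for q in quota]
    leftover = len(free) - sum(counts)
    by_remainder = sorted(range(3), key=lambda i: (-(quota[i] - counts[i]), i))
    for i in by_remainder[:leftover]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    rng.shuffle(free)
    cursor = 0
    for i, name in enumerate(SPLIT_NAMES):
        for s in free[cursor:cursor + counts[i]]:
            assignment[s] = name
        cursor += counts[i]
    return SplitAssignment(assignment=assignment, ratios=ratios)


def trial_statistics(records: Sequence[TrialRecord],
                     group_by: Sequence[str] = ("round_label", "condition"),
                     ) -> dict:
    """Success-rate and timing summaries, overall and per grouping key.

    Success rate is percent to one decimal.  Failed trials contribute the
    recorded cap value to the time statistics; records with no recorded
    time are excluded from timing (not from the success rate).
    """
    if not records:
        raise ValueError("no trial records")
    df = pd.DataFrame({
        "success": [r.success for r in records],
        "elapsed_s": [r.elapsed_s for r in records],
        "round_label": [r.round_label for r in records],
        "condition": [r.condition for r in records],
    })

    def summarise(sub: pd.DataFrame) -> dict:
        times = sub["elapsed_s"].dropna()
        return {
            "attempts": int(len(sub)),
            "successes": int(sub["success"].sum()),
            "success_rate_pct": round(float(100.0 * sub["success"].mean()), 1),
            "time_mean_s": round(float(times.mean()), 1) if len(times) else None,
            "time_sd_s": (round(float(times.std(ddof=1)), 1)
                          if len(times) > 1 else None),
        }

    out = {"overall": summarise(df)}
    for key in group_by:
        groups = {}
        for value, sub in df.groupby(key, sort=True):
            if value == "":
                continue
            groups[str(value)] = summarise(sub)
        if groups:
            out[f"by_{key}"] = groups
    return out


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of subgroup means."""
    if len(means) != len(ns) or not means:
        raise ValueError("means and counts must align and be nonempty")
    return float(np.average(means, weights=ns))


@dataclass(frozen=True)
class LetterboxTransform:
    """Record of a letterbox resize, sufficient for exact box round-trips."""

    scale: float
    pad_top: float
    pad_left: float
    target: int

    def apply_box(self, box: Box) -> Box:
        return Box(box.row_min * self.scale + self.pad_top,
                   box.col_min * self.scale + self.pad_left,
                   box.row_max * self.scale + self.pad_top,
                   box.col_max * self.scale + self.pad_left)

    def invert_box(self, box: Box) -> Box:
        return Box((box.row_min - self.pad_top) / self.scale,
                   (box.col_min - self.pad_left) / self.scale,
                   (box.row_max - self.pad_top) / self.scale,
                   (box.col_max - self.pad_left) / self.scale)


def letterbox_resize(frame: np.ndarray, target_square_size: int,
                     ) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize to a zero-padded square.

    The longer side is scaled to ``target_square_size``; the shorter side
    is padded symmetrically with zeros (odd padding puts the extra pixel
    at the bottom/right).
    """
    if target_square_size <= 0:
        raise ValueError("target size must be positive")
    h, w = frame.shape[:2]
    scale = target_square_size / max(h, w)
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    resized = np.asarray(
        Image.fromarray(frame).resize((new_w, new_h), Image.BILINEAR))
    pad_top = (target_square_size - new_h) // 2
    pad_left = (target_square_size - new_w) // 2
    out = np.zeros((target_square_size, target_square_size) + frame.shape[2:],
                   dtype=frame.dtype)
    out[pad_top:pad_top + new_h, pad_left:pad_left + new_w] = resized
    return out, LetterboxTransform(scale=scale, pad_top=float(pad_top),
                                   pad_left=float(pad_left),
                                   target=target_square_size)
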