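"""File formats: JSON-lines detection streams, YOLO labels, PNG frames.

Detection streams are JSON-lines files: a header record
``{"schema": "nbguide.detections/1", "height": H, "width": W, ...}``
followed by one record per frame holding pixel-coordinate boxes and an
optional run-length-encoded FI mask.  YOLO label files are the usual one
line per box: ``class_index cx cy w h [confidence]`` with centre/size
normalised by the frame dimensions.

Run-length encoding is row-major over the flattened mask, alternating
run lengths starting with the number of leading zeros (COCO-style
uncompressed counts).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from PIL import Image

from .types import Box, CLASSES, Detection, UltrasoundFrame

SCHEMA = "nbguide.detections/1"
CLASS_INDEX = {label: i for i, label in enumerate(CLASSES)}


class StreamFormatError(ValueError):
    """A detection stream line failed to parse; carries the line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


# --- run-length encoding -------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Row-major RLE of a binary mask; counts start with the zero run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        raise ValueError("cannot encode an empty array")
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    edges = np.concatenate(([0], changes + 1, [flat.size]))
    counts = np.diff(edges).tolist()
    if flat[0]:  # counts must start with a (possibly zero) run of zeros
        counts = [0] + counts
    return {"shape": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    counts = rle["counts"]
    total = int(np.prod(shape))
    if sum(counts) != total:
        raise ValueError("RLE counts do not cover the mask")
    flat = np.zeros(total, dtype=bool)
    pos = 0
    for i, run in enumerate(counts):
        if i % 2 == 1:
            flat[pos:pos + run] = True
        pos += run
    return flat.reshape(shape)


# --- JSON-lines detection streams ---------------------------------------

def _detection_to_record(det: Detection) -> dict:
    rec = {"label": det.label, "box": [float(v) for v in det.box],
           "confidence": float(det.confidence)}
    if det.mask is not None:
        rec["mask_rle"] = rle_encode(det.mask)
    return rec


def _record_to_detection(rec: dict) -> Detection:
    mask = rle_decode(rec["mask_rle"]) if "mask_rle" in rec else None
    return Detection(rec["label"], Box(*rec["box"]),
                     float(rec["confidence"]), mask=mask)


def write_detection_stream(path, frames: Iterable[dict],
                           height: int, width: int,
                           metadata: Optional[dict] = None) -> None:
    """Write per-frame records ``{"frame": i, "detections": [...], ...}``.

    Each frame dict must hold a ``detections`` list of :class:`Detection`;
    any other keys (depth_cm, condition, ...) are passed through.
    """
    path = Path(path)
    with path.open("w") as fh:
        header = {"schema": SCHEMA, "height": int(height), "width": int(width)}
        if metadata:
            header.update(metadata)
        fh.write(json.dumps(header) + "\n")
        for rec in frames:
            out = {k: v for k, v in rec.items() if k != "detections"}
            out["detections"] = [_detection_to_record(d)
                                 for d in rec["detections"]]
            fh.write(json.dumps(out) + "\n")


def read_detection_stream(path) -> tuple[dict, list[dict]]:
    """Read a stream; returns ``(header, frames)`` with parsed detections."""
    path = Path(path)
    header: Optional[dict] = None
    frames: list[dict] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(lineno, f"invalid JSON: {exc}") from exc
            if lineno == 1:
                if rec.get("schema") != SCHEMA:
                    raise StreamFormatError(
                        lineno, f"expected schema {SCHEMA!r}")
                header = rec
                continue
            try:
                rec["detections"] = [_record_to_detection(d)
                                     for d in rec.get("detections", [])]
            except (KeyError, TypeError, ValueError) as exc:
                raise StreamFormatError(lineno, str(exc)) from exc
            frames.append(rec)
    if header is None:
        raise StreamFormatError(1, "missing header record")
    return header, frames


# --- YOLO-style label text ----------------------------------------------

def write_yolo_labels(path, detections: Iterable[Detection],
                      height: int, width: int,
                      with_confidence: bool = True) -> None:
    """One line per box: ``class cx cy w h [conf]``, normalised to [0, 1]."""
    lines = []
    for det in detections:
        b = det.box
        cy = (b.row_min + b.row_max) / 2.0 / height
        cx = (b.col_min + b.col_max) / 2.0 / width
        bh = b.height / height
        bw = b.width / width
        parts = [str(CLASS_INDEX[det.label]),
                 f"{cx:.6f}", f"{cy:.6f}", f"{bw:.6f}", f"{bh:.6f}"]
        if with_confidence:
            parts.append(f"{det.confidence:.6f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, height: int, width: int) -> list[Detection]:
    detections = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise StreamFormatError(lineno, "expected 5 or 6 fields")
        try:
            idx = int(parts[0])
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise StreamFormatError(lineno, str(exc)) from exc
        if not (0 <= idx < len(CLASSES)):
            raise StreamFormatError(lineno, f"class index {idx} out of range")
        box = Box((cy - bh / 2) * height, (cx - bw / 2) * width,
                  (cy + bh / 2) * height, (cx + bw / 2) * width)
        detections.append(Detection(CLASSES[idx], box, conf))
    return detections


# --- PNG frames ----------------------------------------------------------

def save_frame_png(path, frame: UltrasoundFrame) -> None:
    """8-bit grayscale PNG plus a JSON sidecar with acquisition metadata."""
    path = Path(path)
    Image.fromarray(frame.pixels, mode="L").save(path)
    sidecar = {"depth_cm": frame.depth_cm,
               "probe_width_cm": frame.probe_width_cm,
               "index": frame.index, "subject": frame.subject,
               "condition": frame.condition}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_frame_png(path) -> UltrasoundFrame:
    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("L"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return UltrasoundFrame(pixels=pixels, **sidecar)
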