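"""Synthetic femoral-region B-mode phantom with analytic ground truth.

The phantom emulates a transverse scan of the inguinal region: a circular,
pulsatile femoral artery (FA); a larger elliptical, compressible femoral
vein (FV) whose size also tracks circulating volume (hypovolemia shrinks
it); and a thin hyperechoic fascia iliaca (FI) band above the vessels.
Vessel lumens render anechoic (dark), the fascia hyperechoic (bright),
over a speckled background with linear depth attenuation.

All geometry is defined in physical millimetres in a fixed "world" frame;
the probe window slides along the lateral (mediolateral) axis, so operator
motion simply shifts which part of the scene is imaged.  Because every
structure is analytic, ground-truth masks, tight bounding boxes and the
fascia centroid are known exactly for every frame, which lets an oracle
detector with controllable noise stand in for a trained network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import Box, Detection, PixelCalibration, UltrasoundFrame

FRAME_RATE_HZ = 30.0  # fixed frame clock; trial time = frames / 30

# Echo levels on the 8-bit scale (before attenuation and speckle).
_BACKGROUND_LEVEL = 90.0
_FASCIA_LEVEL = 220.0
_LUMEN_LEVEL = 8.0


class SceneConfigError(ValueError):
    """A scene parameter is outside its admissible range."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class SceneParams:
    """Full description of one phantom scene at one instant.

    Lengths are millimetres unless suffixed otherwise; ``(axial, lateral)``
    ordering throughout.  ``volemia`` scales both vein semi-axes (1.0 =
    normovolemic); ``compression`` additionally shrinks the vein's axial
    semi-axis, emulating probe pressure.
    """

    image_height_px: int = 480
    image_width_px: int = 320
    depth_cm: float = 6.0
    probe_width_cm: float = 4.0
    fa_center_mm: tuple[float, float] = (30.0, 0.0)
    fa_radius_mm: float = 4.0
    fa_pulse_amp_mm: float = 0.3
    heart_rate_bpm: float = 60.0
    fv_center_mm: tuple[float, float] = (32.0, 9.0)
    fv_axes_mm: tuple[float, float] = (5.0, 6.5)
    compression: float = 0.0
    volemia: float = 1.0
    fi_band_points_mm: tuple[tuple[float, float], ...] = (
        (21.0, -16.0), (19.5, 0.0), (21.0, 16.0))
    fi_thickness_mm: float = 2.0
    lateral_offset_mm: float = 0.0
    speckle_seed: int = 0
    speckle_amp: float = 0.35
    attenuation: float = 0.35
    anatomy_jitter_mm: float = 1.5
    frame_index: int = 0

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration.from_settings(
            self.depth_cm, self.probe_width_cm,
            self.image_height_px, self.image_width_px)

    @property
    def condition(self) -> str:
        return "normovolemic" if self.volemia >= 1.0 else "hypovolemic"

    def fa_radius_at(self, frame_index: int) -> float:
        """Instantaneous artery radius on the cardiac pulsation cycle."""
        phase = 2.0 * np.pi * (self.heart_rate_bpm / 60.0) \
            * frame_index / FRAME_RATE_HZ
        return self.fa_radius_mm + self.fa_pulse_amp_mm * float(np.sin(phase))

    def fv_axes_effective(self) -> tuple[float, float]:
        ax, lat = self.fv_axes_mm
        return (ax * self.volemia * (1.0 - self.compression), lat * self.volemia)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-class truth for one rendered frame."""

    masks: dict  # label -> (H, W) bool array (may be all-False)
    boxes: dict  # label -> Box or None (tight box of the mask)
    fi_centroid_px: Optional[tuple[float, float]]
    fa_center_px: Optional[tuple[float, float]]
    fa_radius_px: Optional[tuple[float, float]]  # (axial, lateral)


def _validate(scene: SceneParams) -> None:
    positive = {
        "image_height_px": scene.image_height_px,
        "image_width_px": scene.image_width_px,
        "depth_cm": scene.depth_cm,
        "probe_width_cm": scene.probe_width_cm,
        "fa_radius_mm": scene.fa_radius_mm,
        "fi_thickness_mm": scene.fi_thickness_mm,
        "heart_rate_bpm": scene.heart_rate_bpm,
    }
    for name, value in positive.items():
        if value <= 0:
            raise SceneConfigError(name, f"must be positive, got {value}")
    if scene.fa_pulse_amp_mm < 0:
        raise SceneConfigError("fa_pulse_amp_mm", "must be non-negative")
    if any(a <= 0 for a in scene.fv_axes_mm):
        raise SceneConfigError("fv_axes_mm", "semi-axes must be positive")
    if not (0.0 <= scene.compression <= 1.0):
        raise SceneConfigError("compression", "must lie in [0, 1]")
    if not (0.0 < scene.volemia <= 1.0):
        raise SceneConfigError("volemia", "must lie in (0, 1]")
    if not (0.0 <= scene.speckle_amp <= 1.0):
        raise SceneConfigError("speckle_amp", "must lie in [0, 1]")
    if not (0.0 <= scene.attenuation < 1.0):
        raise SceneConfigError("attenuation", "must lie in [0, 1)")
    if len(scene.fi_band_points_mm) < 2:
        raise SceneConfigError("fi_band_points_mm", "needs >= 2 points")


def make_scene(config: SceneParams | None = None, seed: int = 0) -> SceneParams:
    """Validate a configuration and apply seeded anatomical jitter.

    Jitter (uniform within ``+/- anatomy_jitter_mm``) displaces the vessel
    centres and the fascia band, emulating between-subject / between-site
    variation.  Deterministic: equal ``(config, seed)`` give equal scenes.
    """
    base = config if config is not None else SceneParams()
    _validate(base)
    rng = np.random.default_rng(seed)
    j = base.anatomy_jitter_mm
    d_ax, d_lat = (rng.uniform(-j, j), rng.uniform(-j, j)) if j > 0 else (0.0, 0.0)
    scene = dataclasses.replace(
        base,
        fa_center_mm=(base.fa_center_mm[0] + d_ax, base.fa_center_mm[1] + d_lat),
        fv_center_mm=(base.fv_center_mm[0] + d_ax, base.fv_center_mm[1] + d_lat),
        fi_band_points_mm=tuple((p[0] + d_ax, p[1] + d_lat)
                                for p in base.fi_band_points_mm),
    )
    _validate(scene)
    return scene


def step_scene(scene: SceneParams, operator_move_mm: float,
               frame_index: int) -> SceneParams:
    """Advance the scene: slide the probe laterally and set the frame phase."""
    return dataclasses.replace(
        scene,
        lateral_offset_mm=scene.lateral_offset_mm + operator_move_mm,
        frame_index=frame_index,
    )


def set_depth(scene: SceneParams, depth_cm: float) -> SceneParams:
    """Re-image the same anatomy at a new depth setting."""
    if depth_cm <= 0:
        raise SceneConfigError("depth_cm", "must be positive")
    return dataclasses.replace(scene, depth_cm=float(depth_cm))


def _grids(scene: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Physical coordinates (mm) of pixel centres: axial depth and world lateral."""
    cal = scene.calibration
    ax = (np.arange(scene.image_height_px) + 0.5) * cal.mm_per_px_axial
    half_w = 5.0 * scene.probe_width_cm  # probe_width_cm/2 in mm
    lat = scene.lateral_offset_mm - half_w \
        + (np.arange(scene.image_width_px) + 0.5) * cal.mm_per_px_lateral
    return ax[:, None], lat[None, :]


def _band_mask(ax: np.ndarray, lat: np.ndarray,
               points: tuple[tuple[float, float], ...],
               thickness: float) -> np.ndarray:
    """Pixels within thickness/2 of the fascia polyline (finite extent)."""
    half = thickness / 2.0
    best = np.full(np.broadcast_shapes(ax.shape, lat.shape), np.inf)
    for (a0, l0), (a1, l1) in zip(points[:-1], points[1:]):
        da, dl = a1 - a0, l1 - l0
        denom = da * da + dl * dl
        t = ((ax - a0) * da + (lat - l0) * dl) / denom
        np.clip(t, 0.0, 1.0, out=t)
        dist2 = (ax - (a0 + t * da)) ** 2 + (lat - (l0 + t * dl)) ** 2
        np.minimum(best, dist2, out=best)
    return best <= half * half


def _tight_box(mask: np.ndarray) -> Optional[Box]:
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(mask.any(axis=0))
    return Box(float(rows[0]), float(cols[0]),
               float(rows[-1] + 1), float(cols[-1] + 1))


def render_frame(scene: SceneParams) -> tuple[UltrasoundFrame, GroundTruth]:
    """Render one frame and its analytic ground truth.

    Echo model: depth-attenuated background with the fascia band painted
    bright and the vessel lumens dark, then multiplicative Rayleigh-like
    speckle (mean 1) scaled by ``speckle_amp``.  Speckle is seeded from
    ``(speckle_seed, frame_index)`` so sequences are reproducible.
    """
    _validate(scene)
    ax, lat = _grids(scene)
    cal = scene.calibration

    fa_r = scene.fa_radius_at(scene.frame_index)
    fa_mask = ((ax - scene.fa_center_mm[0]) ** 2
               + (lat - scene.fa_center_mm[1]) ** 2) <= fa_r * fa_r
    v_ax, v_lat = scene.fv_axes_effective()
    fv_mask = (((ax - scene.fv_center_mm[0]) / v_ax) ** 2
               + ((lat - scene.fv_center_mm[1]) / v_lat) ** 2) <= 1.0
    fi_mask = _band_mask(ax, lat, scene.fi_band_points_mm, scene.fi_thickness_mm)

    gain = 1.0 - scene.attenuation * ax / (10.0 * scene.depth_cm)
    img = np.broadcast_to(_BACKGROUND_LEVEL * gain,
                          fa_mask.shape).astype(np.float64).copy()
    img[fi_mask] = (_FASCIA_LEVEL * np.broadcast_to(gain, img.shape))[fi_mask]
    img[fa_mask | fv_mask] = _LUMEN_LEVEL

    if scene.speckle_amp > 0:
        rng = np.random.default_rng([scene.speckle_seed, scene.frame_index])
        # Rayleigh with unit mean so speckle is brightness-neutral on average
        speck = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=img.shape)
        img *= (1.0 - scene.speckle_amp) + scene.speckle_amp * speck

    frame = UltrasoundFrame(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        depth_cm=scene.depth_cm, probe_width_cm=scene.probe_width_cm,
        index=scene.frame_index, condition=scene.condition)

    masks = {"FA": fa_mask, "FV": fv_mask, "FI": fi_mask}
    boxes = {label: _tight_box(m) for label, m in masks.items()}
    if fi_mask.any():
        rr, cc = np.nonzero(fi_mask)
        fi_centroid = (float(rr.mean()), float(cc.mean()))
    else:
        fi_centroid = None
    if fa_mask.any():
        half_w = 5.0 * scene.probe_width_cm
        fa_center_px = (
            scene.fa_center_mm[0] / cal.mm_per_px_axial - 0.5,
            (scene.fa_center_mm[1] - scene.lateral_offset_mm + half_w)
            / cal.mm_per_px_lateral - 0.5)
        fa_radius_px = (fa_r / cal.mm_per_px_axial, fa_r / cal.mm_per_px_lateral)
    else:
        fa_center_px = fa_radius_px = None
    truth = GroundTruth(masks=masks, boxes=boxes, fi_centroid_px=fi_centroid,
                        fa_center_px=fa_center_px, fa_radius_px=fa_radius_px)
    return frame, truth


@dataclass(frozen=True)
class OracleNoise:
    """Corruption model for the oracle detector.

    ``dropout_prob`` may be a single probability applied to every class or a
    ``{label: p}`` mapping.  With all fields zero the oracle reproduces the
    ground truth exactly with confidence 1.0.
    """

    jitter_sd_px: float = 0.0
    dropout_prob: float | dict = 0.0
    false_positive_rate: float = 0.0
    confidence_noise: float = 0.0
    mask_dropout_prob: float = 0.0

    def dropout_for(self, label: str) -> float:
        if isinstance(self.dropout_prob, dict):
            return float(self.dropout_prob.get(label, 0.0))
        return float(self.dropout_prob)

    def validate(self) -> None:
        probs = list(self.dropout_prob.values()) if isinstance(
            self.dropout_prob, dict) else [self.dropout_prob]
        for p in probs + [self.false_positive_rate, self.mask_dropout_prob]:
            if not (0.0 <= float(p) <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.jitter_sd_px < 0 or self.confidence_noise < 0:
            raise ValueError("noise scales must be non-negative")


#: Noise presets used by the scripted campaigns.
NOISE_PROFILES = {
    "zero": OracleNoise(),
    "low": OracleNoise(jitter_sd_px=0.5, dropout_prob=0.02,
                       confidence_noise=0.05),
    "moderate": OracleNoise(jitter_sd_px=1.5, dropout_prob=0.15,
                            false_positive_rate=0.05, confidence_noise=0.1,
                            mask_dropout_prob=0.1),
    "heavy": OracleNoise(jitter_sd_px=4.0, dropout_prob=0.4,
                         false_positive_rate=0.15, confidence_noise=0.2,
                         mask_dropout_prob=0.3),
    "blind": OracleNoise(dropout_prob=1.0, mask_dropout_prob=1.0),
}


def oracle_detect(truth: GroundTruth, noise: OracleNoise | None = None,
                  seed: int = 0,
                  frame_shape: tuple[int, int] | None = None,
                  ) -> tuple[list[Detection], Optional[np.ndarray]]:
    """Emit detections from ground truth under a controllable noise model.

    Returns ``(detections, fi_mask)``; the mask is the segmentation-model
    stand-in and may be dropped independently of the FI box.  Deterministic
    given ``seed``.
    """
    noise = noise or OracleNoise()
    noise.validate()
    rng = np.random.default_rng(seed)
    if frame_shape is None:
        any_mask = next(iter(truth.masks.values()))
        frame_shape = any_mask.shape
    height, width = frame_shape

    detections: list[Detection] = []
    for label in ("FA", "FV", "FI"):
        box = truth.boxes.get(label)
        if box is None:
            continue
        if rng.random() < noise.dropout_for(label):
            continue
        corners = np.array(box, dtype=float)
        if noise.jitter_sd_px > 0:
            corners = corners + rng.normal(0.0, noise.jitter_sd_px, size=4)
        jittered = Box(*corners).clipped(height, width)
        if jittered.is_degenerate():
            continue
        shift = float(np.mean(np.abs(corners - np.array(box)))) if \
            noise.jitter_sd_px > 0 else 0.0
        conf = 1.0 - min(1.0, shift / 10.0)
        if noise.confidence_noise > 0:
            conf += rng.uniform(-noise.confidence_noise, noise.confidence_noise)
        detections.append(Detection(label, jittered,
                                    float(np.clip(conf, 0.0, 1.0))))

    if noise.false_positive_rate > 0:
        while rng.random() < noise.false_positive_rate:
            label = ("FA", "FV", "FI")[rng.integers(3)]
            r0 = rng.uniform(0, height - 8)
            c0 = rng.uniform(0, width - 8)
            fp_box = Box(r0, c0, r0 + rng.uniform(8, height / 3),
                         c0 + rng.uniform(8, width / 3)).clipped(height, width)
            detections.append(
                Detection(label, fp_box, float(rng.uniform(0.05, 0.3))))

    fi_mask = truth.masks.get("FI")
    if fi_mask is not None and fi_mask.any():
        if rng.random() < noise.mask_dropout_prob:
            fi_mask = None
    else:
        fi_mask = None
    return detections, fi_mask
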