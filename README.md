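# nbguide

Ultrasound landmark guidance for fascia iliaca nerve blocks.

A fascia iliaca compartment block delivers local anesthetic into the
fascial plane above the femoral nerve. Placing the needle requires
recognising three landmarks on a transverse B-mode image of the inguinal
region — the femoral artery (FA), femoral vein (FV), and the thin fascia
iliaca (FI) layer — and choosing an aimpoint inside the FI that stays
safely clear of the artery. `nbguide` implements the image-interpretation
and operator-guidance chain of an AI-assisted needle-guidance device as a
testable Python library and CLI, for researchers working on automated
regional anesthesia, detection post-processing, or closed-loop ultrasound
guidance.

Because the clinical datasets and trained detector weights behind such
devices are not public, the package ships a synthetic femoral-region
phantom (pulsatile circular artery, compressible ellipse vein, thin
fascia band, speckle and depth attenuation) with analytically known
ground truth, and an *oracle detector* whose noise (box jitter, per-class
dropout, false positives, confidence noise) is fully controllable. Every
downstream rule can therefore be tested end to end with no data
downloads.

## What it implements

- **Detection post-processing** — keep only the top-scoring box per
  class; if the FA and FV boxes overlap by more than 75% (IOU), keep the
  higher-confidence one and fall back to the other class's next candidate
  below the threshold; persist a missing class as the corner-wise mean of
  its boxes from the five most recent frames, dropping the estimate after
  the window expires.
- **Depth calibration** — from a 6 cm survey depth, set depth to
  `ceil(deepest vessel bottom [cm] + 1)` and iterate to the fixed point.
- **Aimpoint and safety** — aimpoint = centroid of the FI segmentation
  mask (bounding-box centre as fallback or operator override); Euclidean
  mm distance from the aimpoint to the FA box must clear a 1 mm margin
  before the aligned "green box" state is declared; otherwise the
  operator is asked to reposition cranially/caudally.
- **Closed-loop trials** — a seeded operator model (search sweep,
  compliance gain, latency, motion noise) runs the full loop at 30 Hz
  against the phantom with a configurable time cap; campaigns aggregate
  trials into success-rate / timing tables.
- **Evaluation protocol** — greedy confidence-ranked box matching at
  IOU ≥ 0.5, per-class precision–recall curves and average precision
  (AP, precision-envelope rule; AUPRC of all classes = macro mean), Dice
  coefficient `2|A∩B|/(|A|+|B|)` summaries, subject-level 70:10:20
  splits, and letterbox resizing with exact box back-projection.

## Worked example

```python
import nbguide as nb

scene = nb.make_scene(seed=7)                      # jittered anatomy
frame, truth = nb.render_frame(scene)              # 480x320 B-mode frame
dets, fi_mask = nb.oracle_detect(truth, nb.OracleNoise(jitter_sd_px=1.0),
                                 seed=7)

tracker = nb.LandmarkTracker()
states = nb.process_frame(tracker, dets, fi_mask)  # top-1 + arbitration
calib = frame.calibration
aim = nb.compute_aimpoint(states["FI"].mask, states["FI"].box, calib)
aim = nb.with_safety(aim, states["FA"].box, calib)
instr = nb.guidance_step(aim, needle_path_col=frame.width / 2, calib=calib)
```

prints, with the formatting of the example script:

```
aimpoint px      : (164.8, 169.1)  [mask_centroid]
aimpoint mm      : (20.6, 21.1)
artery margin mm : 5.81  safe=True
instruction      : MOVE_MEDIAL  lateral error +1.1 mm
```

The aimpoint is the FI mask centroid, 20.6 mm deep and 21.1 mm across;
it is 5.81 mm from the artery box (safe at the 1 mm margin), and the
operator is told to slide the probe 1.1 mm toward increasing column to
bring the needle path onto it. A full closed-loop trial:

```python
rec = nb.run_trial(seed=7, noise=nb.NOISE_PROFILES["low"])
# success=True  time=18.8 s  aim error 0.00 mm
```

succeeds in 18.8 simulated seconds (mostly the operator's scan-search
phase) with the final aimpoint on the true fascia centroid.

The same pipeline is scriptable from the shell:

```bash
nbguide simulate --seed 0 --frames 30 --out out/sim
nbguide guide    --stream out/sim/detections.jsonl --out out/transcript.csv
nbguide evaluate --pred out/sim/detections.jsonl \
                 --truth out/sim/ground_truth.jsonl
nbguide campaign --kind in-vivo-style --seed 0 --out out/campaign
```

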