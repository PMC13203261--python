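# Methods

This note documents the models, parameters, numerical conventions and
design choices behind `nbguide`, and what the synthetic phantom does and
does not establish about real ultrasound data.

## Coordinate and box conventions

Images are `uint8` arrays indexed `[row, col]`; row is the axial axis
(down = deeper), col the lateral (mediolateral) axis. Boxes are
half-open pixel intervals `[row_min, row_max) × [col_min, col_max)`, so
integer boxes have exact integer areas and IOU/overlap arithmetic is
unambiguous. Physical scaling is linear: axial mm/px = `10·depth_cm/H`,
lateral mm/px = `10·probe_width_cm/W`; px→mm→px round trips are exact.

Mask centroids are the arithmetic mean of the true-pixel *indices*,
while a box centroid is the centre of its half-open extent. The two
conventions differ by exactly half a pixel for a filled rectangle (index
mean 14.5 for rows 10…19 vs box centre 15.0). Both are kept as stated
because each is the natural definition for its object; all accuracy
comparisons (aimpoint vs. true centroid) use the index-mean convention
on both sides, so the offset cancels. At the default trial resolution
half a pixel is 0.125 mm, far below the 1 mm alignment tolerance.

## The phantom

The scene is defined analytically in world millimetres and re-rendered
for any probe position and depth setting:

- **FA**: circle, default centre (30, 0) mm, radius 4 mm, pulsating
  sinusoidally ±0.3 mm at 60 bpm on the 30 Hz frame clock (period = 30
  frames).
- **FV**: ellipse, centre (32, 9) mm, semi-axes (5, 6.5) mm. `volemia`
  scales both semi-axes (hypovolemic campaigns use 0.65); `compression`
  additionally shrinks the axial semi-axis. Vein area is therefore
  monotone non-increasing in both, by construction and by test.
- **FI**: a band of constant thickness (2 mm) around a shallow
  three-point polyline spanning ±16 mm laterally — a finite structure
  whose world-frame centroid is a well-defined target.
- **Echo model**: mid-grey background with linear depth attenuation
  (35% at the image bottom), fascia bright (220), lumens dark (8),
  multiplicative Rayleigh speckle with unit mean (amplitude 0.35),
  seeded per `(speckle_seed, frame_index)`.

`make_scene(config, seed)` applies uniform anatomical jitter
(±1.5 mm default) to vessel centres and the fascia band, emulating
subject and scan-site variation; given equal `(config, seed)` the scene,
frames and ground truth are bit-identical.

Ground truth (per-class masks, tight boxes, FI centroid, analytic FA
circle) follows from the same inequalities that drive the renderer, so
every ground-truth box is exactly the tight box of its mask.

**What the phantom does not model**: acoustic shadowing, refraction and
reverberation artefacts, out-of-plane anatomy, probe tilt, nerve
visibility, and tissue deformation other than the vein compression
term. Passing tests on the phantom demonstrate the correctness of the
decision logic (arbitration, persistence, calibration, safety margin,
guidance), not detector performance on clinical images — which is why
detector quality enters only through the controllable oracle noise
model.

## Oracle detector

With zero noise the oracle returns the ground-truth boxes and FI mask at
confidence 1.0. Noise terms: Gaussian corner jitter (px), per-class
Bernoulli dropout, geometric-count false positives at confidence
U(0.05, 0.3), uniform confidence noise, and independent FI-mask dropout.
Confidence is `clip(1 − mean|corner shift|/10 + U(−c, c), 0, 1)` —
crude, but monotone in localisation error, which is all the ranking
metrics need. Four named profiles (`zero`, `low`, `moderate`, `heavy`,
plus `blind`) pin the grids used by campaigns and the safety suite.

## Post-processing

- Top-1 per class; confidence ties broken by larger area, then smaller
  `row_min` (deterministic output).
- Vessel arbitration: "overlap by more than 75%" is implemented as
  IOU > 0.75. IOU is the only overlap measure defined by the evaluation
  protocol; intersection-over-minimum is available via
  `overlap_measure="iomin"` for the reading where the fraction of the
  smaller box is meant.
- Persistence (window 5): a class missing on the current frame is
  estimated as the corner-wise *mean* of its accepted boxes from the
  last 5 frames ("last-seen" available via `aggregate="last"`), with the
  age reported; after 6 consecutive misses nothing is reported. Under
  independent per-frame dropout `p` the long-run empty-estimate rate is
  `p⁶`. Persisted estimates are flagged and excluded from PR evaluation,
  which consumes raw detections: the PR metrics characterise the
  detector, not the tracker. Masks are carried (most recent), never
  averaged.

## Depth calibration

Proposal = `ceil(deepest vessel bottom in cm + 1.0)`, clamped to
[3, 10] cm; iterate propose→set→re-detect until proposal equals the
current depth, budget 5 acquisition cycles. The 1 cm buffer is exact:
the round-up already absorbs "approximately". Decreases are allowed.
Starting from 6 cm, a vessel deeper than the current image is clipped at
the bottom row, so each iteration raises depth by ≥ 1 cm until the
vessel is visible; over vessel bottoms in [2, 8] cm the fixed point
`ceil(bottom+1)` is reached within 3 depth changes (the worst case,
bottoms in (7, 8], runs 6→7→8→9). The contact check is a deliberately
simple stand-in — standard deviation of the top 10% of rows above a
floor of 4 grey levels — since coupled frames carry speckle texture and
air frames are near-uniform.

## Guidance and trials

The needle path is a fixed image column (the centre); needle mechanics
are out of scope. Lateral error (mm) is signed toward increasing
column; a MOVE instruction is emitted when |error| > 1 mm. The FA
"edge" is its bounding box (the artery has no mask); the margin is the
Euclidean point-to-rectangle distance computed after converting both to
millimetres, so anisotropic pixel scaling cannot bias it. ALIGNED_SAFE
requires |error| ≤ 1 mm *and* margin ≥ 1 mm, held for 15 consecutive
frames (0.5 s) to suppress single-frame flicker; an aligned aimpoint
with an unknown margin (no FA estimate) keeps SCANNING, and with a known
but insufficient margin triggers the cranial/caudal reposition, which is
simulated by re-jittering the scene (out-of-plane motion is not modelled
geometrically).

The operator model is seeded and deliberately human-like: an initial
mediolateral search sweep lasting U(5, 35) s (amplitude 8 mm, period
4 s) before instructions are followed, then compliance gain 0.5 per
instruction, 20-frame reaction latency, 0.4 mm motion noise. These
defaults were chosen once so that low-noise trial times land on the
tens-of-seconds scale that human-operated trials occupy, and then
pinned; they are **not** fitted to any published mean time, and
simulated timings should not be read as predictions of human
performance. Failed trials record the time cap as their elapsed time
and enter timing statistics at that value.

## Evaluation

Matching is greedy per frame and class: predictions in descending
confidence each claim the unmatched truth with the highest IOU ≥ 0.5.
AP uses the monotone precision-envelope (all-points) rule, the dominant
convention for the single-stage detector family this protocol targets;
trapezoidal integration is available as a flag. The all-classes AUPRC
is the unweighted (macro) mean of per-class APs. AP is invariant under
strictly increasing confidence rescaling, and a noise-free oracle
yields AP 1.0 for every class and FI Dice 1.0 — both asserted by test.
Dice of two empty masks is an error rather than a convention value.
Subject-level splits use seeded shuffling with largest-remainder
rounding (20 subjects → 14/2/4) and support pinning subjects to splits
(e.g. one of three bench subjects in each split). Letterbox resizing
scales the longer side to the square target and zero-pads the shorter
side symmetrically; the transform record back-projects boxes exactly.

Success rates are reported as percentages to one decimal; grouped time
statistics use the sample standard deviation. Records rebuilt from
published count tables carry no per-attempt times and are excluded from
timing aggregates.

## Problem sizes and tolerances

Default frames are 480×320 (0.125 mm/px at 6 cm); closed-loop trials
and campaigns use 240×160 (0.25 mm/px), which keeps a 60-trial campaign
around a minute of compute while leaving quantisation an order of
magnitude below the 1 mm tolerances. The test suite uses 300-frame
sequences for oracle-equivalence checks, 10,000 frames for the
persistence law (asserted within 3 binomial standard errors of `p⁶` —
an approximation, since overlapping miss-runs are weakly dependent),
a 0.1 cm grid over [2, 8] cm for depth calibration, 3 noise profiles ×
50 seeded trials (30 s cap, short-search operator) for the safety
invariant, and 1,000 randomised small instances per metric against
brute-force oracles.

## Known limitations

- The oracle's confidence model is monotone in jitter but not a
  calibrated probability; ranking metrics are meaningful, absolute
  confidences are not.
- The operator model has no hand tremor spectrum, no probe-pressure
  coupling to the compression term, and follows instructions with a
  fixed gain; convergence speed is therefore optimistic for compliant
  settings and the search phase dominates simulated times.
- Cranial/caudal repositioning re-draws anatomy rather than moving
  through a 3-D volume; sequential repositions are independent draws.
- The sciatic-nerve class is carried in the vocabulary but has no
  phantom structure or guidance rules.
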