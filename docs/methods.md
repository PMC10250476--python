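# Methods

This note records the models, conventions and design choices behind
`ethopose`, and what the synthetic benchmark does and does not establish.

## Egocentric normalization

Each frame is normalized independently (no temporal smoothing; tracks are
used as the tracker emits them).  The body point is translated to the
origin, a middle-neck vector is formed from the two neck points, and all
parts are rotated counter-clockwise by `rot = degrees(arctan2(v_x, v_y))`,
the signed angle of that vector from the +y axis.  This maps the
middle-neck vector onto the non-negative y-axis; since the middle-neck
vector is the left-minus-right neck *difference*, it is the neck line —
not the spine — that lands on +y, and the spine ends up along +x.  The
classifier is indifferent to this overall fixed orientation; what matters
is that the transform is a per-frame isometry of relative geometry and
exactly invariant under rigid motion of the animal.

An alternative convention that aligns the neck *midpoint* (and hence
approximately the spine) with +y is available as
`middle_neck_mode="midpoint"`; the difference convention is the default.

Degenerate frames with a zero middle-neck vector get rotation 0° and are
flagged, never dropped, so frame indices stay aligned with label tables.
Angles are stored in degrees in `(-180, 180]`; internal trigonometry uses
radians.

## Labels

Behavior names are matched exactly after trimming surrounding whitespace
and lower-casing; anything else (including a trailing space) is reported
by the validator rather than silently accepted, because name drift is the
annotation error class this guard exists for.  Overlapping slices are an
error, not last-writer-wins: behaviors are mutually exclusive under a
single-observer protocol, so an overlap indicates an annotation bug.

## Windows

Sliding windows advance one frame at a time and are flattened frame-major
into vectors of length `n_features × window_size`.  Training windows
never straddle a label boundary or a frame-index gap created by
unlabeled-frame removal — a mixed-label window has no coherent target.
Each window is attributed to its **last** frame (causal convention): at
prediction time this is the frame at which the window's content was fully
observable, and it keeps ethograms aligned. Where a window's prediction
is attributed is a genuine convention choice (first/center/last frame);
the causal one is used throughout and documented here once.

## Classifier

The shipped backend is a scikit-learn random forest with
`max_features = sqrt` and balanced class weights
`w_c = total/(n_classes · count_c)` computed explicitly in
`classify.class_weights` (the weighted counts sum back to the total — a
useful audit identity).  Defaults: 20 trees (a good accuracy/time
trade-off; validation curves over 1–100 trees are supported), seed-fixed
and therefore bit-reproducible.  Tree-level parameters not surfaced in
the config (depth, leaf sizes) stay at library defaults and are recorded
in the fitted model's metadata.  The backend contract
(`fit(X, y, class_weight, seed)` / `predict_proba(X)`) lets deep
time-series architectures plug in without pipeline changes; none ship
here.

## Evaluation

Five-fold blocked ("non-shuffled") cross-validation: contiguous test
blocks of `n // 5` windows, remainder joining the last block; fold *i*
tests on block *i* and trains on the rest, so the last fold is exactly
"first 80 % train, last 20 % test" and doubles as the held-out split for
per-class metrics and confusion matrices.  Shuffled splits are
deliberately not offered: at ~120 fps neighboring windows are
near-duplicates and shuffling would leak them across the split.

Metrics follow the standard precision/recall/F1 definitions with the
conservative zero convention (a metric with an empty denominator is 0);
the headline score is the support-weighted F1.  Learning curves use
contiguous prefixes of each fold's training windows, never random
subsamples, preserving the blocked discipline.

## Tuple thresholds

The post-processing rule `(fallback, target, threshold)` reassigns a
frame predicted as `target` to `fallback` when the fallback class's own
probability is at least the threshold.  A margin rule (comparing
`target − fallback`) would produce the same qualitative trade; the
absolute-fallback-probability form is implemented because it is the
simpler rule with the intended monotone behavior: at threshold 1 the rule
is inert, at threshold 0 it absorbs every target call, and raising the
threshold never removes target predictions.  Rules apply in list order
with at most one reassignment per frame.  Choosing and tuning rules is
left to the user; no automatic optimization is attempted.

## Synthetic benchmark

The simulator produces what the pipeline consumes — 10-keypoint tracks
(head, beak, left/right neck, body, four wing points, tail) at 119.88 fps
on a 1280×960 canvas with per-point likelihoods — with deliberately
simple kinematics.  Its job is to carry the statistical structure of the
problem, not anatomical realism:

- **Jitter** is i.i.d. Gaussian, default 3 px per keypoint, the
  magnitude of typical tracker error.  Note the leverage effect:
  jittered neck points inject heading noise through the normalization
  rotation (≈ 4° for the 60 px neck baseline), which laterally smears
  distal parts by several pixels — an effect real tracks share.
- **Static classes** are posture-defined: eating lowers head and beak
  with a slow dip cycle, preening moves head/beak to a wing point in
  alternating contact episodes, fluffing displaces the wing points
  outward with amplified ruffling jitter.
- **Walking** translates the bird (2 px/frame with heading wander,
  bouncing off the arena margin) and adds vertical head-bobbing — the
  signature of pigeon locomotion and, after normalization removes the
  translation, the only remaining walking cue.  This is a deliberate
  design choice: per-frame egocentric normalization cancels pure
  translation exactly, so a translation-only walking model would be
  indistinguishable from standing by construction.
- **Shakes** are lateral sinusoids (amplitude 10 px, period 10 frames)
  of head+beak or tail.  Standing adds a slow AR(1) idle drift of head
  and tail (sd 2.5 × jitter, correlation time ~50 frames), so the
  *marginal* per-frame head distribution in standing nearly matches a
  shake bout; only the temporal pattern inside a window separates them.
  This realizes the intended mechanism for the window-size effect:
  single-frame classifiers are near chance on shakes while 16-frame
  windows are separable.  The drift amplitude scales with the jitter
  parameter, so zero-noise tracks are exactly static.
- **Beak occlusion**: on 60 % of frames the beak likelihood drops to
  0.05–0.35 and its position is glitched, so the default likelihood
  cutoff (0.6, mirroring common tracker cutoffs) excludes the beak —
  leaving 9 parts × 2 = 18 features.
- **Imbalance**: the default profile is standing 30 %, eating 25 %,
  walking 20 %, preening 10 %, fluffing 7 %, head/tail shake 4 % each,
  interleaved in shuffled 2,000-frame rounds so every behavior occurs in
  every cross-validation block.

What passing tests on this benchmark shows: the pipeline's mechanics
(normalization, windowing, weighting, blocked CV, thresholds) behave as
specified, and the classifier recovers behaviors whose signal survives
normalization.  What it does not show: performance on real video, where
tracking error is autocorrelated and heavy-tailed, behaviors blend into
each other, bout boundaries are fuzzy, and inter-individual variation
exists.  Real-data scores must be established on real annotations.

## Problem sizes and numerical conventions

The bundled experiments run the benchmark at 50,000 frames (≈ 7 minutes
of recording), 20 trees and windows of 16 and 1 — sizes chosen so a full
reproduction completes in about a minute on a single CPU while every
class still has hundreds of test windows per fold.  Window vectors are
stored as float32; coordinates and state are float64.  CSV serialization
uses six decimal places, so I/O round trips are exact to 1e-6.
Probability rows are validated to sum to 1 within 1e-9; rotation matrices
are orthonormal to 1e-12.  Argmax ties (possible with few trees) break
deterministically to the first class in model order and are flagged.

## Known limitations

- Only step-1 sliding windows and raw coordinates; no engineered
  kinematic features (velocities, joint angles) or smoothing filters.
- One animal per track; no identity handling.
- The tuple-threshold rule is pairwise and one-shot per frame; chained
  reassignment is intentionally not performed.
- The random forest treats window positions as unordered features; it
  exploits temporal structure only through axis-aligned splits, which is
  exactly why fast oscillatory behaviors remain its weak spot.
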