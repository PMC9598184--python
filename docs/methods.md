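# Methods

`msfgait` implements a complete multisegment-foot (MSF) gait-analysis chain:
3-D marker trajectories → segment coordinate frames → relative Euler and
planar projection angles → event-anchored scalar features → SVM
classification of autism vs control gait under leave-one-out
cross-validation (LOOCV) → summed-rank model comparison → Shapley-based
feature-group importance.  Because clinical marker data of this kind are
rarely shareable, the package ships a first-class synthetic cohort generator
that defines the study conditions for every downstream test.

## Coordinate conventions and the rigid-segment model

Lab axes: X anterior (walking direction), Y left, Z up; ground plane Z = 0;
sagittal plane X–Z; transverse plane X–Y.  All angles are degrees, marker
coordinates millimetres, forces newtons.

The foot-shank complex is five rigid segments — shank (Sha), total foot
(Foot, the single-segment model), calcaneus (Cal), midfoot (Mid) and
metatarsus/forefoot (Met) — each carrying a marker cluster.  A segment frame
is built from a marker triad: origin at the triad centroid, z along the
triad-plane normal (winding fixed so z points up/proximal at the reference
pose), x along an anterior–posterior marker pair projected into the triad
plane, y = z × x.  The reported rotation is expressed relative to the frame
computed at the segment's stored reference pose, so the reference pose has
identity orientation and the construction is exactly equivariant under rigid
motion of the whole marker set.  Frame recipes (triad, AP pair, reference
geometry) are data, not code: real captures supply their own marker map.
Segment-frame conventions differ between laboratories; correctness here is
certified by exact synthetic round trips, not by matching any one published
convention.

Joint angles are the intrinsic x-y-z (Cardan) decomposition of
R_rel = R_proximalᵀ · R_distal for the five tracked pairs (Sha-Foot,
Sha-Cal, Cal-Mid, Cal-Met, Mid-Met): X = flexion/extension, Y =
adduction/abduction or inversion/eversion, Z = internal/external rotation.
The middle angle is confined to [−90°, 90°]; frames within 0.5° of the
gimbal singularity are logged, never clipped.  The decomposition is
implemented in closed form and cross-checked in tests against
`scipy.spatial.transform.Rotation` as an independent oracle.

Eight planar projection angles complement the Euler curves: F2G, S2G, V2G
(sagittal angle of the 1st/2nd/5th metatarsal shaft against the anterior
ground axis), S2F and S2V (transverse angles between metatarsal shafts),
F2Ps/F2Pt (sagittal/transverse first-metatarsal vs hallux phalanx), and MLA
(sagittal interior angle of the medial longitudinal arch at the navicular).
Projected angles are directed and reported in [0°, 180°].  Markers are
filtered (2nd-order zero-phase Butterworth, 8 Hz cut-off, forward–backward
pass so the effective order doubles and phase lag vanishes) *before*
projection.

## Gait events, normalization, pooling

Stance is gated by the vertical ground reaction force: heel-strike (HS) is
an upward crossing of a 20 N threshold (configurable; the value is a common
force-plate gating choice), toe-off (TO) a downward crossing, with 10 ms
debouncing and linear interpolation of the crossing instant between force
samples.  One cycle spans HS→HS; every channel is linearly resampled onto a
101-point 0–100 % grid and `stance_percent = 100·(TO−HS)/(HS′−HS)` marks
the stance/swing boundary.  Normalization is exact for piecewise-linear
curves.

Walking speed of a candidate cycle is the mean anterior velocity of a
reference (shank) marker over the cycle; the analysed cycle per participant
is the one closest to that participant's mean speed (ties → earliest).
Left/right symmetry is assessed per feature with a paired t-test; a
zero-variance paired difference is reported as p = 1 (no evidence of
asymmetry).  Asymmetric features are flagged and logged but pooling — the
mean of the two sides per participant — proceeds regardless; one pooled
sample per participant enters classification (n = 40 with the default
19/21 cohort), with a `sides="both"` switch for per-side samples.

## Feature schema

Per Euler channel: value at HS (the 0 % sample), value at TO (interpolated
at `stance_end`), full-cycle ROM, max/min during stance and swing, and the
times of those extrema in % cycle — 11 items × 15 channels = 165
rotational features.  Per planar channel: max/min during stance — 16
features.  Stance covers grid points ≤ `stance_end`; extremum ties resolve
to the earliest sample.  The schema is extensible (planar HS, ROM and
extremum times can be toggled on) and the realized counts are logged,
because published totals for pipelines of this kind depend on exactly these
toggles and are not always reconstructible; the counts here follow from the
schema arithmetic and nothing else.

Features are grouped by their source channel: the four MSF groups (Cal-Met,
Cal-Mid, Mid-Met, Sha-Cal), the SSF group (Sha-Foot), and the eight planar
groups.  Group combinations are enumerated by level (all subsets of size
1…4 of the five Euler groups, plus the MSF-combined and MSF+SSF sets and
the all-planar set).

## Classification and model comparison

Each feature-group combination × kernel (linear, RBF) defines a model.
Under LOOCV each sample is held out once; features are z-scored with the
training fold's statistics (SVMs are scale-sensitive; per-fold scaling
avoids leakage) and predictions are pooled into one confusion matrix.
Metric suite: accuracy, sensitivity, specificity, PPV, NPV, F1
(= 2TP/(2TP+FP+FN)), MCC (standard product-of-marginals form), and
trapezoidal AUC from the held-out decision scores.  Any 0/0 ratio is 0 —
so the degenerate all-control classifier on 19/21 scores accuracy 52.5 %,
sensitivity 0, specificity 1, PPV 0, F1 0, MCC 0, and NPV = TN/(TN+FN) =
52.5 %.  Mean ROC curves average TPR vertically on a fixed 101-point FPR
grid.

Forward feature selection is wrapper-based and greedy: the candidate whose
addition maximizes the (stratified 5-fold) CV score joins the subset;
selection stops when the best improvement stays below ε (default 10⁻³) for
`patience` (default 3) consecutive steps and the subset at the plateau
point is returned.  Two placements are supported: `paper` mode selects once
on the full table before LOOCV (optimistically biased, but the conventional
reporting choice this pipeline mirrors), `nested` mode would re-select
inside each fold; the mode is an explicit switch so the bias is visible,
never silent.  Hyper-parameter tuning is an inner 5-fold grid search over
C ∈ {0.01, 0.1, 1, 10, 100} and γ ∈ {scale, 0.001, 0.01, 0.1, 1}; ties go
to the smallest C, then the smallest γ.

Summed ranking compares models: each metric is midranked across models
(rank 1 = best), ranks are summed (SR), and the lowest SR wins; SR ties
resolve by higher accuracy, then name.  The ranking is invariant to metric
column order.

### A note on the LOOCV null

LOOCV carries an anti-learning bias: the held-out sample's class is
under-represented in its training fold, so on label-permuted data flexible
models predict the *other* class slightly more often than chance and the
pooled MCC is biased negative.  Measured on 40-sample noise tables over 50
seeds: RBF C=1 ≈ −0.09, linear C=1 ≈ −0.03, strongly regularized models
exactly 0 (pure majority prediction).  This is a property of LOOCV itself;
the sanity tests therefore exercise the linear kernel, and results from
flexible models on small cohorts should be read with this bias in mind.

## Shapley attribution

Players are features or whole feature groups.  Coalition values use
marginal feature removal: coordinates outside the coalition are replaced by
draws from a background set (the training table) and the model output is
averaged over draws.  Local scope attributes one sample's decision value
(positive → autism, negative → control) relative to the background-mean
base value; global scope is a loss decomposition,
v(S) = L(marginal prediction) − L(prediction with S present), averaged over
the table, with binary cross-entropy on the logistic transform of the SVM
decision value as the loss.  Retraining per coalition is not used; the
marginalized-input value function keeps one fitted model and makes the
attribution a statement about that model.

Exact Shapley values enumerate all 2^p coalitions (p ≤ 15 — the standard
grouping of 4 MSF + 1 SSF + 8 planar groups is 13 players, within reach);
a seeded permutation-sampling estimator with standard errors covers larger
player sets.  The estimators are verified against a full
permutation-average oracle and the efficiency/symmetry/dummy/additivity
axioms on randomized games.  Group reports sort by value (global) or
|value| (local); local waterfall rows carry signed direction and sum to
prediction − base.

## The synthetic cohort generator

The generator is the package's test bed and defines its study conditions:
19 autism / 21 control participants, one gait cycle each, markers at
100 Hz, GRF at 1000 Hz, stance fraction 0.60, walking speed
1.25 ± 0.28 m/s (autism) and 1.21 ± 0.16 m/s (control).

Every angle channel is an order-6 truncated Fourier series fitted (via a
periodic spline and FFT truncation) to hand-drawn keypoint templates of
typical gait curve shapes.  Per-participant variation = relative jitter of
the Fourier harmonics (SD 10 %), a constant offset (SD 1.5°), and a global
phase shift of at most 2 % of the cycle — producing between-participant
bands of a few degrees, the scale seen in pediatric multisegment-foot
reference data.  Group effects are offsets (optionally scalings) applied to
the autism group on named channels; the default places −5° on Mid-Met
eversion (Y) and +5° on Mid-Met internal rotation (Z) — roughly 2–3
between-participant SDs, i.e. a clearly detectable but not trivial effect,
chosen once as the generator's definition of the reported
midfoot–forefoot group difference.  A calibration mode additionally shifts
each participant's F2G curve so that the cohort's F2G max-in-stance values
are draws from the reported group distributions (autism 84.15 ± 15.29°,
control 91.38 ± 10.47°).

Two modes:

* **angles** — every channel an independent Fourier curve sampled straight
  onto the 101-point grid, plus i.i.d. measurement noise (SD 0.5°).  Used
  for classification/attribution studies: an effect configured on one
  channel stays confined to that channel.
* **markers** — a rigid forward model.  The calcaneus carries a whole-foot
  sagittal pitch curve (heel rise peaking near toe-off); Mid and Met hang
  off it through the free relative-angle curves; the shank and total foot
  are back-solved so every tracked pair matches its configured truth.
  Cal-Met is *derived* by composing Cal-Mid with Mid-Met, and planar truths
  are computed from the noise-free marker geometry — so the kinematics
  module round-trips the generator exactly (≈10⁻¹² deg at zero noise).
  Marker clouds ride rigidly on the segments with isotropic Gaussian noise
  (default SD 0.5 mm); in marker mode an F2G effect is a whole-foot pitch
  offset about the lab Y axis, which shifts the sagittal projection angle
  exactly.

The vertical GRF is a plateau plus two raised-cosine bumps (loading and
push-off), strictly positive on the open stance interval and zero outside,
with a small vertical step at the contact boundaries so threshold detection
is sample-accurate.  Only the vertical component is generated — events need
only thresholding.

What the generator does **not** emulate: soft-tissue artifact and marker
wobble correlated with motion, anatomical coupling between channels in
angle mode, kinetic realism of the GRF waveform beyond its double-bump
shape, subgroup structure within the autism group (e.g. hypotonia), and
multi-trial within-participant variability (one cycle per participant by
default).  Passing tests therefore demonstrate that the *pipeline* is
correct and that the configured effects are recoverable — not that real
autism gait is classifiable at any particular accuracy.

## Numerical choices and degenerate inputs

* Rotation matrices are validated to RᵀR = I, det +1 within 1e-9 by
  construction (cross products of unit vectors).
* `arcsin`/`arccos` arguments are clipped to [−1, 1] to absorb float error.
* Collinear triads, zero-length projections, missing markers (NaN), empty
  GRF traces, one-class label vectors, and sub-minimal cohorts raise typed
  errors naming the offending marker/frame/channel.
* All randomness flows from explicit seeds (`numpy.random.Generator`;
  cohort-level `SeedSequence.spawn` per participant), so identical
  configuration + seed reproduces a cohort bit-for-bit.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script study sizes are the package's default
experimental design: 40-sample cohorts (19/21) for classification checks,
50 seeded replicates for the MSF-vs-SSF ordering and the permutation null,
20 replicates for the Shapley group-ranking study, 150 participants per
group for calibration means, and 4 zero-noise trials for kinematic round
trips.  Fractions of replicates and Monte-Carlo means at these sizes have
sampling error of a few percent, which the stated tolerances reflect.
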