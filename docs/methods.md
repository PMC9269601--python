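# Methods

## Data model and exclusion rule

A trial is three aligned per-sample sequences — gaze x, gaze y (screen
pixels, origin top-left, y downward) and an event status label in
{FIXATION, SACCADE, BLINK} — plus subject id, group label, color
configuration token, trial id and sampling rate (default 60 samples/s, a
per-trial field rather than a global constant).  Blink/missing samples
carry NaN coordinates, never zeros.  Event labels are taken as given
(tracker-labeled); the package deliberately performs no velocity- or
dispersion-based event detection.

Trials shorter than 5 s total duration are excluded before any analysis.
"Reading time" for this rule is total trial duration (sample count /
sampling rate), not active reading time, because it is defined for every
trial including heavy-blink ones; the boundary case (exactly 5 s) is
retained.

## Scalar features

Counts are numbers of maximal FIXATION/SACCADE runs; durations are sums of
run lengths over the sampling rate.  Conventions chosen so every retained
trial has a complete vector:

- *frequency* = count / **total** reading time (always positive after the
  exclusion filter; active reading time would also have been defensible but
  can only differ by the blink fraction);
- averages over an absent event kind are 0, not undefined;
- inter-saccade intervals are **onset-to-onset** (well defined even for
  adjacent saccade runs, unlike end-to-start);
- standard deviations are population-form (divisor = number of values);
  fewer than two intervals yields 0.

Active reading time is (fixation + saccade samples)/rate, so it always
equals fixation-total + saccade-total duration, and equals total reading
time exactly when the trial has no blinks.

## Self-intersection counting

FI_j counts unordered pairs of non-adjacent polyline segments whose
*closed* segments intersect.  Adjacent pairs always share a vertex and are
excluded entirely; non-adjacent pairs touching at a point count 1; a
collinear overlap counts 1 per pair (not per contact point).  The predicate
is the standard orientation/on-segment test with an absolute tolerance of
1e-9 on cross products; on pixel-scale integer-valued data the arithmetic
is effectively exact.  Pair counting (rather than counting distinct
intersection points) was chosen because it is deterministic, O(m²)
oracle-checkable, and insensitive to coincident crossings.  Fixations with
fewer than 4 samples have no non-adjacent pair and contribute FI_j = 0;
they still count toward n.

## Box-counting fractal dimension

FD_j is estimated on the figure drawn by the fixation polyline:

1. anchor a grid at the bounding-box top-left; base scale
   S = max(width, height, 4) px, padded up to 16 px so the ladder always
   has at least three scales;
2. dyadic ladder s = S/2, S/4, … down to max(2 px, S/64) — between three
   and six scales;
3. densify the polyline to ≤ 0.5 px point spacing (so thin diagonal lines
   cannot skip boxes), quantized to 1e-6 px so binning is immune to
   last-bit float jitter under rigid translation;
4. count occupied boxes N(s) at each scale; FD is the OLS slope of log N(s)
   against log(1/s) over the whole ladder, with no scale pruning.

Degenerate polylines (fewer than two distinct points) take FD = 0 and are
included in the trial mean; estimates are clipped to [0, 2.2] to bound
estimator overshoot.  The estimator lands within [0.9, 1.1] on straight
lines and [1.8, 2.05] on a 2-px boustrophedon filling a 128-px square
(asserted in the suite).

## Visualization

Scanpaths are drawn one line per consecutive sample pair: jet color at
min(length, 200 px)/200 (200 px being the intended maximal within-line
saccade length; longer line-sweep saccades clip to the top color), solid
for fixation-fixation pairs and dashed for any pair touching a saccade
sample, nothing for pairs touching a blink, red stars at the last/first
valid gaze points around each blink, y axis inverted to screen
orientation.  Opacity decays with the sample index t of the earlier point
as `0.9 − 0.8·min(1, t/(MRT·Ts))` with MRT = 40 s and Ts = 60 Hz by
default, i.e. linearly from 0.9 down to 0.1 at the maximum reading time;
the formula is implemented exactly as stated even though a full 1-to-0
ramp might look more natural.

## Classification protocol

Folds are subjects (leave-one-subject-out), so identity cannot leak from
train to test.  Each fold standardizes the training matrix to mean 0 and
population standard deviation 1 (zero-variance columns centered only) and
applies the same parameters to the test matrix.  Classifiers are pinned:
LR (l2, C = 1, lbfgs, 100 iterations), SVC (C = 1, RBF, probability
calibration on), KNN (k = 5, Euclidean), RF (100 trees, Gini, no depth
limit, all features per split, bootstrap).  One seed controls SVC
calibration and RF bootstraps.  Predictions and P(dyslexic) are pooled over
all test folds before computing ACC/Se/Sp/F1/AUROC, with dyslexic as the
positive class (sensitivity-to-dyslexia is the screening-relevant
direction).  For KNN and RF the positive-class probability is the
neighbor/tree vote fraction.  Feature ranking uses mean decrease in
impurity from a random forest fit on the full standardized table.

## Statistical analysis

One value per subject per color (each subject reads each color once; if
replicates ever occur the mean is taken).  Per color, dyslexic vs control:
two-sided Mann–Whitney U (exact null when both groups ≤ 20 and tie-free,
tie-corrected normal approximation otherwise) and Levene's test with
center = mean (the classical form; Brown–Forsythe via the
``levene_center`` argument).  Within the dyslexic group, every unordered
color pair gets a two-sided Wilcoxon signed-rank on subjects having both
trials, zero differences dropped, exact sign-flip null when ≤ 25 nonzero
differences remain.  Cells with an empty group, fewer than two usable
pairs, or all-zero differences are flagged not-computable rather than
raising.  No multiple-testing correction is applied by default (raw
thresholds are the reporting convention here); Holm adjustment is available
explicitly.

## Synthetic gaze generator

The generator emulates the study structure end to end: 15 control + 15
dyslexic subjects, 13 color-configuration tokens, one trial per
subject × color, 60 Hz, a 40 s reading-time cap.  A trial walks word
anchors across 6 text lines of 8 words (left to right, wrapping, with
occasional two-word regressions), placing at each word a fixation whose
trace is a bounded direction-persistent random walk, bridged by 2–4-sample
saccades; blink gaps arrive as a Poisson process (3/min, 0.2 s) and blank
the covered samples.  Lognormal per-subject effects (σ = 0.15) scale jitter
and dwell, inducing within-subject correlation across colors.

The class contrast in the default profile lives **only** in the fixation
complexity dials: control jitter 0.6 px/sample with reversal probability
0.08 vs dyslexic 2.2 px and 0.45.  Larger, more frequently reversing steps
fold the trace over itself, which is exactly what FIC/FIV/FFD measure, so
the generator has an interpretable monotone link to the features it is
meant to exercise.  Dwell means (0.25 s), dwell/interval variability,
regression rate and blink behavior are equal across groups by default —
temporal and count features carry *no* class signal — though every dial is
settable per group.  Colors never modulate behavior, so color-pair
comparisons are null by construction.

What passing tests therefore show: the feature estimators, the LOOCV
protocol, the ranking and the statistics behave correctly on data with a
known, isolated complexity contrast.  What they do not show: that real
dyslexic gaze separates this cleanly.  Real recordings mix complexity
differences with slower reading, more regressions and device noise; the
perfect synthetic accuracies are a property of the isolated contrast, not a
clinical claim.  The generator also makes no attempt at oculomotor realism
(no main-sequence saccade dynamics, word-frequency effects or calibration
drift).

## Problem sizes used in the checks

The end-to-end checks run the full default study (390 trials) over 10
seeds; geometry-oracle equivalence uses 1,000 random 50-point polylines;
the null-calibration check uses 10,000 replicates of a 6 + 6 exact
Mann–Whitney test.  Unit tests run on reduced studies (e.g. 8 subjects × 3
colors) chosen to exercise the same code paths at a fraction of the cost.

## Known limitations

- Event labels are consumed, not detected; recordings lacking a status
  channel need upstream event detection.
- The intersection-count convention (pairs, closed segments) and the
  box-counting ladder are declared package conventions; other reasonable
  conventions would shift absolute feature values, though not the group
  ordering on data like the generator's.
- With ~50 fixations per trial the per-trial FIC/FFD means are stable, but
  very short trials (just past the 5 s filter) estimate them from few
  fixations and are noisier.
- LR uses the pinned 100-iteration budget; on pathological inputs it may
  stop short of convergence (warnings are suppressed inside the
  cross-validation loop by design).
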