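# Methods

`ethoacc` classifies the behavior of grazing cattle from collar-mounted
tri-axial accelerometers, and ships a synthetic collar-data generator so
the full pipeline — ingestion, cleaning, feature extraction,
classification, and the two central experiments (smoothing-window sweep
and data-reduction bootstrap) — is testable end to end without any
field data.

## Sensor model and conventions

The collar records acceleration at 40 Hz on three axes with **+X
forward, +Y right, +Z down**, so an upright, motionless animal reads
+1 g on Z.  This convention is not consistent across the biologging
literature, so it is fixed in `ethoacc.core` and assumed by both the
generator and the signal-verification rules.  Magnetometry (10 Hz,
arbitrary units) and GPS fixes (15-min interval) are optional side
channels.

Behavior observations form *bouts*: half-open intervals
`[start_utc, end_utc)` labeled with one of five ethogram behaviors
(grazing, walking, resting, ruminating, grooming) and an observation
source (`in_pasture`, a continuous 1-s stream, or `collar_video`, 15-s
clips recorded hourly).  Epochs are integer UTC seconds; a second is
labeled only when it is wholly contained in a bout, so bout boundaries
never double-label.

## Synthetic data generator

### Bout schedule

Behavior sequences are a semi-Markov renewal process: bout durations
are exponential with per-behavior means, behaviors drawn i.i.d. with
probability proportional to `target_proportion / mean_bout_duration`.
By the renewal-reward theorem the long-run *time share* of each
behavior then converges to its target proportion.  Defaults:

| behavior   | time share | mean bout (s) |
|------------|-----------:|--------------:|
| resting    | 0.355      | 120 |
| grazing    | 0.335      | 300 |
| ruminating | 0.215      | 120 |
| walking    | 0.094      | 30  |
| grooming   | 0.001      | 15  |

The shares mirror a cleaned field observation set from extensively
grazed steers; the bout means encode long grazing meals, short walking
transits, and rare, brief grooming.  Grooming's tiny share makes the
rare-class fragility seen in data-reduction experiments reproducible.

### Signal signatures

Per sample, acceleration is the 1 g gravity vector rotated by the
bout's *pitch* about the Y axis (head-down angle), plus a per-axis
sinusoid (gait or chewing rhythm), plus i.i.d. Gaussian noise
(broadband movement energy):

| behavior   | pitch (°) | freq (Hz) | amp (g) | noise sd (g) |
|------------|----------:|----------:|--------:|-------------:|
| grazing    | 90 | 1.0 | 0.15 | 0.25 |
| walking    | 0  | 1.8 | 0.30 | 0.15 |
| resting    | 0  | –   | 0    | 0.05 |
| ruminating | 0  | 1.0 | 0.04 | 0.05 |
| grooming   | 30 | 3.0 | 0.10 | 0.20 |

Grazing's 90° pitch transfers gravity from Z to X (the head-down
posture), with high noise for the biting and tearing of forage.  No
quantitative amplitudes exist to copy, so the defaults are calibrated
once to reproduce the *qualitative* structure of the real signals:
clear grazing/walking separation at any window, and a
resting/ruminating distinction that a 1-s window genuinely
under-resolves.  The last point is why ruminating's chewing amplitude
(0.04 g) sits below the resting noise floor (0.05 g): a 40-sample
standard-deviation estimate of the difference is too noisy at 1 s and
sharp at 10 s, which is the mechanism that makes longer smoothing
windows pay off and gives the accuracy-vs-window curve its plateau
shape (≈ 0.92 at 1 s rising to ≈ 0.99 from 5–10 s on).

Bout transitions cosine-blend the pitch angle, sinusoid and noise level
over 0.5 s.  Blending the *angle* (not the gravity vectors) keeps the
noise-free trace exactly on the unit gravity sphere, so the
pure-gravity norm invariant holds through transitions; the ramp also
prevents step discontinuities that would make classification
artificially easy.

Magnetometry is a yaw random walk (per-behavior rate, deg/√s scaling so
Var[yaw(T)] = rate²·T) projecting a fixed earth field; GPS is a
persistence-0.7 correlated random walk reflected at the pasture
rectangle.  `corrupt_signal` injects three known field artifacts (clock
drift, axis flips, collar spin) for testing the verification rules.

### What the generator does *not* emulate

Real collar data have postural diversity within behaviors, non-Gaussian
and autocorrelated noise, drifting collar fit, diurnal structure, and
observer labeling error.  The synthetic task is therefore easier than
the field task; passing tests show the *pipeline* is correct and that
its qualitative orderings (window plateau, learning-curve asymptote,
rare-class fragility) emerge from the stated mechanisms — not that the
specific accuracies transfer to real deployments.

## Cleaning rules

* **Mixed video clips**: any 15-s collar-video clip containing more
  than one behavior is removed whole (time-sync ambiguity).  Without
  explicit clip ids, each maximal contiguous run of collar-video bouts
  is treated as one clip.
* **Signal verification**: the field practice of visually discarding
  bouts whose signal contradicts the label is replaced by reproducible
  rule-based flags: grazing epochs whose 10-s static-X mean is below
  0.3 g (head not down) and resting epochs whose 10-s VeDBA mean
  exceeds 0.2 g (not quiescent).  Thresholds are configurable and the
  rules can be disabled.
* **GPS join**: each bout takes the fix nearest its midpoint; exact
  ties go to the earlier fix (arbitrary but fixed).
* **Percentages** in ethogram summaries are rounded half-away-from-zero
  at one decimal, matching the reporting style of field summaries.

## Features

For a window of `w` seconds (1–60) and trailing alignment, the epoch
labeled second `s` summarizes the `40·w` samples in `[s+1−w, s+1)` —
a causal window ending with the epoch's own second (centered alignment
is available).  Partial edge windows are dropped so every row is
comparable; hence a frame of `D` seconds yields `D − w + 1` epochs.

Static acceleration is a 2-s centered running mean per axis (edges
shrink to available samples); dynamic = raw − static exactly.  ODBA is
the L1 norm and VeDBA the L2 norm of the dynamic vector, bounded as
VeDBA ≤ ODBA ≤ √3·VeDBA.  Per epoch the table carries the raw-axis
snapshot, mean/median/sd/min/max per axis, the dynamic snapshot,
instantaneous ODBA/VeDBA plus their five window statistics (33 feature
columns; 51 with magnetometry).  Standard deviations are **population**
(divisor N) statistics, pinned by the brute-force oracle tests.
Zero-phase Butterworth filtering (default order 2, 0.3 Hz — neither is
prescribed anywhere, so they are package defaults) is available for
static/dynamic density inspection but off by default in the feature
set, since it duplicates the running-mean decomposition.

## Classifier and metrics

The learner is a random forest (scikit-learn), default 500 trees,
√p features per split, unlimited depth, exposed through a
Model/Results pair: `BehaviorClassifier(table).fit(seed)` returns a
results object with predictions, feature importances, persistence and a
`summary()`.  The 70/30 split is stratified by (animal, label) with the
per-stratum train share within one row of 70%; singleton strata fall
back to a global draw with a warning.  Because per-second splitting
places temporally adjacent epochs on both sides, accuracies are
optimistic relative to animal- or bout-blocked evaluation; the split is
kept because it matches the procedure being reproduced, and bout-level
blocking can be layered on by callers via the schedule.

From the confusion matrix (rows true, columns predicted):
accuracy = trace/total; per class, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP).  A class absent from
the truth or the predictions reports `None` (undefined), never 0.

## Experiments and problem sizes

The default synthetic study is 8 animals × 2,500 s ≈ 20,000 labeled
epochs.  The window sweep re-extracts features at windows
{1, 2, 5, 10, 15, 20, 30, 60} s and refits per window; `plateau_detect`
returns the smallest window within 1% (relative) of the curve maximum —
the "~optimal window" has no sharper published criterion, so the 1%
rule is the package's own.  The data-reduction experiment retains, per
(animal, behavior) cell, `round(p·n)` rows (half-up) without
replacement — preserving each animal's behavior composition — and
bootstraps B replicates per proportion, reporting mean, sd and standard
error (plots ribbon the sd).  Desk-scale defaults are a
{1, 5, 10, 25, 50, 75, 100}% grid with B = 25; the full 1–100% × B=100
grid is a parameter away.  The experiment loops default to 100-tree
forests: on these well-separated features the forest error is flat well
past 50 trees, and the sweep alone fits 160 forests, so the 500-tree
default is reserved for single fits.  Source comparison down-samples
the larger observation source to the smaller's per-behavior counts
before fitting per source, so volume never confounds the comparison.

All experiment outputs carry the seed and a config hash; every
generator, split, fit and subsample is deterministic given its seed.

## Known limitations

* Synthetic realism as above; absolute accuracies are ceiling-ish.
* `structured_subsample`'s half-up rounding drops cells with
  `p·n < 0.5`, so extremely rare classes vanish at small p — which is
  precisely the rare-class fragility the reduction experiment measures.
* No significance testing between curves; the replicate tables are
  persisted so callers can apply their own.
* Magnetometer features are implemented but no claim is made that they
  help; they default to off in the study pipeline.
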