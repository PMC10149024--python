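# Methods

This note documents the models, assumptions, parameter choices and
known limitations of `scigait`.  Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and conventions

Global frame: x forward, y lateral, z vertical (up), gravity
g = 9.80665 m/s².  The accelerometer measures specific force (movement
acceleration plus the reaction to gravity) in a sensor frame whose
sagittal tilt follows the shank; the gyroscope measures angular
velocity in the same frame.  Canonical units everywhere are SI (s, m,
m/s², rad/s); percent-valued features are stored as percent.

Because straps rotate and mounting is never guaranteed, the sagittal
channel ω_z is chosen as the gyro axis with the largest variance during
walking, and its sign convention (positive during forward swing) is
resolved from the data: after low-pass filtering at 2.5× the stride
frequency the broad swing lobe dominates the sharp contact reversals,
so the sign of the dominant extremum gives the polarity.  This replaces
a "median peak polarity" rule, which is ambiguous whenever the contact
reversals are deeper than the swing peak (typical for slow walkers).

## Event detection

* **Cadence.**  FFT (Hann window, 4× zero padding) of ω_z with rest
  periods excised; the stride rate is the lowest prominent spectral
  peak (height ≥ 35 % of the band maximum, prominence ≥ 10 %) in the
  physiological band 0.3–1.5 Hz — the *first main* component.  Taking
  the global maximum instead would double the cadence of slow walkers,
  whose second harmonic carries more energy than the fundamental.
* **Mid-swing peaks.**  Local maxima of ω_z, minimum separation 0.6×
  the stride period, adaptive minimum height
  max(0.2 × 95th percentile of |ω_z|, 0.5 rad/s).  The percentile
  scaling keeps the threshold meaningful from shuffling to brisk gait;
  the floor rejects idle noise.  Ties resolve to the earliest sample.
* **Contacts.**  Within windows of 0.35× the stride period, the initial
  contact (IC) is the ω_z minimum after each mid-swing peak and the
  final contact (FC) the minimum before it.  An accelerometer-magnitude
  peak within ±50 ms corroborates the IC as an existence check only;
  the gyro minimum keeps the event time (averaging the cues was found
  to let mid-swing deceleration peaks, not the landing impact, dominate
  the accel cue and bias the timing).
* **Rest segmentation.**  2 s moving variance of ω_z below
  0.01 (rad/s)².  Strides whose duration exceeds 2.5× the cadence
  period are treated as spanning a rest and excluded.

Temporal parameters per stride (consecutive same-side ICs): duration;
step duration to the contralateral IC; swing % = (IC − preceding
FC)/stride; double support % = total time both feet are grounded within
the stride, from the intersection of the two sides' stance intervals.

## Orientation and trajectory

A complementary filter integrates the gyroscope (strapdown, per-sample
rotation vectors) and pulls the tilt toward the accelerometer's gravity
direction with gain 0.01 per sample at 200 Hz (≈0.5 s time constant).
The correction is applied only when ‖accel‖ is within ±0.5 m/s² of 1 g:
during impacts and mid-swing the accelerometer does not point along
gravity and would corrupt the estimate.  Heading is unobservable
without a magnetometer and left free.

Per stride (between consecutive mid-stance instants, each the minimum
gyro norm within a stance):

1. rotate specific force to the global frame, subtract gravity;
2. trapezoidal integration to velocity; zero-velocity update at both
   anchors by removing the linear velocity drift;
3. trapezoidal integration to displacement; for level walking both
   anchors are on the ground, so the residual net vertical displacement
   is drift and its linear ramp is removed as well;
4. rotate the horizontal plane so the net displacement defines the
   forward axis (per stride, which tolerates hallway turns);
5. read off stride length (net horizontal displacement), height (max
   vertical) and width (max |lateral|).

Strides with net displacement < 0.2 m are flagged as probable turns and
excluded from spatial statistics (configurable).  Walking speed is
stride length / stride duration; distance is the sum of one foot's
stride lengths, so rest time adds elapsed time but no distance.

## Features

* **cov** uses the sample standard deviation (ddof = 1).
* **asym** is computed for all base parameters except stride length,
  whose left/right means coincide by construction of the stride.
* **d2r** uses a piecewise-linear interpolant of control values over
  speed (ties averaged, queries clamped to the control range and
  flagged); the lookup speed is the trial mean stride speed.
* **Cyclograms** are resampled to 100 points uniformly in normalised
  stride time, anchored at the stride start, centred at the centroid
  and scaled to unit RMS radius.  SSD is the summed squared pointwise
  difference to the reference shape; area is the absolute shoelace
  polygon area (reported for both the normalised and the raw-scale
  shape — both conventions exist in the literature).  ACC computes per
  normalised-time segment the circular mean resultant length of the
  segment direction across cycles, averaged over segments.  Segments
  shorter than 5 % of a cycle's mean segment length are treated as
  zero-length and excluded: the ankle is nearly still through stance
  (~60 % of normalised time) and such segments' directions are
  integration residue, not movement.
* **Smoothness** is the modified spectral arc length of ω_z over the
  concatenated walking segments: magnitude spectrum normalised to its
  maximum, adaptive cutoff at the largest frequency ≤ 20 Hz with
  normalised magnitude ≥ 0.05, negated arc length over [0, cutoff]
  (always ≤ 0; closer to 0 is smoother).
* **Change metrics** are slope/intercept of an ordinary least-squares
  fit of speed, stride length and cadence against stride mid-times —
  a unit-free fractional change per second; speed inconsistency is
  |change in speed|.  They require ≥ 10 strides spanning ≥ 120 s.
* **Side rule.**  Side-specific parameters come from the more impaired
  side (lower per-leg LEMS); right side for healthy controls and LEMS
  ties; asym always uses both sides.

## Cluster discovery

Features are standardised (zero mean, unit sd; constant features
dropped with a warning).  PCs are retained until the cumulative
explained variance reaches 0.65 (configurable).  k is chosen on the
Ward dendrogram: the k whose merge down to k−1 clusters is highest
relative to the preceding merge (ties to the smaller k) — the merge
height criterion is the natural reading of a dendrogram elbow.  K-means
(50 restarts, fixed seed) partitions the retained PC scores; labels are
re-indexed by decreasing cluster-mean 6MWT distance.  Core features:
top-5 |loading| per retained PC (absolute loadings — sign carries no
importance information), Kruskal–Wallis filter at α = 0.05, and of each
pair with |Pearson r| > 0.9 the larger-p member is dropped.  Group
comparisons: Kruskal–Wallis for continuous variables, Fisher's exact
test for categorical (exact 2×2, seeded Monte-Carlo conditional-on-
margins beyond), Dunn's post-hoc z with tie correction, reported
unadjusted (α = 0.05 with no correction) alongside a Holm-adjusted
column for transparency.  Missing feature values drop the trial
(median imputation available as an option).

## Improvement prediction

One observation per consecutive assessment pair; the label is a strict
Δdistance > 16.5 m (the 6MWT standard error of measurement for this
population — "more than the SEM" reads as strict).  Subjects whose
first assessment falls after day 365 are shifted so it sits at day 365
(chronic phase).  Feature set 1 = {present 6MWT distance, days since
injury, days until next assessment}; set 2 adds all gait parameters.
The classifier is a random forest (500 trees, unlimited depth, fixed
seed — defaults chosen in the absence of any canonical values, exposed
in `PredictionConfig`).  Evaluation is leave-one-subject-out;
standardisation, |r| > 0.9 redundancy removal and top-10
importance-based selection are refit inside every training fold by
default so nothing leaks from the held-out subject (a flag restores the
simpler whole-dataset variant).  Training rows are put in a canonical
order per fold so results do not depend on how the caller ordered
observations.  A fold with a single-class training set predicts the
majority class and is logged.  Accuracy is (TP+TN)/N; confusion
matrices are reported absolute and row-normalised.

## The synthetic-data generator

`simulate_trial` builds each stride's endpoint path analytically:
forward motion follows a minimum-jerk profile over the swing, vertical
and lateral excursions are sin² bumps peaking at the planted height and
width, and the foot is exactly still through stance, so ZUPT anchors
are valid by construction.  The sagittal angular velocity is one broad
sin² forward lobe per swing plus Gaussian reversal dips (σ = 50 ms) at
the two contacts, sized so the net shank rotation per stride is zero.
The accelerometer is the analytic second derivative of the path
expressed in the tilting sensor frame plus gravity and white noise; the
gyroscope is the shank rate plus a constant bias and white noise.
Stride-to-stride variability is lognormal multipliers on duration and
length (positive by construction, cov directly controllable); speed
drift scales stride length linearly in time; rest breaks freeze both
feet; an optional constant mounting rotation about the shank axis
emulates an arbitrarily rotated strap.

Defaults describe an unremarkable ambulatory walker: stride 1.1 s /
1.2 m (≈1.1 m/s), height 0.12 m, width 0.05 m, swing 38 %, cov 3 %,
360 s trial.  For a periodic bipedal gait the double-support fraction
is kinematically tied to the swing fraction (1 − 2×swing, independent
of the left-right phase offset), so it is derived rather than a free
knob; supplying an inconsistent value is an error.  Noise defaults
(accel 0.1 m/s², gyro 0.05 rad/s) are typical MEMS figures.

What the generator does *not* emulate: musculoskeletal dynamics, foot
pitch during roll-over (the ankle path is purely translational between
contacts), soft-tissue artefact, turning arcs at hallway ends, or
pathological multi-peak ω_z morphologies.  Passing tests therefore show
that the pipeline is internally correct and robust to noise, bias,
strap rotation, speed and rest breaks — not that it is validated on
patient data.

`simulate_cohort_features` draws diagonal-covariance Gaussian clusters.
`simulate_longitudinal_cohort` gives each subject per-trial standard
normal gait features and 6MWT distances whose increments are
Δ = 16.5 + effect × (mean of the first three gait features) + N(0, 30 m);
with effect = 0 labels are chance-level and roughly balanced around the
SEM threshold, matching the repeat structure (10 subjects twice, 9
thrice, 4 four times → 40 observations).

## Numerical choices and degenerate inputs

* Quaternions follow scipy's scalar-last convention; unit norm is
  maintained to 1e−6.
* Sustained ‖accel‖ < 0.5 m/s² raises a free-fall/invalid-input error.
* Synchronisation resamples both sensors linearly onto a shared uniform
  200 Hz grid over the overlapping interval; < 30 s overlap is an
  error.
* cov with zero mean, asym with both sides zero, d2r with a zero
  reference, change metrics with a zero intercept: all raise rather
  than return infinities.
* Degenerate (all-zero) cyclogram shapes are excluded; fewer than 5
  cycles is an error for ACC.
* Ward/k-means ties: equal elbow scores take the smaller k; k-means
  restarts are seeded.

## Problem sizes

The test suite and acceptance script run on 60 s trials for unit-level
checks and full 360 s trials for end-to-end recovery; cohort analyses
use 60 trials (4×15) for clustering and the 23-subject / 40-observation
longitudinal structure for prediction, with 10-seed replications and
200-tree forests in the replicated cross-validation experiments.
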