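# Methods

## Problem setting

People with type 1 diabetes keep near-continuous self-records of blood
glucose, bolus insulin and carbohydrate intake.  Incipient infection raises
insulin resistance, producing a characteristic contextual anomaly: glucose
stays high *despite* more insulin and less food.  glysense operationalises
this as novelty detection in the plane spanned by the
insulin-to-carbohydrate ratio and the mean blood glucose per time bin.
Normal days of one person form a compact elliptical cloud there; infection
days shift up and to the right in both coordinates simultaneously.
Detection is strictly personal: every model is trained on one patient-year.

## Feature construction

* **Binning.**  Calendar days or clock hours (half-open bins).  The ratio
  is the ratio of bin totals, Σbolus/Σcarb, never a mean of per-event
  ratios; bins with zero carbohydrate or no glucose reading are marked
  missing rather than infinite.
* **Imputation.**  Linear interpolation per dimension, nearest-value fill
  at the series edges.  A series whose missing fraction exceeds
  `max_missing` is rejected as too sparse.  The default is 0.5; the hourly
  pipeline raises it to 0.95 because meals occupy only a few hours a day,
  so the hourly ratio dimension is inherently sparse and the interpolated
  values are exactly the between-meal carry-forward a clinician would
  expect.
* **Smoothing.**  Trailing (causal) moving average over 48 hours — 2
  samples daily, 48 hourly — so the pipeline remains usable prospectively.
  The first bins carry partial averages (the first sample passes through).
  Smoothing spreads an episode boundary into its neighbours: the first day
  after an episode is a *normal-labelled* day with a half-elevated feature
  value.  This contamination is intrinsic to causal smoothing and is why
  test-time scaling must not clip (next point).
* **Scaling.**  Min-max to [0, 1] per dimension.  `scale_minmax` applied
  with training-fold parameters clips to [0, 1], the conservative contract
  for external users.  Inside the evaluation protocol, however, the
  training-fold scaler is applied to test objects *without* clipping:
  min-max scaling exists to make the two dimensions commensurate, and
  clipping would project every excursion beyond the training range onto the
  box boundary — in the worst case exactly onto the (contaminated)
  training maximum, collapsing nearest-neighbour distances of infection
  days to zero.  This was observed, not hypothesised (1-NN AUC dropped from
  ~1.0 to 0.42 with clipping on).
* **Units.**  mg/dL internally; mmol/L input is converted by ×18.016 at
  ingestion.

## One-class models and threshold calibration

All models expose `fit` on target-only data and `score` with a uniform
orientation (higher = more anomalous; density models return negative
log-likelihood or Mahalanobis distance).  The decision threshold is the
empirical (1 − β)-order statistic of the training anomaly scores, so with
distinct scores exactly ⌊βn⌋ training objects are rejected; β = 0 rejects
nothing; the default β = 0.01.  When training points are scored for
calibration, the neighbour- and kernel-based models (K-NN, LOF, Parzen
family, NN-d) exclude the point from its own neighbourhood — otherwise the
1-NN training score is identically zero and calibration collapses.

The SVDD and one-class ν-SVM duals are box-constrained simplex QPs solved
by a hand-written SMO with second-order working-set selection and an
incrementally maintained gradient; the default stopping tolerance 1e-6 on
the KKT violation gives dual objectives accurate to ~1e-10 on the problem
sizes used here (tests compare against an independent SLSQP solve at
1e-6).  The incremental SVDD adds training points one at a time, re-solving
(warm-started) only when the newcomer violates the current KKT conditions;
since the dual is strictly convex for a Gaussian kernel on distinct points
it reaches the same optimum as the batch solver.  The Gaussian kernel is
K(a,b) = exp(−‖a−b‖²/σ²); the kernel width is the consistency-selected
hyperparameter.  For SVDD/ν-SVM the box is C = 1/(νn) with ν = 0.05 by
default, loose enough that the post-hoc β-quantile threshold, not C,
controls the rejection rate.

Model-specific notes: the MST description uses the *entire* minimum
spanning tree and scores distance to the nearest tree edge as a segment
(not vertex-only), so the tree's geometry is the domain.  The robust
Gaussian uses FastMCD with support fraction 0.75.  The mixture uses full
covariances, 10 EM restarts, 200 iterations, tolerance 1e-6.  K-means uses
k-means++ with 3 seeded restarts.  The SOM is a batch-trained 5×5
rectangular grid with a Gaussian neighbourhood shrinking linearly from half
the grid diagonal to 0.5 over 100 epochs.  The autoencoder is a
single-hidden-layer network (3 sigmoid units, linear readout) trained by
full-batch gradient descent with momentum on internally standardised
inputs, deterministically seeded — deliberately tiny for 2-D inputs.

## Hyperparameter selection

Most models go through **consistency selection**: candidates are ordered
from least to most complex (kernel width: smaller = more complex; neighbour
counts: smaller = more complex; cluster/component counts: larger = more
complex), each candidate's target-rejection rate is estimated by 5-fold CV
on the training targets with thresholds calibrated at β, and the most
complex candidate whose rate does not exceed β + √(β(1−β)/n) is chosen
(falling back to the least complex).  Default grids: σ ∈ {1.6 … 0.05} on
scaled data, k ∈ {min(25, n/2) … 1}, K-means k ∈ {2 … 10}, mixture
m ∈ {1 … 4}.  The Parzen family instead maximises the leave-one-out
log-likelihood over a 40-point log-spaced bandwidth grid (per dimension for
the naïve variant).  MST, NN-d, Gaussian, MCD-Gaussian, PCA (fixed 0.67
variance fraction), SOM and the autoencoder have no searched
hyperparameter.

LOO-ML bandwidths are known to undersmooth when the sample contains
near-duplicate points; on N(0,1) samples of n = 200 the selected bandwidth
tracks the Silverman rate within a factor of 3 for the large majority of
seeds but individual samples can fall below.

## Unsupervised detectors

Classical LOF and COF run on the complete dataset (no training phase), each
point excluded from its own neighbourhood; COF uses the set-based nearest
path with linearly decreasing chaining weights.  Defaults k = 30 (daily)
and k = 240 (hourly); the operating threshold T is a per-run parameter with
daily default 1.2, the sensitive end of the useful daily operating range
(≈1.2–2.4).  Because local sparsity is not illness, rare-but-normal
behavioural days (see quadrant scenarios below) exceed T while one-class
models trained with those days present accept them — the documented
false-alarm mode of the unsupervised route.

## Evaluation protocol

Target objects are split into 5 shuffled folds, repeated 20 times (fold
counts differ by at most one).  Each round trains on 4/5 of the target
objects only — optionally subsampled to 30/60/90/120 objects (1–4 months at
daily granularity; ×24 hourly) — with the scaler and all hyperparameters
fitted inside the training part.  The test set is the held-out target fold
plus the nontarget objects oversampled with replacement to the fold size
(every original nontarget object appears at least once; the nontarget set
is never trained on and is reused across folds).  Metrics, reported as
mean (SD) percentages over all rounds: AUC (rank statistic, ties half
credit, nontarget high); specificity — here the fraction of *nontarget*
objects correctly flagged, the convention used in this application area for
infection-day recall; F1 with the *target* class positive.  The asymmetry
is intentional and stated in the report header.  All randomness derives
from the run seed; identical configurations reproduce reports exactly.

The timing harness measures wall-clock train/test durations on synthetic
Gaussian data at 240–2880 objects; numbers are informational only.

## Synthetic patient-year generator

The generator emulates the *feature-level* statistics of real self-recorded
patient-years, not glucose physiology:

* Daily glucose level ~ Normal(120, 15) mg/dL with within-day AR(1)
  readings (φ = 0.7, stationary SD 18) at ~5 jittered finger-stick times;
* 4 meals/day at fixed times with jitter; carbs ~ Normal(50, 15) g
  (truncated); bolus = carbs × per-meal ratio (Normal(0.1, 0.02) U/g) ×
  lognormal(0.15) dosing noise;
* An infection episode applies a step change for its duration: +60 mg/dL
  glucose elevation, ×1.6 insulin demand, ×0.7 carb intake by default.
  Effect sizes are free simulation parameters (no published quantification
  exists); the defaults encode a clearly symptomatic episode.  Onset and
  offset are steps, not ramps.
* Quadrant scenarios rewrite single non-infection days to land in the
  rare-but-normal corners of the (ratio, BG) plane, anchored to the
  patient's own empirical quantiles (e.g. "insulin action": ratio at the
  95th percentile + 0.5 SD, glucose at the 10th percentile − 0.35 SD, with
  small day-to-day jitter).  The offsets were fixed once so the events are
  jointly rare (Mahalanobis radius ≈ 2.6–2.8 σ) yet inside a β = 0.01
  one-class boundary (≈3 σ) — the geometry that makes them false alarms for
  density-only detectors and non-events for one-class models.

What the generator does **not** emulate: glucose–insulin dynamics, CGM
sensor error, basal insulin (excluded from the ratio by definition),
weekday/seasonal structure, gradual onset, or record-keeping gaps beyond
random bin sparsity.  Passing tests on synthetic data therefore demonstrate
correctness and the qualitative orderings of the method, not clinical
performance on real self-recorded data.

## Numerical and problem-size choices

* Threshold order statistic uses strict-inequality rejection so β = 0
  rejects nothing; score ties are accepted as target.
* NN-d with a zero denominator scores 0 when the numerator is 0, else +∞.
* LOF/COF neighbourhoods contain exactly k points (index-order
  tie-break); on continuous data this coincides with the k-distance
  convention almost surely.
* The calibration acceptance check at n = 10,000 covers the density,
  reconstruction and NN-d models; the kernel-machine (SMO) models are
  exercised at the protocol's fold sizes (hundreds of objects), where they
  operate in practice, since calibration correctness is model-independent.
* Directional comparisons (smoothed vs raw) use 3×5 CV per condition over
  10 simulated years; the full 20×5 protocol is used for absolute
  detection claims.

## Known limitations

* Bivariate features only; CGM-derived features (rate of change,
  time-in-range) are out of scope.
* The hourly path leans heavily on imputation between meals; its ratio
  dimension is a step function between boluses.
* Consistency selection can legitimately choose k = 1 for neighbour
  models on clean data; combined with score clipping this is degenerate
  (hence no clipping in the protocol).
* The unsupervised threshold T is not auto-tuned; it is an operating
  choice.
* COF is O(n·k²) with a dense distance matrix — fine for patient-years
  (n ≤ 8,760), not for population-scale data.
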