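# Methods

This note records the modeling conventions, defaults and design choices
behind `persglu`, and what the synthetic cohort does and does not show.

## Data model and timing conventions

All timestamps are UTC epoch seconds; local clock time for circadian
features comes from a configurable timezone offset (default 0, i.e. the
cohort lives at UTC). The CGM defines a 5-minute epoch grid; wearable
epochs are half-open intervals `[a, a + 300 s)` phase-aligned to the
first glucose timestamp.

**Historical rule.** The feature row for the glucose reading at time
`t` may use data from 5 minutes to 24 hours before `t`. Writing
`c = t − 300 s`:

* per-epoch sensor summaries describe the last fully historical epoch
  `[c − 300, c)`;
* epoch-grid rollups (EDA peaks, activity bouts, 2-h accelerometry)
  cover the 24/12/288 epochs ending at `c`;
* food windows are `(t − w, c]` for `w ∈ {2 h, 8 h, 24 h}`, and the
  eating-event binary marks the interval `(t − 600, c]`;
* the wake-time feature is the estimate from the most recent *completed*
  day, carried forward. Assigning the current day's wake time would leak
  future data into early-morning rows, because the day's estimate needs
  the whole day's averages.

A reading is retained when at least 24 h of sensor data precede it
(`t − data_start ≥ 24 h`); the 24-h windows of the very first retained
rows are therefore clipped by up to 5 minutes at the recording start.
This makes a gap-free 10-day wear produce exactly 9 × 288 rows.

## Feature definitions

* **Summary statistics** (mean, sd, min, max, q1, q3, skew) per epoch
  for heart rate, accelerometry vector magnitude `√(x²+y²+z²)` (counts
  of 1/64 g), EDA and skin temperature. sd is the sample (n−1)
  estimator; quartiles use linear interpolation of order statistics;
  skew is the adjusted Fisher–Pearson coefficient, defined as 0 for a
  constant window (flat sensors should not propagate missingness);
  fewer than 2 samples → all seven missing.
* **EDA unique peaks**: local maxima with topographic prominence
  ≥ 0.3 µS after enforcing a minimum separation of 4 samples (1 s at
  4 Hz), computed per epoch (never on the whole trace, which would let
  future samples shape a past peak's prominence). Rolling 2-h total and
  per-epoch mean follow.
* **HRV** over the epoch's inter-beat intervals, in ms: mean, median,
  max, min, SDNN (sample sd), RMSSD (root mean square of successive
  differences), NN50 (successive differences > 50 ms) and
  pNN50 = NN50 / number of intervals. The pNN50 denominator is the
  interval count, not the difference count, so pNN50 ∈ [0, 1). Fewer
  than 2 intervals → the difference-based metrics are missing.
* **Activity bout**: epoch mean accelerometry vector magnitude *and*
  epoch mean heart rate both above the participant's expanding mean over
  all prior epochs; the first epoch is 0. "Prior average" is expanding
  (all history), not windowed.
* **Wake time**: per calendar day, an epoch is scored awake (1) unless
  at least two of {ACC mean, ACC sd, HR mean, HR sd} fall below their
  day averages; the 0/1 series is smoothed with a trailing 3-h rolling
  mean; the wake time is the earliest epoch whose smoothed first
  difference exceeds a slope threshold while the smoothed value 25 and
  75 minutes later both exceed the candidate's. The threshold default is
  0.02 per epoch: the trailing 36-epoch mean of a 0/1 series can change
  by at most 1/36 ≈ 0.028 per epoch, so any threshold above that can
  never fire; 0.02 sits just below the ceiling and, on a clean
  square-wave day, pins the detection to the step. Days with no
  qualifying epoch fall back to the previous day's estimate.
* **Food**: nutrient sums and eating-event counts over the three
  windows; event means divide the count by the window's epoch capacity
  (24/96/288).
* **Demographics/personalization**: biological sex (0 = female,
  1 = male), HbA1c (%), and the participant id as a learnable feature.

Missing cells are imputed per participant by forward fill then the
participant's column median (configurable; `none` disables). Forward
fill is causal; the median step only ever applies to cells with no
history at all.

## Excursion labels

μ and σ are computed over the reading's trailing 24-h window excluding
the reading itself, with the sample (n−1) sd, implemented with prefix
sums (O(n)). Boundary readings (exactly μ ± σ) are PersNorm — "within
one standard deviation" is read inclusively. Readings with fewer than
`min_history_points` (default 144 ≈ 12 h of a complete grid) prior
readings stay unlabeled and are excluded from classification. Labeling
is invariant to shifting the whole series by a constant and to positive
rescaling, since both thresholds transform with the data.

The per-class summary reports mean, sample sd, range, adjusted
Fisher–Pearson skewness, excess kurtosis, and the Kolmogorov–Smirnov
statistic against a normal distribution with the class's own fitted
mean and sd.

## Models

**Classification.** Undersampling to the minority class once, before
cross-validation. Repeated stratified k-fold (10 splits × 3 repeats,
seeded). Inside each fold: recursive feature elimination, one feature
per step, down to 20, ranked by tree impurity importance or absolute
coefficient; then a decision-tree classifier (library defaults: Gini,
unlimited depth) on the selected features. Metrics per fold: balanced
accuracy, weighted precision/recall/F1, and an R² on integer-coded
labels (PersLow 0, PersNorm 1, PersHigh 2) floored at zero — R² on a
categorical target is ill-posed, and the floor matches how such values
are conventionally reported. The logistic baseline runs at library
defaults on unscaled features; its optimizer regularly stops at the
iteration cap, which is part of what makes it a baseline, and the
warning is suppressed at the fit site.

**Regression.** Per fold: a random-forest regressor (default 1000
trees) ranks features by normalized impurity importance; features at or
above the 0.005 cutoff feed an XGBoost regressor with max depth 6, 100
estimators, learning rate 0.1 (all other hyperparameters at library
defaults). If nothing clears the cutoff the single best feature is
kept. The personalized model splits each participant's rows
chronologically at ⌈n/2⌉. Fold seeds are `seed + fold index`.
Predictions are unclipped by default; an optional [40, 400] mg/dL clip
exists in config. Cohort metrics average per-participant RMSE, MAPE and
accuracy = 100 − MAPE.

**Importance.** One random forest per LOPOCV training set; importances
(already normalized to sum to 1) are averaged across folds (sd with
n−1). Aggregation renormalizes by the total before converting to
percent, so each taxonomy axis sums to exactly 100. The feature → 
(category, source, engineering) mapping ships as a versioned YAML
(`persglu/data/feature_taxonomy.yaml`): summary statistics map to their
sensor's category, HRV and EDA peaks to stress, accelerometry summaries
and bout features to activity, wake time to circadian rhythm (wearable
source), demographics to user input, the id to the model itself.

## Synthetic cohort

The generator emulates the study design the analysis assumes: 16
participants (default), 8–10 days, the stated sampling rates, and ~42%
CGM wear gaps (≈1500 glucose points per participant). Glucose is
baseline + circadian sinusoid + Σ meal kernels + Σ activity dips +
AR(1) noise, clipped to [40, 300] mg/dL. The meal kernel is a unit-peak
log-normal impulse peaking 30 min after the meal with half-amplitude 90
min later, scaled by 0.8 mg/dL per g sugar + 0.3 mg/dL per g carbohydrate
— magnitudes chosen so a typical logged meal raises glucose by a
realistic 30–60 mg/dL. Activity bouts elevate heart rate (+30 bpm) and
accelerometry and depress glucose by a rectangular dip with exponential
recovery. EDA bursts are Gaussian bumps with prominence ~N(0.5, 0.1) µS
during waking hours. Streams are quantized to device-like resolutions
(integer accelerometer counts, 0.01-bpm heart rate, 0.001-µS EDA).
Sleep (23:00 to ~07:00, per-day jitter) quiets heart rate and
accelerometry so wake-time detection has signal. Inter-beat intervals
integrate the heart-rate phase with ~25 ms timing jitter, making the
HRV block non-degenerate.

Per-participant randomness is keyed by (seed, participant id, stage),
so a participant's data is unchanged by the cohort size and every run
is reproducible from one seed.

What the cohort does **not** contain: insulin kinetics, dawn
phenomenon, sensor drift or motion artifacts, meal-log omissions, or
inter-feature correlations beyond the planted causal paths. Passing
tests on it demonstrate that the pipeline recovers known planted
structure without lookahead leakage — not that the models would reach
any particular accuracy on clinical data.

## Problem sizes

Tests and the acceptance script run the effect-recovery cohort at 8
participants × 5 days with strong meal/activity effects, low AR(1)
noise and the study-like 42% gap fraction, and scale the selection
forests to 50 trees (20–30 for the smallest smoke configurations);
these are the package's chosen desk-scale problem sizes, and the
qualitative contracts (above-chance classification, tree ≥ logistic,
models beat naive baselines, food dominates importance) are stable
across seeds at this scale. The paper-faithful defaults (16 × 8–10
days, 1000-tree forests) remain the config defaults for full-scale
runs.

## Known limitations

* The wake-time detector assumes a single consolidated sleep period per
  day; shift-work or fragmented sleep would confuse the day-average
  criterion.
* The 70/30 holdout and the repeated CV stratify by class only, not by
  participant, so rows from one person appear on both sides of a split
  (as the protocol prescribes); the LOPOCV regression is the
  participant-disjoint evaluation.
* MAPE is undefined at zero glucose; the generator's clip at 40 mg/dL
  keeps it well-defined, but real data with dropouts coded as 0 must be
  cleaned first.
* Balancing by undersampling discards majority-class rows once, before
  CV; fold-internal rebalancing would use the data differently.
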