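# Methods

`coexp` implements a complete analysis chain for classifying a
firefighter's carbon-monoxide (CO) exposure level from heart rate (HR)
derived from a wearable single-lead ECG. Because the original field
recordings are private, the package pairs the analysis with a synthetic
generator that reproduces the statistical structure the analysis
assumes; this note records the models, the tunable parameters, the
numerical choices, and what the synthetic results do and do not show.

## Exposure levels

CO concentration (ppm) is binned instantaneously against occupational
exposure standards into four levels with lower-inclusive,
upper-exclusive bounds: L1 = [0, 25), L2 = [25, 200), L3 = [200, 400),
L4 = [400, ∞). The levels partition the non-negative axis, so every
reading maps to exactly one level. L4 is retained in code even though
the emulated campaign never reaches it; downstream stages operate on
the set of observed levels. No time-weighted-average or short-term
dose accumulation is performed — the standards supply bin edges only.

Each CO reading at tick `t_k` is taken to describe the just-elapsed
interval `[t_k, t_{k+1})` (last observation carried forward over the
60 s sensor cadence; the final reading covers one full cadence). Beats
outside CO coverage are dropped and counted in the log. LOCF was chosen
because an in-continuum gas sensor reports the interval it has just
integrated; the labeling is insensitive to this choice except within
one cadence tick of each level transition.

## ECG processing

* **Low-pass filter.** Butterworth low-pass at 40 Hz applied
  forward–backward (zero phase). The order is 6: applied in both
  directions this leaves ≈24 dB attenuation at 50 Hz, meeting the
  ≥20 dB suppression needed for mains interference, which a 4th-order
  zero-phase design (≈17 dB) does not. Passband components (QRS
  fundamentals < 30 Hz) pass within 1%.
* **Baseline wander.** Subtraction of a centered moving average,
  window 1.0 s — longer than one beat at 60 beats/min, much shorter
  than respiratory or motion drift. At the record edges the window
  shrinks to the valid overlap rather than padding, so no samples are
  fabricated. The sub-0.5 Hz band edge of the useful ECG band is
  realized by this subtraction rather than an explicit high-pass: the
  1 s average passes only sub-∼1 Hz content, and subtracting it
  removes the drift band while leaving the QRS intact.
* **R-peak detection.** Derivative–square–integrate (150 ms window)
  with an adaptive threshold at 30% of the 99th-percentile candidate
  energy, a 0.2 s refractory spacing, and refinement of each candidate
  to the local signal maximum within ±100 ms. On noise-free synthetic
  records every template R is found within ±2 samples with no spurious
  detections. A flat record returns an empty result with a warning
  (documented choice) so batch runs survive dead leads.
* **Heart rate.** `HR_i = 60 · rate / (R_{i+1} − R_i)` beats/min, one
  value per R-R interval, stamped at the closing peak. HR is treated
  per-beat throughout: campaign-scale totals (~28–33 k samples per
  ~5 h subject) are only consistent with per-beat values.

Quality-control limits: resting ceiling 100 beats/min and
intense-activity ceiling 0.70 × 220 = 154 beats/min, used to flag
out-of-range HR, not to filter it.

## Synthetic data generator

The generator emulates a three-subject, ~5 h-per-subject campaign:

* **CO profile** (per 60 s tick): tick counts per level are allocated
  from `level_shares` by largest remainder, so occupancy is exact at
  tick granularity. Default shares (0.8249, 0.1397, 0.0354, 0) follow
  the campaign's observed per-level sample proportions. Elevated ticks
  are grouped into burst episodes of nominally 900 s placed at random
  among baseline ticks; within a burst the concentration starts near
  the top of the episode's highest level and decays exponentially
  (rate 3/episode-length) with 2% jitter, clipped into the level's
  bin — a sharp excursion followed by clearance. Baseline is
  5 ± 1 ppm, clipped below 24 ppm; everything is capped at the 500 ppm
  sensor ceiling.
* **HR trajectory**: each beat starting inside tick k draws
  `Normal(hr_medians[level_k], hr_sd)` clipped to [40, 220]. Defaults
  `hr_medians = (110, 120, 128, 136)` sit inside the observed 100–154
  range and increase strictly with level — the structure the group
  comparison is designed to detect; `hr_sd = 8` beats/min is a
  realistic within-level spread for sustained heavy exertion. Neither
  value is a claim about the real data; both are configuration. A
  fixed block of draws is consumed per tick so output is bit-identical
  for a given seed regardless of beat counts.
* **ECG synthesis**: a Gaussian-sum PQRST template (R amplitude 1 mV,
  narrow Q/S flanks so the template maximum stays on the R center) is
  placed at R-times spaced `round(60 · rate / HR_i)` samples — the
  exact inverse of the HR equation — with optional 0.3 Hz sinusoidal
  drift and white noise for robustness tests.

What the generator does **not** emulate: heart-rate variability
spectra, ectopic beats, electrode artifacts, the exercise–HR
confound, or any causal CO→HR physiology beyond a level-dependent
median shift. Consequently, passing tests demonstrate that the
pipeline recovers structure of this simple kind faithfully and that
its arithmetic matches the published counts — not that the classifier
would reach the published accuracy on real recordings.

## Balancing and scaling

HR is min-max scaled to [0, 1] per subject (so subjects are
comparable), then minority levels are topped up to the majority count
with Gaussian noisy replicates: a source row drawn uniformly with
replacement, `N(0, noise_sd²)` added to its scaled HR, clipped to
[0, 1], flagged `is_replicate`. `noise_sd = 0.01` on the unit scale —
small enough to preserve class geometry, large enough to break ties.
Scaling precedes oversampling because the noise magnitude is only
interpretable on the common scale. Applied to the campaign's class
counts (76,667 / 12,987 / 3,291) this yields 76,667 per class and
230,001 total; the stratified 70/30 split of that balanced set gives
161,001 / 69,000 (train size = round of 0.7 × total, per-class floors
reconciled by largest remainder).

Oversampling **before** splitting lets replicates of one original land
on both sides of a split, which inflates hold-out estimates; the
pipeline therefore exposes both the faithful order (`mode="faithful"`,
the default) and a leakage-safe order (`mode="leakage_safe"`) that
splits originals first and re-oversamples inside each CV training
fold, evaluating on untouched originals.

## Statistics

* **Lilliefors normality screen**: Kolmogorov–Smirnov distance to a
  normal with estimated mean/sd; p-values from the standard
  approximation table (statsmodels backend) by default, or by seeded
  Monte Carlo (`method="mc"`, ≥10,000 replicates recommended).
* **Kruskal–Wallis** with midranks and tie correction; p from the
  χ²(k−1) approximation. Implemented in-package because the group mean
  ranks and tie terms feed the multiple comparison; it agrees with the
  standard library implementation to machine precision.
* **Independence combinations**: with three subjects, the three cyclic
  level→subject assignments ensure each level group is drawn from a
  different subject, keeping the three samples independent.
* **Multiple comparison** on mean ranks: pairwise studentized-range
  (Tukey–Kramer-type) tests with infinite df and tie-adjusted rank
  variance `V = N(N+1)/12 − Σ(t³−t)/(12(N−1))`; the interval on a rank
  difference excludes 0 exactly when p < α (α = 0.05 throughout). A
  Bonferroni variant is available behind a flag. Per-group display
  intervals use half-width `q_crit/2 · √(V/n_g)`, which makes
  "intervals disjoint" equivalent to pairwise significance for equal
  group sizes (approximate otherwise).
* **Box-plot summaries** use linear-interpolation quantiles and
  1.5 × IQR whiskers (whisker = most extreme point inside the fence),
  so they are reproducible bit for bit.

No parametric ANOVA branch exists: the protocol routes non-normal HR
to the rank test.

## Classification

An ensemble of 100 bootstrap-aggregated classification trees with
majority voting, fitted on the single scaled-HR predictor. With one
feature, per-split random predictor selection is a no-op, so the
random-forest implementation coincides with plain tree bagging; tree
depth is unlimited (no depth control is part of the protocol).
Evaluation: stratified, seeded 10-fold CV with the pooled out-of-fold
confusion matrix (pooling, not per-fold averaging, so the matrix total
equals the dataset size), and a stratified 70/30 hold-out evaluation.
Metrics per class: precision TP/(TP+FP), recall TP/(TP+FN), F1 their
harmonic mean, reported in percent with unweighted macro averages;
undefined metrics on empty classes are reported as 0 with a warning.
On a balanced evaluation set, accuracy equals macro recall exactly.

Adaptive boosting is exposed (library defaults) for method comparison;
random-undersampling boosting is not implemented and raises.

## Determinism and problem sizes

Every source of randomness flows from one master seed through a seed
sequence; reports embed the resolved configuration and derived seeds,
and a rerun with the same config reproduces the report bit-identically.

Test and acceptance runs use deliberately scaled problem sizes chosen
to exercise every code path at comfortable cost: 30–60 min synthetic
campaigns for pipeline runs (a 30 min campaign is the shortest in
which the rare L3 level still occupies a CO tick), 1,000 null
simulations at n = 500/group for the Kruskal–Wallis calibration,
20 seeded campaigns for the pairwise-significance rate, and 500 beats
per class for classifier sanity checks. Count arithmetic
(oversampling, splits, tabulation) runs at the full published sizes
since it is O(n) in cheap operations.

## Known limitations

* The synthetic CV/test accuracies (~50% for the default scenario's
  overlapping level distributions) are properties of the generator's
  noise level, not estimates of real-world performance; the published
  hold-out metrics cannot be reproduced without the original private
  recordings.
* Single-predictor classification ignores the exercise–HR confound;
  elevated HR from exertion alone is indistinguishable from CO-driven
  elevation by construction.
* The R-peak detector's adaptive threshold assumes reasonably uniform
  QRS amplitude, adequate for template-based synthetic data and clean
  wearable traces, not for severe arrhythmia or electrode pop.
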