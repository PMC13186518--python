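# Methods

This note documents the models, parameter choices and numerical conventions
behind `actiphen`, and what the synthetic cohort does and does not emulate.

## Analysis-day construction

An analysis day is a local midnight-to-midnight calendar window. The night's
sleep, and the morning log that rates it, are assigned to the calendar date
of waking (logs are completed each morning). A day is retained only if it

- holds exactly 24 h of epochs (2880 at 30 s) — a daylight-saving day has
  23 or 25 wall-clock hours and fails this;
- has off-wrist time strictly below 30% (the threshold itself excludes);
- has a sleep log for the waking date;
- is not the transition day or either of the 2 days after a time change;
- is neither the first nor the last study day, which are dropped
  unconditionally because circadian measures on them would rarely span a
  full window. A clean 7-day recording therefore retains days 2–6.

Timestamps are naive local wall-clock; offset changes are carried as
explicit `timezone_events` so the time-change rule can be applied without a
timezone database. Missing epochs are materialized as off-wrist zeros, which
keeps day windows rectangular and never changes the observed count sum.

## Sleep scoring

The proprietary scorer used with the original device is not reproducible, so
sleep/wake is scored by the open weighted-moving-window family: epoch *i* is
sleep when `Σ_k w_k · c_{i+k} < T`. Defaults: weights
`(0.04, 0.04, 0.2, 0.2, 2, 0.2, 0.2, 0.04, 0.04)` over ±2 min of 30-s
epochs, wake threshold `T = 40` ("medium"; low 20, high 80), zero-padded
edges. Sleep onset is the start of the first run of ≥10 consecutive scored
minutes, offset the end of the last; TST and WASO are counted between onset
and offset. Efficiency uses the full bed-to-rise interval as denominator
(vendor convention). Fragmentation is the movement index (% of interval
epochs with any activity) plus the immobility-fragmentation index (% of
immobile bouts lasting ≤1 min). Nights with no qualifying sleep run yield
missing metrics and their day rows are dropped with a logged reason.

All of these are configurable (`ScoringConfig`); downstream checks on this
module are deliberately property-based (planted-bout recovery, threshold
monotonicity, fragmentation extremality) rather than tied to any vendor's
output.

## Circadian features

- **Cosinor**: exact least squares on `[1, cos ωt, sin ωt]`, `ω = 2π/24`;
  amplitude `√(β²+γ²)`, acrophase `atan2(γ, β)/ω mod 24`. `R²` is clamped to
  0 for a constant day (SST = 0). Circadian rhythm strength is defined as
  this `R²` — the most common operationalization of rhythm robustness, and
  monotone in it.
- **IV** is computed on the day's 24 hourly means (the literature standard;
  a single day supplies only 24 hourly values); it is ≈0 for a smooth
  sinusoid and ≈2 in expectation for white noise, and undefined (missing)
  for a constant day.
- **IS** is mathematically a multi-day quantity; it is computed once per
  participant over the retained days' hourly profiles and broadcast to each
  of that participant's day rows. Fewer than 2 days → missing.
- **M10/L5** windows slide at epoch resolution and do not wrap midnight.
- Off-wrist epochs are excluded from feature computations rather than
  zero-filled (zeros would bias L5 and the cosinor trough downward); a day
  that passed the 30% QC rule loses at most a modest fraction of epochs.

## Feature selection

Within-person means (the "aggregated features") are scored by the one-way
two-group ANOVA F, equal to the squared pooled-variance t statistic.
Selection is greedy by descending F, rejecting any candidate whose |Pearson
r| with an already-accepted feature is ≥0.70, until 3 are accepted; ties in
F break lexicographically for determinism. Selection on the full sample
leaks label information into every fold by construction; this replicates the
small-sample design being studied, and a `selection_scope="within_fold"`
mode re-selects on each fold's training persons for an honest variant.

## LOSO model

Each fold holds out one participant's day rows. Per fold:

- a Yeo-Johnson power transform (λ per feature by maximum likelihood, then
  standardization) is fitted on training rows only and applied to the
  held-out rows; a config switch can pool train+test to replicate a
  potentially leaky variant. Constant columns get λ = 1 with a warning.
- hyperparameters are drawn at random (default 25 draws) from a small-data
  grid — depth {2,3,4}, learning rate {0.01,0.05,0.1,0.3}, rounds
  {25,50,100,200}, subsample {0.7,1.0}, column subsample {0.7,1.0}, min
  child weight {1,5} — and scored by day-level AUC under 3-fold
  participant-grouped, label-stratified inner CV, so tuning never sees
  within-person leakage.
- `base_score` is pinned at 0.5 rather than estimated from training labels.
  Estimating it imprints the training split's class prevalence on every
  prediction, and under leave-one-subject-out that prevalence is
  anticorrelated with the held-out label (one positive removed leaves a
  less-positive training set), which drags null-model AUC well below
  chance. With a fixed prior the trees must earn any class signal from the
  features. Even so, LOSO retains a mild pessimistic bias at n = 33 with 8
  positives; the permutation-null AUC sits slightly below 0.5.
- day probabilities for the held-out participant are averaged into one
  person-level probability. Folds whose training split is single-class are
  flagged invalid rather than scored.

A structural leakage guard verifies per fold that the held-out participant
contributed no training rows and exactly its own test rows.

## Evaluation

AUC uses the Mann–Whitney formulation with ties counted ½; its 95% CI is a
seeded percentile bootstrap over persons (2000 resamples; single-class
resamples redrawn). Confusion metrics threshold the person probability at
0.5 (inclusive); with no predicted positives, precision is reported missing
and F1 is 0 by convention. The bootstrap AUC comparison resamples persons
with replacement — jointly for participants the two models share — and
reports the two-sided `p = 2·min(P(Δ≤0), P(Δ≥0))` with the
`(count+1)/(iterations+1)` Monte-Carlo correction, so p is never exactly 0.

Attributions are exact TreeSHAP values queried from the boosted ensemble on
each fold's held-out (transformed) rows; local accuracy — attributions plus
base value equal the margin — is asserted to 1e-6 on every row. Information
gain is total split gain per feature, averaged over folds; unused features
get 0. Both summaries are reported in descending order.

## Discriminant-validity regressions

OLS of person-level predicted probabilities on the outcome flag (1/0), a
non-PTSD current-diagnosis flag (1 = present) and age in years, uncentered,
with an intercept; p-values from the t distribution with n − k − 1 df (not
the normal — n ≈ 33). Rank-deficient designs raise, naming the degenerate
term. The logistic regression of the outcome on averaged selected features
reports Nagelkerke
`R² = (1 − exp(2(L₀ − L₁)/n)) / (1 − exp(2L₀/n))`; detected separation is
flagged, the coefficients carry a warning, and R² is reported at its limit
of 1.

## Synthetic cohort

The generator emulates the study design: 33 participants (8 clinician
diagnoses), 7 days × 2880 epochs, nightly in-bed intervals around
23:00–07:00 with morning logs for waking days 2–7.

Per participant-day activity is `mesor + amplitude·cos(2π(t − φ)/24)`
(mesor ~ N(150, 20), amplitude ~ N(120, 15), φ ~ N(15 h, 1 h)) scaled by an
hour-level multiplicative modulation N(1, 0.35) and perturbed by AR(1) epoch
noise (coefficient 0.6 — chosen to put IV between its sinusoid (~0) and
white-noise (~2) extremes — innovation SD 60), clipped at 0. Inside the rest
interval, activity is replaced by a sleep process: sleep-onset latency
(8 min + person trait SD 8), wake bouts totalling a planted WASO
(20 min + person trait SD 10, night SD 6) placed in disjoint mid-night
blocks, and isolated low-count movement epochs (probability 0.05, person SD
0.03) that raise fragmentation without being scored wake.

Diagnosed participants receive signed shifts: restfulness −1.0 points, WASO
+12 min, efficiency −1.5 percentage points (implemented as extra onset
latency so it does not double-count WASO), fragmentation +4 index points
(via movement probability), acrophase +0.75 h. Each is roughly one
between-person SD: large enough that the group-difference sign is
recoverable at n = 33, small enough that the cohort does not separate
perfectly and the person-level feature–outcome correlations stay in the
moderate range typical of small clinical actigraphy samples. Quality and
restfulness are drawn jointly at both the person and the night level with
correlation 0.9. PCL-5 totals are N(44, 9) for diagnosed and N(20, 9) for
controls, truncated to 0–80, which puts the ≥31 and ≥38 flag prevalences
near 10/33 and 7/33. The non-PTSD diagnosis flag is independent of all
features (prevalence 0.45), so discriminant validity holds by construction.
`planted_truth` returns every generative parameter; features not directly
planted are listed as emergent.

What the generator does **not** emulate: naps and multiple rest intervals,
shift-work schedules, physiologically detailed accelerometry, off-wrist
episodes, weekday/weekend structure, and feature–outcome relationships
beyond the planted ones. Passing tests therefore demonstrate that the
pipeline recovers known structure under its own assumptions — not that real
cohorts carry this much signal.

## Problem sizes and budgets

The test suite and the acceptance script run the full default cohort
(33 × 7 × 2880 epochs). Multi-seed calibration properties use 20 seeded
replicates. Permutation-null and toy-model checks run the identical pipeline
code with a reduced hyperparameter search (1–8 random draws instead of 25),
which is a tuning-budget choice, not a different model: the null behavior
and fold structure under test do not depend on the search width. One LOSO
outcome run with the default 25-draw search takes ~20 s on one CPU; the
acceptance script (three outcomes plus bootstrap comparisons) about a
minute.

## Known limitations

- The sleep scorer approximates, but is not, the proprietary algorithm of
  any specific device; absolute TST/WASO levels depend on its threshold.
- Full-sample feature selection is optimistically biased by design (see
  above); use `within_fold` for honest generalization estimates.
- With 8 positives of 33, person-level metrics are unstable: bootstrap CIs
  are wide and single-participant changes move sensitivity by 12.5 points.
- LOSO person probabilities come from 33 differently calibrated models;
  only their ranking, not their absolute scale, is comparable across folds.
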