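# Methods

## The scoring model

An arousal is an abrupt EEG shift to higher frequency lasting at least 3 s,
preceded by at least 10 s of stable sleep. Its **intensity** is defined here
as the mean peak-to-peak amplitude of the central EEG channels within the
event window:

    A = ½ [ (max − min) of C3 + (max − min) of C4 ]   over [onset, onset + duration)

Amplitudes of all real arousals in a dataset are quantile-binned at their
25th/50th/75th percentiles (linear-interpolation quantiles) into levels 1–4;
bins are right-closed, with open outer sentinels so every fitted value falls
inside a bin. Stable-sleep control windows ("sham arousals": 9 s windows in
non-wake sleep, at least 10 s from any arousal boundary, 10–14 per recording)
are assigned level 0, giving a five-level target. Two threshold modes exist:
`fit` (recompute quartiles from the data at hand — the default, since
quartile edges are dataset-specific) and `fixed` (apply the shipped reference
edges 93/164/404 µV from a 96-recording clinical OSA cohort).

Amplitudes are measured after preprocessing (0.3 Hz high-pass, resampling to
128 Hz); whether to measure before or after filtering is a genuinely open
choice and is configurable.

## Features

Each event contributes a pair of equal-length windows: the arousal window and
the window immediately before it. Four signals are analyzed: the sample-wise
means C3/4, O1/2, F3/4 (the composite convention for paired derivations;
configurable, since a referential-derivation reading is also defensible) and
the chin EMG. Per signal, a 5-level discrete wavelet transform (Daubechies-4,
periodization boundary) yields sets D1–D5 and A5; per set the mean power,
mean absolute coefficient value (MABS), and variance are computed, plus the
15 MABS ratios over unordered set pairs with the finer set in the numerator.
That is 6+6+15+6 = 33 statistics × 4 signals = 132 features. Computing the
variance per coefficient set (not once per signal) is the only reading
consistent with that count; likewise 15 unordered rather than 30 ordered
ratio pairs. Four auxiliary statistics of the C3/4 composite — mean band
power spectral intensity (bands 0.5–4, 4–8, 8–13, 13–30, 30–60 Hz, clipped
at Nyquist), average power, RMS, and the DFA scaling exponent — complete the
136.

Every feature is normalized as value(arousal) / value(pre-arousal). The
normalization makes the 132 wavelet features invariant to rescaling both
windows, which is the property that lets classifiers generalize across
recordings with different gains. Denominators are guarded with a *relative*
epsilon: the denominator is floored at 1e−12 × the larger operand (capping
ratios at 1e12), and 0/0 is defined as 1 (no change). An absolute 1e−12
floor would be mis-scaled for band powers in volts², which are legitimately
~1e−25 in bands the signal barely occupies.

Numerical notes: with periodization, the DWT is orthonormal and coefficient
energy equals signal energy to machine precision **when the window length is
a multiple of 2⁵**; at other lengths the per-level odd-length padding breaks
strict orthogonality (deviations up to ~2%), which does not affect feature
ratios meaningfully but is why the energy-conservation property is asserted
on multiple-of-32 lengths. DFA uses non-overlapping windows log-spaced in
[4, N/4] with per-window linear detrending; the exponent is the least-squares
slope of log F(n) vs log n (≈0.5 for white noise, ≈1.5 for Brownian-like
signals — both verified by simulation). The 0.3 Hz zero-phase Butterworth
high-pass is idempotent away from its cutoff, but its slowest transient has a
~1.4 s time constant, so idempotence holds only in the interior of a window;
filtering therefore happens on whole recordings before segmentation, and with
padding of several cutoff periods.

## Per-stage classification

Arousal characteristics differ across sleep stages, so one classifier is
trained per stage (REM, N1, N2, N3). The protocol:

1. one global stratified 80/20 split (test size is the ceiling, matching the
   reference cohort's 2,903 / 11,609 partition of 14,512 events), then
   partition by stage at onset;
2. SMOTE oversampling of every minority level to the majority count, on
   training data only (k = 5 nearest minority neighbours; k falls back for
   small classes; synthetic rows carry a `synthetic:` id prefix so leakage
   audits can exclude them). Whether to balance before or after splitting is
   not a settled question; balancing strictly after avoids leakage;
3. recursive feature elimination with 5-fold cross-validation, run for both
   classifier families (random forest and LightGBM gradient boosting); the
   subset with the highest mean CV accuracy wins, ties to the smaller
   subset; feature selection runs on the balanced training data;
4. the family with the higher RFECV accuracy is kept (ties to the random
   forest, then the smaller subset);
5. hyperparameters are tuned by a tree-structured Parzen estimator with
   successive-halving pruning (in-package implementation: per-dimension
   Parzen good/bad density ratio after a random start-up; a trial is pruned
   when its running fold-mean falls below the median of earlier trials at
   the same rung). Search spaces: random forest over n_estimators, max_depth,
   min_samples_leaf, max_features; gradient boosting over n_estimators,
   learning_rate, num_leaves, min_child_samples, colsample_bytree. The
   default objective is mean CV accuracy; `level0_sensitivity` is offered
   because maximizing control-window recovery is an equally defensible goal.

Stages whose training set lacks events or levels are skipped with a warning
(sparse N3 test sets may legitimately contain only the upper levels).
Everything is seeded; a fixed seed reproduces the report byte for byte.

## Evaluation

Metrics are one-vs-rest per level: sensitivity, specificity, PPV, NPV, and
AUROC (rank statistic; ties get half credit). Undefined 0/0 ratios are
reported as absent, never as 0. Two aggregation rules: the per-level
**average** row is the unweighted mean across the stages whose test set
contains the level (this rule — and not support-weighting — reproduces the
reference cohort's 83.07% from stage values 82.22/80.56/86.42); the **total**
row pools every prediction and support-weights the pooled per-level metrics.

## The synthetic generator

Clinical polysomnography with scorer annotations is not redistributable, so
the pipeline is exercised on synthetic recordings with known ground truth.
What it emulates:

- a Markov-chain hypnogram in 30 s epochs whose stationary occupancy
  approximates an OSA cohort (≈ N1 19%, N2 53%, N3 8%, REM 15%, W 5%);
- seven channels at 200 Hz: six EEG channels of stage-profiled colored noise
  (band-limited components weighted per stage: delta-dominant N3, mixed
  low-voltage REM) at 10 µV RMS with a 10% broadband noise floor, and a chin
  EMG with high-frequency tone halved during REM atonia;
- arousals at 32 events/hour (a typical OSA arousal index), durations
  uniform on [3, 15] s, placed by seeded rejection sampling so that every
  event has stable, event-free, non-wake sleep for max(10 s, its own
  duration) before onset and 10 s clearance after;
- event amplitudes from a log-normal law (median 180 µV, σ = 0.9, so its
  quartiles sit near the reference cohort's 93/164/404 µV edges). The four
  intensity strata are the law's quartile bins. Strata are drawn as balanced
  random permutations (stratified sampling — the bins are equiprobable, so
  this preserves the marginal law while keeping counts within one of each
  other) and the amplitude from the conditional law within the stratum,
  compressed towards the stratum's geometric median by 1/class_separation.
  Separation 1 reproduces the unmodified law; the default 5 makes strata
  essentially disjoint. Stratified sampling matters: with i.i.d. stratum
  draws, empirical quartile boundaries shift by O(√n) events and no degree
  of separation can push recovery above ≈ 1 − 1/√n at desk-scale n;
- each arousal is an additive burst of 8–30 Hz noise with 0.5 s
  raised-cosine ramps, normalized so its peak-to-peak on each EEG channel
  equals the drawn amplitude (0.4× on the chin).

What it does **not** emulate: spindles, K-complexes, artifacts, apnea or
desaturation physiology, inter-subject variability, or any correlation
between arousal intensity and sleep-stage context beyond the background
spectra. Passing recovery tests therefore shows that the pipeline's stages
compose correctly and that its statistics behave as designed — not that the
clinical classification performance of a real cohort would be matched.

## Problem sizes and defaults

Desk-scale defaults: 8 recordings × 45 min, ≈ 190 arousals plus ≈ 95 sham
windows, n_trials = 10 for the end-to-end run (30 as the library default),
RFE step 0.15 of remaining features, minimum subset 5. A full end-to-end run
takes a couple of minutes on one CPU. The EDF writer stores 16-bit samples
with per-channel symmetric physical ranges (quantization ≤ phys_max/32767);
recordings are processed one at a time so memory stays flat.

## Known limitations

- Intensity is a pure amplitude measure; time-frequency structure does not
  enter the level definition.
- The per-stage models are validated on a random event-level split, not
  subject-wise; subject-independent validation is future work.
- The reference quartile edges shipped as `REFERENCE_THRESHOLDS` are
  cohort-specific and should not be applied to new data without checking
  the amplitude distribution.
- The composite "C3/4" convention (averaging the two channels) is an
  interpretation; a configurable map supports alternatives.
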