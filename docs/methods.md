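# Methods

This note documents the models, estimators, parameter choices and known
limitations of `trinet-eeg`, in the order the pipeline applies them.

## Data model

A subject is an `EpochedRecording`: fixed-length epochs (default 2 s) of
channel or ROI time series at a common sampling rate (default 500 Hz).
Downstream stages operate on ROI series matching the packaged 24-ROI atlas
— 12 bilateral Brodmann-area regions grouped into visual (V1, V2), auditory
(A1, A2), default-mode (PHC, PCC, AG, MPFC), salience (INS, dACC) and
central-executive (DLPFC, PPC) networks. The atlas resource reproduces its
source table verbatim, including the BA46 label for MPFC and BA27 for PHC;
connection features are ordered by the row-major upper triangle over the
atlas ROI order (L before R within each region), giving 276 named pairs.

## Preprocessing

* **Filters.** All band-pass filtering is zero-phase (forward–backward)
  6th-order Butterworth in second-order sections. Zero phase is mandatory:
  lagged coherence and phase–amplitude coupling both read phase relations,
  which a causal filter would distort. Butterworth SOS was chosen over
  linear-phase FIR because a delta-band FIR (1 Hz edge) with a proportional
  transition width is several seconds long and cannot be applied to 2-s
  epochs; the SOS design meets every contract we assert on 2-s epochs
  (attenuation far beyond 20 dB one octave outside the band after the
  double pass, repeat-filter RMS change 3.7% < 5%, in-band cross-correlation
  peak at lag 0). Order 6 rather than 4 because the 4th-order design loses
  5.5% RMS on repeated filtering of white noise, just outside the 5%
  idempotence contract.
* **Band tables.** Analysis bands tile 1–44 Hz: delta 1–4, theta 4–8,
  alpha 8–13, beta 13–30, gamma 30–44 Hz. The coupling stage uses the
  separate theta 4–7 / gamma 30–45 Hz table conventional for theta–gamma
  PAC. Both tables are kept as given; adjacent analysis bands share their
  printed edge frequency, so the 0.5 Hz-resolution bin at a shared edge
  contributes to both bands. On synthetic data whose only content sits in
  one band this lets immediately adjacent bands inherit part of a planted
  effect; comparisons between non-adjacent bands (e.g. alpha vs delta) are
  unaffected.
* **Notch.** Zero-phase IIR notch at 50 Hz, quality factor 20: a pure line
  tone on a 2-s epoch is suppressed below 10% RMS including edge
  transients, while a tone 5 Hz away keeps ≥94% of its amplitude.
* **Resampling.** Polyphase (`resample_poly`) with built-in anti-aliasing;
  only downsampling is supported (the acquisition→analysis direction).
* **Outlier exclusion.** Z-scores against the sample mean/SD of a feature
  vector, default threshold ±5 SD, applied to per-subject feature vectors
  before classification rather than to raw samples. Note the sample SD is
  inflated by the outlier itself, so a single extreme value in a short
  vector can survive; this matches the plain z-score rule rather than a
  robust variant.

## Synthetic cohorts

The generator produces two-group cohorts in which every downstream effect
is planted in exactly the form its estimator detects:

* **Background** is white Gaussian noise per ROI (`noise_sd`, default 1);
  optional narrowband oscillators add band-limited Gaussian components.
* **Lagged coupling** between a ROI pair: a shared narrowband component
  `s`, with ROI i receiving `m·s + √(1−m²)·own_i` and ROI j the same with
  `s` rotated by a constant phase via its analytic signal. The mixing
  proportion m ∈ [0, 1] is the coupling strength; at lag φ the expected
  band lagged coherence is ≈ m⁴ sin²φ / (1 − m⁴ cos²φ), so m = 1, φ = 90°
  gives 1 and φ = 0 plants purely instantaneous coupling that the estimator
  must read as 0.
* **PAC**: a narrowband gamma carrier multiplied by
  `(1 + depth·cos θ(t)) / (1 + depth)` where θ is the Hilbert phase of a
  planted theta component (also added to the signal so the phase is
  observable). `depth` ∈ [0, 1] is the modulation depth.
* **Group effects**: an effect table maps each coupling/PAC spec to
  group-specific strength/depth values.
* **Determinism**: each subject's generator stream is seeded by the SHA-256
  hash of (master seed, group label, subject index), reduced below 2³¹ —
  reproducible across platforms, no collisions between subjects.
* Defaults (500 Hz, 2-s epochs, 150 epochs ≈ 5 min of retained data)
  emulate the scale of a single pediatric resting-state session after
  artifact rejection.

What the generator does **not** emulate: 1/f background spectra, volume
conduction and sensor mixing (unless routed through the toy leadfield),
ocular/muscle artifacts, non-stationarity across the session, and
inter-subject variability beyond the seeded noise. Passing recovery tests
therefore shows estimator correctness under controlled conditions, not
robustness to real-world artifacts.

## Lagged coherence

Cross-spectra are estimated Welch-style: one Hann taper per 2-s epoch, FFT,
outer products averaged over epochs (0.5 Hz resolution at the default
epoch length). Per bin,

    LC = Im[S_xy]² / (S_xx·S_yy − Re[S_xy]²),

and the band value divides the bin-averaged numerator by the bin-averaged
denominator (pooled form; the mean of per-bin ratios is available via
`agg="per_bin"`). The denominator uses Re[S_xy]² — the standard form, under
which Cauchy–Schwarz on the averaged spectra bounds the value by 1. Values
are clipped to [0, 1] against rounding. Degenerate bins (denominator at the
numerical floor, i.e. perfect instantaneous coherence): a vanishing
numerator yields 0 (the identical-signals case); otherwise the value is
marked undefined with a warning. A single-epoch estimate is degenerate
(|S_xy|² ≡ S_xx·S_yy) and warns.

## Modulation index

Phase and amplitude are extracted per epoch (zero-phase band-pass, then
analytic signal), one low-band cycle is trimmed from each end of each epoch
to remove filter/Hilbert edge effects, and the trimmed segments are pooled
per ROI. The phase circle (−π, π] is divided into n = 18 equal bins (20°,
the usual convention for the entropy MI); Shannon entropy is taken in bits
to match the lb(n) normalization. Empty phase bins contribute zero mean
amplitude (with a warning); a constant or all-zero amplitude returns MI = 0.
MI is exactly invariant to amplitude scaling and to phase rotations by
multiples of the bin width; arbitrary rotations change it only through
binning discretization. The estimator's null bias is positive and shrinks
with series length; at the default pooled length the null median is below
0.01, and planted-depth recovery is assessed by monotonicity rather than
absolute value, since the MI scale depends on carrier-to-noise ratio.

## Standardized minimum-norm inverse

Given a sensors × sources gain G, the operator is
W = Gᵀ(GGᵀ + αI)⁺ with each row divided by √R_jj, R = WG the resolution
matrix. α defaults to 10⁻² · mean eigenvalue of GGᵀ (scale-free); α = 0 is
allowed when G has full column rank (rank-deficient gains raise an error
advising α > 0 — note GGᵀ itself is always singular when sensors exceed
sources, which the pseudoinverse handles). Standardization gives exact
zero-localization error for a noiseless single source, verified
exhaustively on the toy leadfield (ring of sensors, jittered inner ring of
sources, inverse-square gains). ROI series are the first SVD component of
the member sources, sign-aligned to the ROI mean series.

## Group inference

Pooled-variance t (df = n₁+n₂−2; two groups of 40 and 42 give df = 80),
two-sided throughout. Family-wise correction uses the max-|t| permutation
null over features: labels reshuffled, t recomputed per feature, maximum
|t| recorded per permutation; the critical threshold is the (1−α) quantile
(upper interpolation) and a feature is significant iff its observed |t|
strictly exceeds it. The observed labeling is always a member of the null
set, making the test valid (never anticonservative). When the number of
distinct label assignments is at most the requested permutation count the
test enumerates all of them; note that two-sided max-|t| nulls pair each
split with its complement, so n vs n designs have only C(2n, n)/2
effectively distinct values — with very small groups the achievable
rejection rates are correspondingly coarse. MI group maps use per-ROI
t-tests with Benjamini–Hochberg FDR (statsmodels). Demographic tables are
tested by Pearson chi-square without continuity correction and by one-way
ANOVA reconstructed from per-group mean/SD/n.

## Classification

Linear SVM, C = 1, features standardized to zero mean / unit variance with
the scaler fitted inside each training fold; stratified k-fold (default 10)
with a recorded shuffle seed; accuracy, sensitivity and specificity pooled
over held-out predictions with "impaired" the positive class. Connection
ranking uses the |coefficient| of a single fit on the full standardized
table (per-fold mean-|weight| ranking available), ties broken by the fixed
feature order; the top set is floor(top_frac · n_features), i.e. 13 of 276
at the default 5%. No hyperparameter search or nested CV is performed —
the configuration is fixed and documented precisely so that weight ranking
is meaningful and reproducible.

## Pipeline

`run_pipeline` executes simulate/load → per-band connectivity → PAC →
permutation statistics → classification, writing CSV/TSV/JSON plus a
manifest with every parameter, the master seed and a SHA-256 hash of every
output; identical configurations reproduce byte-identical outputs. The
pipeline runs at ROI level by default so no leadfield is required; the
inverse stage is applied explicitly when sensor-space data and a leadfield
are available.

## Problem sizes used in tests and the acceptance script

Validation cohorts are deliberately small so the full suite runs in
minutes on one CPU: estimator-recovery designs use 2–10 subjects per
group, 1–8 ROIs, 8–60 epochs of 1–2 s at 128–250 Hz; the family-wise
calibration uses 200 null cohorts of 5 vs 5 subjects with exhaustive
252-split permutation (5 vs 5 rather than smaller because two-sided
max-|t| nulls at 4 vs 4 admit only 35 distinct values, making a 5% target
rate unreachable); classifier calibration uses 50 null feature tables of
40 subjects. These sizes trade estimator variance for speed; the defaults
built into `CohortDesign` (150 × 2-s epochs at 500 Hz) reflect the
full-scale study conditions.

## Known limitations

* ICA-based artifact removal, bad-channel interpolation and re-referencing
  are out of scope: synthetic ROI data carry no stereotyped artifacts.
* Lagged coherence is the only connectivity estimator; PLV/wPLI/imaginary
  coherency are not provided.
* No comodulogram or surrogate-normalized MI; group permutation inference
  covers significance.
* The inverse stage ships a toy geometry only; realistic head models and
  template source spaces are intentionally not bundled.
* MI absolute values are small at realistic carrier-to-noise ratios;
  interpret them comparatively (between groups or ROIs), not as effect
  sizes on an absolute scale.
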