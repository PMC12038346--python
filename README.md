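# trinet-eeg

Resting-state EEG analysis of large-scale brain-network reorganization, for
studies comparing a sensory-impaired group against controls. The package
implements the full analysis chain used in pediatric congenital
visual/hearing-impairment research on the triple-network model — band-limited
preprocessing, lagged-coherence functional connectivity over a 24-ROI
atlas spanning the visual, auditory, default-mode, salience and
central-executive networks, theta–gamma phase–amplitude coupling,
permutation-based group inference, and SVM classification of connection
features — together with a seeded synthetic-cohort generator that plants
known coupling and modulation effects, so every estimator can be validated
against recoverable ground truth.

## Methods at the core

**Lagged coherence.** For ROI signals x, y with epoch-averaged cross-spectrum
S_xy(ω) and auto-spectra S_xx, S_yy:

    LC_xy(ω) = Im[S_xy(ω)]² / ( S_xx(ω) · S_yy(ω) − Re[S_xy(ω)]² )

bounded in [0, 1]. Identical (zero-lag) signals give 0 — the instantaneous
component that volume conduction produces is discounted — while a noiseless
quadrature pair gives 1. Band values pool numerator and denominator over
in-band bins. The 24-ROI atlas yields 24·23/2 = 276 connection features per
subject per band (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–44 Hz).

**Modulation index (MI).** Theta phase θ(t) (4–7 Hz) and gamma amplitude
A(t) (30–45 Hz) are extracted by zero-phase filtering and the analytic
signal; the phase circle is cut into n = 18 bins, the mean amplitude per
bin is normalized to a distribution P(j), and

    MI = ( lb(n) − H(P) ) / lb(n),   H(P) = −Σⱼ P(j) lb P(j)

with lb = log₂, so MI ∈ [0, 1]: 0 for phase-independent amplitude, 1 for
amplitude confined to a single bin.

**Group inference.** Pooled-variance two-sample t per feature
(df = n₁+n₂−2), family-wise corrected by the permutation max-|t| null
(exhaustive enumeration when feasible), plus Benjamini–Hochberg FDR for the
per-ROI MI comparisons, and chi-square / one-way ANOVA reconstructed from
summary tables for demographics.

**Classification.** Linear SVM (C = 1) on standardized connection features,
stratified 10-fold cross-validation, accuracy/sensitivity/specificity pooled
over held-out folds, and connection ranking by |coefficient| with the top
5% (13 of 276) reported and annotated by network pair.

A standardized minimum-norm (sLORETA-style) inverse with ROI aggregation is
included for sensor-space inputs with a user leadfield; synthetic cohorts
are generated directly at ROI level.

## Worked example

`examples/02_lagged_coherence.py` plants alpha-band coupling between two
ROIs at controlled strength and lag, then estimates it:

```
zero lag, identical signals : 0.0
quadrature pair, noiseless  : 1.0
strength 0.2 in noise        : 0.0052
strength 0.5 in noise        : 0.0643
strength 0.8 in noise        : 0.4089
```

The zero-lag pair reads exactly 0 (instantaneous coupling is discounted),
the noiseless 90°-lagged pair reads 1, and estimates increase monotonically
with planted strength — for mixing proportion m the expected band value is
≈ m⁴ at a 90° lag, so 0.8 → ≈ 0.41.

`examples/05_classification.py` runs the band-wise classifier on a cohort
with alpha-band connectivity reductions planted in the impaired group:

```
    band  accuracy   sens   spec
   delta     0.600  0.800  0.400
   theta     1.000  1.000  1.000
   alpha     1.000  1.000  1.000
    beta     1.000  1.000  1.000
   gamma     0.550  0.400  0.700

top-ranked alpha connection(s): ['ROI02--ROI03']
```

Alpha (where the effect lives) separates the groups perfectly while the
non-adjacent delta and gamma bands stay near chance; the top-weighted
connection is one of the three planted pairs. The other examples cover
cohort simulation and text export (`01`), phase–amplitude coupling (`03`),
permutation inference and summary-table statistics (`04`), source
localization (`06`) and the end-to-end pipeline with its provenance
manifest (`07`).

A thin CLI wraps the pipeline: `trinet run-all --config run.yaml`, plus
`simulate`, `connectivity`, `cfc`, `stats`, `classify` and `report`
subcommands.

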