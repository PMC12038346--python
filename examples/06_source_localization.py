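"""Standardized minimum-norm localization on a toy leadfield.

Demonstrates the zero-localization-error property: with one active source
and no noise, the arg-max of standardized source power is exactly the true
source, for every source position.
"""

import numpy as np

from trinet_eeg import localize, roi_timeseries, toy_leadfield

lf = toy_leadfield(n_sensors=32, n_sources=20, seed=1)
wave = np.sin(np.linspace(0, 12, 200))

hits = 0
for j in range(lf.n_sources):
    src = np.zeros((lf.n_sources, wave.size))
    src[j] = wave
    hits += localize(lf, lf.gain @ src, alpha=0.0) == j
print(f"correct localizations: {hits}/{lf.n_sources}")

# aggregate sources into two ROIs and recover a planted ROI signal
rng = np.random.default_rng(0)
activity = 0.3 * rng.standard_normal((20, wave.size))
activity[:5] += wave
series, names = roi_timeseries(activity, {"front": list(range(5)),
                                          "back": list(range(5, 20))})
corr = np.corrcoef(series[0], wave)[0, 1]
print(f"ROI 'front' vs planted signal correlation: {corr:.3f}")
print("Standardization makes localization exact in the noiseless single-")
print("source case; ROI series are the first principal direction of their")
print("member sources, sign-aligned with the ROI mean.")
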