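"""Lagged coherence: what it detects and what it deliberately ignores.

Three pair configurations, all in the alpha band:
  * identical signals (zero lag)      -> lagged coherence 0
  * quadrature pair (90-degree lag)   -> lagged coherence ~1
  * graded coupling strengths         -> graded estimates
"""

import numpy as np

from trinet_eeg import (
    CohortDesign, CouplingSpec, GroupEffect, cross_spectrum, generate_subject,
    get_band, lagged_coherence,
)

alpha = get_band("alpha")


def planted_pair(strength, lag, noise, seed):
    design = CohortDesign(
        n_per_group=2, n_roi=2, noise_sd=noise, n_epochs=60,
        sampling_rate=250.0, epoch_len=1.0,
        effects=(GroupEffect(CouplingSpec((0, 1), alpha, lag, strength)),),
    )
    rec = generate_subject(design, "control", seed)
    return lagged_coherence(cross_spectrum(rec), (0, 1), alpha)


print("zero lag, identical signals :", planted_pair(1.0, 0.0, 0.0, 1))
print("quadrature pair, noiseless  :", round(planted_pair(1.0, np.pi / 2, 0.0, 1), 4))
for m in (0.2, 0.5, 0.8):
    vals = [planted_pair(m, np.pi / 2, 0.3, s) for s in range(10)]
    print(f"strength {m:.1f} in noise        : {np.mean(vals):.4f}")
print("Instantaneous (zero-lag) coupling is discounted by design — that is")
print("the component volume conduction would produce; only genuinely lagged")
print("synchronization raises the value, monotonically in planted strength.")
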