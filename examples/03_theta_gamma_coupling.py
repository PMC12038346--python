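"""Theta-gamma phase-amplitude coupling via the entropy modulation index.

Shows the MI endpoints (0 for phase-independent amplitude, 1 for amplitude
confined to one phase bin) and recovery of planted modulation depth.
"""

import numpy as np

from trinet_eeg import (
    CohortDesign, GroupEffect, PACSpec, generate_subject, modulation_index,
    pac_map,
)

rng = np.random.default_rng(0)
phase = rng.uniform(-np.pi, np.pi, 50_000)
print("MI, amplitude independent of phase:",
      modulation_index(phase, np.ones_like(phase)))
amp = np.where((phase > 0) & (phase < 2 * np.pi / 18), 1.0, 0.0)
print("MI, amplitude in a single 20-degree bin:",
      round(modulation_index(phase, amp), 6))

for depth in (0.0, 0.3, 0.6, 0.9):
    design = CohortDesign(
        n_per_group=2, n_roi=1, noise_sd=0.2, n_epochs=25,
        sampling_rate=250.0, epoch_len=2.0,
        effects=(GroupEffect(PACSpec(0, depth=depth)),),
    )
    mis = [pac_map(generate_subject(design, "control", 10 + s)).mi[0]
           for s in range(10)]
    print(f"planted depth {depth:.1f} -> estimated MI {np.mean(mis):.5f}")
print("Estimates grow monotonically with the planted theta-phase ->")
print("gamma-amplitude modulation depth; the absolute MI scale depends on")
print("noise level and series length, so group comparisons use it relatively.")
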