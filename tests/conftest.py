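import numpy as np
import pytest

from trinet_eeg.bands import get_band
from trinet_eeg.synth import CohortDesign, CouplingSpec, GroupEffect, PACSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def alpha_band():
    return get_band("alpha")


@pytest.fixture
def quadrature_design(alpha_band):
    """Noiseless ROI pair coupled at full strength with a 90-degree lag."""
    return CohortDesign(
        n_per_group=2, n_roi=2, noise_sd=0.0, n_epochs=40,
        sampling_rate=250.0, epoch_len=2.0,
        effects=(GroupEffect(CouplingSpec((0, 1), alpha_band,
                                          phase_lag=np.pi / 2, strength=1.0)),),
    )


def coupling_design(strength: float, seed: int, *, lag=np.pi / 2, noise=0.3,
                    n_epochs=60, sfreq=250.0):
    band = get_band("alpha")
    return CohortDesign(
        n_per_group=2, n_roi=2, noise_sd=noise, n_epochs=n_epochs,
        sampling_rate=sfreq, epoch_len=1.0, seed=seed,
        effects=(GroupEffect(CouplingSpec((0, 1), band, lag, strength)),),
    )


def pac_design(depth: float, seed: int, *, noise=0.2, n_epochs=25, sfreq=250.0):
    return CohortDesign(
        n_per_group=2, n_roi=1, noise_sd=noise, n_epochs=n_epochs,
        sampling_rate=sfreq, epoch_len=2.0, seed=seed,
        effects=(GroupEffect(PACSpec(0, depth=depth)),),
    )
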