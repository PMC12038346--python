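"""Theta-gamma phase-amplitude coupling via the entropy modulation index.

The modulation index (MI) measures how strongly the phase of a slow rhythm
modulates the amplitude of a fast one. The low-frequency phase theta(t) and
high-frequency amplitude A(t) are extracted by zero-phase band-pass
filtering followed by the analytic (Hilbert) signal. The phase circle
(-pi, pi] is divided into n equal bins (default n = 18, i.e. 20-degree
bins); the mean amplitude per bin, normalized to sum to one, gives a
distribution P(j). The MI is the normalized Shannon-entropy deficit

    MI = (lb(n) - H(P)) / lb(n),      H(P) = -sum_j P(j) lb P(j)

with lb = log2. MI = 0 when amplitude is uniform over phase (H = lb n) and
MI = 1 when all amplitude concentrates in a single bin (H = 0).

Filter edge samples are discarded from each epoch before pooling, so epoch
boundaries contribute no spurious phase-amplitude covariation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import BandSpec, CFC_AMP_BAND, CFC_PHASE_BAND
from .preprocess import filter_array
from .recording import EpochedRecording

N_BINS_DEFAULT = 18


@dataclass
class PACMap:
    """Per-ROI modulation-index values for one subject."""

    mi: np.ndarray
    roi_names: list[str]
    phase_band: BandSpec = CFC_PHASE_BAND
    amp_band: BandSpec = CFC_AMP_BAND
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.mi.shape != (len(self.roi_names),):
            raise ValueError("mi must have one value per ROI")

    def to_series(self) -> pd.Series:
        return pd.Series(self.mi, index=self.roi_names, name=self.subject_id)


def phase_amplitude_extract(series: np.ndarray, phase_band: BandSpec,
                            amp_band: BandSpec, sfreq: float,
                            trim: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Low-band instantaneous phase and high-band amplitude envelope.

    ``trim`` samples are dropped from each end of both outputs (default:
    one cycle of the phase band's low edge) to remove filter and Hilbert
    edge effects.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("expected a single-ROI 1-D series")
    if series.size < 2 * sfreq:
        raise ValueError("series shorter than 2 s; phase estimation unreliable")
    nyq = sfreq / 2
    if amp_band.hi >= nyq or phase_band.hi >= nyq:
        raise ValueError("band edge at or above Nyquist")
    if trim is None:
        trim = int(round(sfreq / phase_band.lo))
    low = filter_array(series, phase_band, sfreq)
    high = filter_array(series, amp_band, sfreq)
    phase = np.angle(hilbert(low))
    amplitude = np.abs(hilbert(high))
    if trim > 0:
        if 2 * trim >= series.size:
            raise ValueError("trim removes the entire series")
        phase = phase[trim:-trim]
        amplitude = amplitude[trim:-trim]
    return phase, amplitude


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = N_BINS_DEFAULT) -> float:
    """Entropy-normalized modulation index of amplitude over phase bins."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-D series")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be nonnegative")
    if np.all(amplitude == 0):
        warnings.warn("all-zero amplitude; MI set to 0", stacklevel=2)
        return 0.0
    if np.ptp(amplitude) == 0:
        return 0.0  # constant envelope: no modulation by definition

    # circular binning of (-pi, pi] into n equal parts
    idx = np.floor((np.mod(phase + np.pi, 2 * np.pi)) / (2 * np.pi / n_bins)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        warnings.warn(
            f"{int((counts == 0).sum())} empty phase bin(s); their mean "
            "amplitude is treated as 0",
            stacklevel=2,
        )
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return 0.0
    P = means / total
    nz = P[P > 0]
    H = float(-(nz * np.log2(nz)).sum())
    lbn = np.log2(n_bins)
    return float(np.clip((lbn - H) / lbn, 0.0, 1.0))


def pac_map(rec: EpochedRecording, phase_band: BandSpec = CFC_PHASE_BAND,
            amp_band: BandSpec = CFC_AMP_BAND, n_bins: int = N_BINS_DEFAULT,
            roi_names: list[str] | None = None) -> PACMap:
    """Per-ROI MI: extraction per epoch (edge-trimmed), pooled per ROI."""
    names = roi_names or rec.ch_names
    if len(names) != rec.n_channels:
        raise ValueError("roi_names length does not match recording channels")
    mi = np.empty(rec.n_channels)
    for r in range(rec.n_channels):
        phases, amps = [], []
        for e in range(rec.n_epochs):
            ph, am = phase_amplitude_extract(
                rec.data[e, r], phase_band, amp_band, rec.sfreq
            )
            phases.append(ph)
            amps.append(am)
        mi[r] = modulation_index(
            np.concatenate(phases), np.concatenate(amps), n_bins=n_bins
        )
    return PACMap(
        mi=mi, roi_names=list(names), phase_band=phase_band, amp_band=amp_band,
        subject_id=rec.subject_id, group=rec.group,
    )


def mi_table(maps: list[PACMap]) -> pd.DataFrame:
    """Stack subjects' per-ROI MI values into a subjects x ROI DataFrame."""
    if not maps:
        raise ValueError("no PAC maps given")
    return pd.DataFrame([m.to_series() for m in maps])
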