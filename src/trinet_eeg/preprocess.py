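"""Preprocessing chain: resampling, filtering, segmentation, outlier masks.

All filters are zero-phase (forward-backward second-order sections), which
is mandatory here: downstream lagged coherence and phase-amplitude coupling
both read phase relations, and any phase distortion introduced during
band decomposition would contaminate them. A 6th-order Butterworth band-pass
run forward-backward attenuates far more than 20 dB one octave outside the band
and remains applicable to 2-s epochs even for the 1 Hz delta edge, where
linear-phase FIR designs of comparable selectivity would be longer than the
epoch itself.

The z-score outlier rule operates on per-observation feature vectors (e.g.
one subject's connectivity coefficients across a cohort), marking entries
whose |z| exceeds a threshold (default 5 SD) relative to the sample
mean/SD of the vector.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .bands import BandSpec
from .recording import EpochedRecording

FILTER_ORDER = 6  # per pass; effective order doubles under filtfilt


def _check_band(band: BandSpec, sfreq: float) -> None:
    nyq = sfreq / 2.0
    if band.hi >= nyq:
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) reaches Nyquist "
            f"({nyq} Hz) at sampling rate {sfreq} Hz"
        )


def bandpass_sos(band: BandSpec, sfreq: float):
    _check_band(band, sfreq)
    return signal.butter(
        FILTER_ORDER, [band.lo, band.hi], btype="bandpass", fs=sfreq, output="sos"
    )


def filter_array(x: np.ndarray, band: BandSpec, sfreq: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis."""
    sos = bandpass_sos(band, sfreq)
    return signal.sosfiltfilt(sos, x, axis=-1)


def filter_band(rec: EpochedRecording, band: BandSpec) -> EpochedRecording:
    """Zero-phase band-pass each epoch; epoch length is preserved."""
    return rec.copy_with(data=filter_array(rec.data, band, rec.sfreq))


def notch_filter(rec: EpochedRecording, freq: float = 50.0, q: float = 20.0) -> EpochedRecording:
    """Zero-phase notch (power-line) filter at ``freq`` Hz.

    The default quality factor (20) suppresses a pure line tone on a 2-s
    epoch to under 10% RMS including edge transients while keeping ≥94% of
    a tone 5 Hz away.
    """
    if freq >= rec.sfreq / 2:
        raise ValueError(f"notch frequency {freq} Hz at or above Nyquist")
    b, a = signal.iirnotch(freq, q, fs=rec.sfreq)
    data = signal.filtfilt(b, a, rec.data, axis=-1)
    return rec.copy_with(data=data)


def resample(rec: EpochedRecording, target_rate: float) -> EpochedRecording:
    """Polyphase resampling with anti-alias filtering (downsampling only)."""
    if target_rate > rec.sfreq:
        raise ValueError(
            f"upsampling not supported ({rec.sfreq} -> {target_rate} Hz)"
        )
    if target_rate == rec.sfreq:
        return rec.copy_with()
    from fractions import Fraction

    frac = Fraction(target_rate / rec.sfreq).limit_denominator(10_000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return rec.copy_with(data=data, sfreq=target_rate)


def segment(continuous: np.ndarray, sfreq: float, epoch_len: float,
            ch_names: list[str] | None = None, **labels) -> EpochedRecording:
    """Cut a channels x samples array into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded. A signal
    shorter than one epoch yields zero epochs with a warning.
    """
    if epoch_len <= 0:
        raise ValueError("epoch_len must be positive")
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n = int(round(epoch_len * sfreq))
    k = continuous.shape[1] // n
    if k == 0:
        warnings.warn(
            f"signal shorter than one {epoch_len}-s epoch; returning 0 epochs",
            stacklevel=2,
        )
        data = np.empty((0, continuous.shape[0], n))
    else:
        data = np.stack([continuous[:, i * n:(i + 1) * n] for i in range(k)])
    return EpochedRecording(data=data, sfreq=sfreq, ch_names=ch_names or [], **labels)


def zscore_exclude(values: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Boolean keep-mask: True where |z| <= threshold.

    z is computed against the sample mean and (ddof=1) SD of the input
    vector. A zero-variance vector keeps everything, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D feature vector")
    if values.size < 3:
        raise ValueError("need at least 3 observations for outlier z-scoring")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in outlier input")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; keeping all observations", stacklevel=2)
        return np.ones(values.shape, dtype=bool)
    z = (values - values.mean()) / sd
    return np.abs(z) <= threshold
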