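"""Lagged-coherence functional connectivity from epoch-averaged cross-spectra.

Lagged coherence quantifies frequency-domain synchronization between two
signals while discounting zero-lag (instantaneous) coupling, the component
that volume conduction produces trivially on scalp and source EEG. Per
frequency bin it is

    LC_xy(w) = Im[S_xy(w)]^2 / (S_xx(w) * S_yy(w) - Re[S_xy(w)]^2)

where S_xy is the epoch-averaged cross-power spectrum and S_xx, S_yy the
auto-spectra. The value lies in [0, 1]: identical (zero-lag) signals give 0
because Im[S_xy] = 0; a noiseless quadrature pair gives 1 because the real
part vanishes while |S_xy|^2 = S_xx * S_yy.

Band values aggregate the numerator and the denominator separately over
in-band bins before dividing (a pooled-spectrum definition, stabler than
averaging per-bin ratios; the per-bin mean is available via ``agg``).

Cross-spectra are estimated Welch-style: one Hann taper per epoch, FFT,
outer products averaged over epochs. At the default 2-s epochs this gives
0.5 Hz resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas
from .bands import ANALYSIS_BANDS, BandSpec
from .recording import EpochedRecording

_RTOL = 1e-9  # relative floor below which a spectrum term counts as zero


@dataclass
class CrossSpectrum:
    """Epoch-averaged complex cross-spectral matrix per frequency bin."""

    S: np.ndarray          # (n_ch, n_ch, n_freq) complex, Hermitian per bin
    freqs: np.ndarray      # (n_freq,), strictly increasing, Hz
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        if self.S.ndim != 3 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be (n_ch, n_ch, n_freq)")
        if self.S.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.S.shape[0]

    def band_slice(self, band: BandSpec) -> np.ndarray:
        sel = (self.freqs >= band.lo) & (self.freqs <= band.hi)
        if not sel.any():
            raise ValueError(
                f"band {band.name} ({band.lo}-{band.hi} Hz) contains no "
                f"frequency bins (resolution {self.freqs[1] - self.freqs[0]:g} Hz)"
            )
        return sel


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI lagged-coherence values for one subject, one band."""

    values: np.ndarray
    band: BandSpec
    roi_names: list[str]
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if v.shape[0] != len(self.roi_names):
            raise ValueError("roi_names length mismatch")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        """Upper-triangle values, row-major, i < j (276 entries for 24 ROIs)."""
        iu = np.triu_indices(self.n_roi, k=1)
        return self.values[iu]

    def pair_names(self) -> list[str]:
        from .atlas import PAIR_SEP
        n = self.roi_names
        iu = np.triu_indices(self.n_roi, k=1)
        return [f"{n[i]}{PAIR_SEP}{n[j]}" for i, j in zip(*iu)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_names, columns=self.roi_names)

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def cross_spectrum(rec: EpochedRecording, window: str = "hann") -> CrossSpectrum:
    """Epoch-averaged cross-spectral matrix (one taper per epoch)."""
    if rec.n_epochs < 1:
        raise ValueError("recording has no epochs")
    if rec.n_epochs == 1:
        warnings.warn(
            "single-epoch cross-spectrum: lagged coherence is degenerate "
            "(|S_xy|^2 = S_xx S_yy identically)",
            stacklevel=2,
        )
    taper = np.hanning(rec.n_samples) if window == "hann" else np.ones(rec.n_samples)
    F = np.fft.rfft(rec.data * taper, axis=-1)  # (n_epochs, n_ch, n_freq)
    S = np.einsum("eif,ejf->ijf", F, np.conj(F)) / rec.n_epochs
    freqs = np.fft.rfftfreq(rec.n_samples, d=1.0 / rec.sfreq)
    return CrossSpectrum(S=S, freqs=freqs, n_epochs_averaged=rec.n_epochs)


def lagged_coherence(cs: CrossSpectrum, pair: tuple[int, int], band: BandSpec,
                     agg: str = "pooled") -> float:
    """Band lagged coherence for one channel pair, clipped to [0, 1].

    ``agg="pooled"`` averages numerator and denominator over in-band bins
    before dividing; ``agg="per_bin"`` averages the per-bin ratios.
    Degenerate cases: if the denominator vanishes with a vanishing
    numerator (identical signals) the value is 0; if it vanishes with
    signal present at perfect instantaneous coherence, NaN is returned.
    """
    i, j = pair
    sel = cs.band_slice(band)
    Sxy = cs.S[i, j, sel]
    Sxx = np.real(cs.S[i, i, sel])
    Syy = np.real(cs.S[j, j, sel])
    num = np.imag(Sxy) ** 2
    den = Sxx * Syy - np.real(Sxy) ** 2
    scale = float(np.max(Sxx * Syy)) or 1.0
    if agg == "pooled":
        n, d = float(num.mean()), float(den.mean())
        if d <= _RTOL * scale:
            if n <= _RTOL * scale:
                return 0.0
            warnings.warn("denominator vanished with nonzero numerator", stacklevel=2)
            return float("nan")
        return float(np.clip(n / d, 0.0, 1.0))
    elif agg == "per_bin":
        good = den > _RTOL * scale
        if not good.any():
            if num.max(initial=0.0) <= _RTOL * scale:
                return 0.0
            warnings.warn("all in-band bins degenerate", stacklevel=2)
            return float("nan")
        if not good.all():
            warnings.warn("skipping degenerate in-band bins", stacklevel=2)
        return float(np.clip(np.mean(num[good] / den[good]), 0.0, 1.0))
    raise ValueError(f"unknown aggregation {agg!r}")


def connectivity_matrix(rec: EpochedRecording, band: BandSpec,
                        atlas: Atlas | None = None, agg: str = "pooled",
                        cs: CrossSpectrum | None = None) -> ConnectivityMatrix:
    """All-pairs band lagged coherence for one subject (diagonal = 0)."""
    if atlas is not None and rec.n_channels != atlas.n_roi:
        raise ValueError(
            f"recording has {rec.n_channels} channels but atlas defines "
            f"{atlas.n_roi} ROIs"
        )
    if cs is None:
        cs = cross_spectrum(rec)
    sel = cs.band_slice(band)
    S = cs.S[:, :, sel]
    Sxx = np.real(np.einsum("iif->if", S))           # (n_ch, n_bins)
    num = np.imag(S) ** 2                            # (n_ch, n_ch, n_bins)
    den = Sxx[:, None, :] * Sxx[None, :, :] - np.real(S) ** 2
    scale = float(np.max(Sxx) ** 2) or 1.0
    if agg == "pooled":
        n_, d_ = num.mean(axis=-1), den.mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(
                d_ > _RTOL * scale, n_ / np.where(d_ > _RTOL * scale, d_, 1.0),
                np.where(n_ <= _RTOL * scale, 0.0, np.nan),
            )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > _RTOL * scale, num / np.where(den > _RTOL * scale, den, 1.0), np.nan)
        vals = np.nanmean(ratio, axis=-1)
        vals = np.where(np.isnan(vals), 0.0, vals)
    vals = np.clip(vals, 0.0, 1.0)
    np.fill_diagonal(vals, 0.0)
    vals = 0.5 * (vals + vals.T)  # enforce exact symmetry
    names = list(atlas.roi_names) if atlas is not None else list(rec.ch_names)
    return ConnectivityMatrix(
        values=vals, band=band, roi_names=names,
        subject_id=rec.subject_id, group=rec.group,
    )


def connectivity_vectors(rec: EpochedRecording,
                         bands: tuple[BandSpec, ...] = ANALYSIS_BANDS,
                         atlas: Atlas | None = None,
                         agg: str = "pooled") -> dict[str, ConnectivityMatrix]:
    """Per-band connectivity matrices from a single cross-spectrum estimate."""
    cs = cross_spectrum(rec)
    return {
        band.name: connectivity_matrix(rec, band, atlas=atlas, agg=agg, cs=cs)
        for band in bands
    }


def vector_frame(mats: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Stack subjects' 276-vectors into a subjects x pairs DataFrame."""
    if not mats:
        raise ValueError("no connectivity matrices given")
    cols = mats[0].pair_names()
    rows = {}
    for m in mats:
        if m.pair_names() != cols:
            raise ValueError("inconsistent ROI sets across subjects")
        rows[m.subject_id] = m.vector()
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
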