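"""Cross-spectrum and lagged-coherence contracts, with a brute-force oracle."""

import numpy as np
import pytest

from trinet_eeg.atlas import load_atlas, toy_atlas
from trinet_eeg.bands import ANALYSIS_BANDS, get_band
from trinet_eeg.connectivity import (
    connectivity_matrix, connectivity_vectors, cross_spectrum,
    lagged_coherence, vector_frame,
)
from trinet_eeg.recording import EpochedRecording
from trinet_eeg.synth import generate_subject

from conftest import coupling_design


def _rec(rng, n_epochs=20, n_ch=4, sfreq=250.0, dur=1.0):
    data = rng.standard_normal((n_epochs, n_ch, int(dur * sfreq)))
    return EpochedRecording(data=data, sfreq=sfreq)


def test_cross_spectrum_hermitian_with_nonnegative_diagonal(rng):
    cs = cross_spectrum(_rec(rng))
    for k in range(0, cs.freqs.size, 17):
        np.testing.assert_allclose(cs.S[:, :, k], cs.S[:, :, k].conj().T, atol=1e-12)
    diag = np.real(np.einsum("iif->if", cs.S))
    assert np.all(diag >= 0)
    assert np.all(np.abs(np.imag(np.einsum("iif->if", cs.S))) < 1e-12)


def test_independent_noise_has_low_coherence(rng):
    rec = _rec(rng, n_epochs=200, n_ch=2)
    cs = cross_spectrum(rec)
    coh = np.abs(cs.S[0, 1]) / np.sqrt(np.real(cs.S[0, 0]) * np.real(cs.S[1, 1]))
    assert coh.mean() < 0.15


def test_duplicated_channel_has_unit_coherence_zero_lagged(rng):
    x = rng.standard_normal((30, 1, 250))
    rec = EpochedRecording(data=np.concatenate([x, x], axis=1), sfreq=250.0)
    cs = cross_spectrum(rec)
    coh = np.abs(cs.S[0, 1]) / np.sqrt(np.real(cs.S[0, 0]) * np.real(cs.S[1, 1]))
    np.testing.assert_allclose(coh[1:], 1.0, atol=1e-8)
    # identical signals: instantaneous coupling only
    assert lagged_coherence(cs, (0, 1), get_band("alpha")) == 0.0


def test_sinusoid_peaks_in_its_band():
    sfreq, dur = 250.0, 1.0
    t = np.arange(int(dur * sfreq)) / sfreq
    x = np.tile(np.sin(2 * np.pi * 10 * t), (8, 1, 1))
    cs = cross_spectrum(EpochedRecording(data=x, sfreq=sfreq))
    power = np.real(cs.S[0, 0])
    peak = cs.freqs[np.argmax(power)]
    assert 8 <= peak <= 13


def test_quadrature_pair_reaches_one(quadrature_design):
    rec = generate_subject(quadrature_design, "control", 5)
    val = lagged_coherence(cross_spectrum(rec), (0, 1), get_band("alpha"))
    assert val > 0.99


def test_strength_monotonicity_mean_over_seeds(alpha_band):
    means = []
    for strength in (0.2, 0.5, 0.8):
        vals = [
            lagged_coherence(
                cross_spectrum(
                    generate_subject(coupling_design(strength, s), "control", 900 + s)
                ),
                (0, 1), alpha_band,
            )
            for s in range(20)
        ]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_matrix_matches_bruteforce_oracle(rng):
    """Direct per-pair recomputation from raw FFTs, written independently."""
    rec = _rec(rng, n_epochs=20, n_ch=4)
    band = get_band("alpha")
    mat = connectivity_matrix(rec, band).values

    taper = np.hanning(rec.n_samples)
    freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.sfreq)
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    for i in range(4):
        for j in range(i + 1, 4):
            Sxy = np.zeros(sel.sum(), dtype=complex)
            Sxx = np.zeros(sel.sum())
            Syy = np.zeros(sel.sum())
            for e in range(rec.n_epochs):
                Fx = np.fft.rfft(rec.data[e, i] * taper)[sel]
                Fy = np.fft.rfft(rec.data[e, j] * taper)[sel]
                Sxy += Fx * np.conj(Fy)
                Sxx += np.abs(Fx) ** 2
                Syy += np.abs(Fy) ** 2
            Sxy /= rec.n_epochs
            Sxx /= rec.n_epochs
            Syy /= rec.n_epochs
            num = np.mean(np.imag(Sxy) ** 2)
            den = np.mean(Sxx * Syy - np.real(Sxy) ** 2)
            assert mat[i, j] == pytest.approx(num / den, abs=1e-10)


def test_values_bounded_and_symmetric_on_random_inputs(rng):
    band = get_band("beta")
    for _ in range(25):
        rec = _rec(rng, n_epochs=4, n_ch=5)
        m = connectivity_matrix(rec, band).values
        assert np.all((m >= 0) & (m <= 1))
        np.testing.assert_array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)


def test_instantaneous_mixing_does_not_inflate_lagged_coherence(rng):
    """Real zero-lag mixing (volume conduction) must not raise the metric."""
    band = get_band("alpha")
    base, mixed = [], []
    A = np.array([[1.0, 0.6], [0.6, 1.0]])
    for s in range(10):
        r = np.random.default_rng(s)
        rec = _rec(r, n_epochs=60, n_ch=2)
        base.append(lagged_coherence(cross_spectrum(rec), (0, 1), band))
        mrec = rec.copy_with(data=np.einsum("ij,ejt->eit", A, rec.data))
        mixed.append(lagged_coherence(cross_spectrum(mrec), (0, 1), band))
    assert np.mean(mixed) <= np.mean(base) + 0.02


def test_vectorizer_sizes_and_pair_names():
    atlas24 = load_atlas()
    assert atlas24.n_pairs == 276
    assert len(atlas24.pair_names()) == 276
    assert toy_atlas(4).n_pairs == 6
    assert atlas24.pair_names()[0] == "L_V1--R_V1"


def test_connectivity_vectors_five_bands(rng):
    atlas = toy_atlas(4)
    rec = _rec(rng, n_epochs=10, n_ch=4, sfreq=250.0)
    out = connectivity_vectors(rec, atlas=atlas)
    assert set(out) == {b.name for b in ANALYSIS_BANDS}
    for m in out.values():
        assert m.vector().shape == (6,)
    frame = vector_frame([out["alpha"]])
    assert list(frame.columns) == atlas.pair_names()


def test_relabelling_equivariance(rng):
    band = get_band("alpha")
    rec = _rec(rng, n_epochs=15, n_ch=4)
    perm = np.array([2, 0, 3, 1])
    prec = rec.copy_with(data=rec.data[:, perm, :],
                         ch_names=[rec.ch_names[p] for p in perm])
    m = connectivity_matrix(rec, band).values
    mp = connectivity_matrix(prec, band).values
    np.testing.assert_allclose(mp[np.ix_(np.argsort(perm), np.argsort(perm))], m,
                               atol=1e-12)


def test_atlas_mismatch_rejected(rng):
    rec = _rec(rng, n_ch=4)
    with pytest.raises(ValueError, match="atlas"):
        connectivity_matrix(rec, get_band("alpha"), atlas=load_atlas())


def test_single_epoch_warns(rng):
    rec = _rec(rng, n_epochs=1)
    with pytest.warns(UserWarning, match="single-epoch"):
        cross_spectrum(rec)
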