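"""Phase-amplitude coupling: extraction, modulation index, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trinet_eeg.bands import CFC_AMP_BAND, CFC_PHASE_BAND, BandSpec
from trinet_eeg.cfc import (
    N_BINS_DEFAULT, mi_table, modulation_index, pac_map, phase_amplitude_extract,
)
from trinet_eeg.synth import generate_subject

from conftest import pac_design


def test_phase_slope_matches_sinusoid_frequency():
    sfreq = 500.0
    t = np.arange(int(10 * sfreq)) / sfreq
    x = np.sin(2 * np.pi * 6.0 * t)
    phase, _ = phase_amplitude_extract(x, CFC_PHASE_BAND, CFC_AMP_BAND, sfreq)
    slope = np.polyfit(np.arange(phase.size) / sfreq, np.unwrap(phase), 1)[0]
    assert abs(slope - 2 * np.pi * 6.0) / (2 * np.pi * 6.0) < 0.01


def test_constant_carrier_gives_flat_amplitude():
    sfreq = 500.0
    t = np.arange(int(10 * sfreq)) / sfreq
    x = np.sin(2 * np.pi * 40.0 * t)
    _, amp = phase_amplitude_extract(x, CFC_PHASE_BAND, CFC_AMP_BAND, sfreq)
    assert np.all(amp >= 0)
    assert amp.std() / amp.mean() < 0.05


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        phase_amplitude_extract(np.zeros(2000), CFC_PHASE_BAND, CFC_AMP_BAND, 80.0)


class TestModulationIndex:
    def test_uniform_distribution_gives_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 50_000)
        assert modulation_index(phase, np.ones_like(phase)) == 0.0

    def test_single_bin_concentration_gives_one(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 10_000)
        amp = np.where((phase > 0) & (phase < 2 * np.pi / N_BINS_DEFAULT), 1.0, 0.0)
        assert modulation_index(phase, amp) == pytest.approx(1.0)

    def test_cosine_envelope_matches_closed_form_binning(self):
        """Oracle: P(j) proportional to the bin-averaged 1 + cos(phase),
        computed from the analytic integral (sin b - sin a)/(b - a)."""
        n_bins = 18
        n = n_bins * 20_000
        phase = -np.pi + (np.arange(n) + 0.5) * (2 * np.pi / n)  # midpoint grid
        amp = 1.0 + np.cos(phase)
        edges = -np.pi + np.arange(n_bins + 1) * (2 * np.pi / n_bins)
        width = 2 * np.pi / n_bins
        bin_means = 1.0 + (np.sin(edges[1:]) - np.sin(edges[:-1])) / width
        P = bin_means / bin_means.sum()
        H = -(P * np.log2(P)).sum()
        expected = (np.log2(n_bins) - H) / np.log2(n_bins)
        assert modulation_index(phase, amp, n_bins) == pytest.approx(expected, abs=1e-6)

    def test_amplitude_scale_invariance_exact(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.exponential(1.0, 5000)
        assert modulation_index(phase, amp) == modulation_index(phase, 3.7 * amp)

    def test_bin_width_phase_shift_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.exponential(1.0, 5000) * (1 + 0.5 * np.cos(phase))
        base = modulation_index(phase, amp)
        shift = 3 * (2 * np.pi / N_BINS_DEFAULT)
        shifted = np.angle(np.exp(1j * (phase + shift)))
        assert modulation_index(shifted, amp) == pytest.approx(base, abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(100, 2000),
           bins=st.integers(2, 36))
    def test_mi_always_in_unit_interval(self, seed, n, bins):
        r = np.random.default_rng(seed)
        mi = modulation_index(r.uniform(-np.pi, np.pi, n), r.exponential(1.0, n), bins)
        assert 0.0 <= mi <= 1.0

    def test_constant_and_zero_amplitude_give_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 1000)
        assert modulation_index(phase, np.full(1000, 2.5)) == 0.0
        with pytest.warns(UserWarning, match="zero"):
            assert modulation_index(phase, np.zeros(1000)) == 0.0

    def test_null_series_bias_is_small(self):
        """Independent phase/amplitude at the study's pooled length."""
        mis = []
        for s in range(20):
            r = np.random.default_rng(s)
            n = 100_000
            mis.append(modulation_index(r.uniform(-np.pi, np.pi, n),
                                        r.exponential(1.0, n)))
        assert np.median(mis) < 0.01


def test_depth_monotonicity_mean_over_seeds():
    means = []
    for depth in (0.0, 0.3, 0.6, 0.9):
        vals = [
            pac_map(generate_subject(pac_design(depth, s), "control", 500 + s)).mi[0]
            for s in range(20)
        ]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2] < means[3]


def test_pac_map_is_deterministic_and_localized():
    d = pac_design(0.8, 3)
    # two ROIs: PAC planted only in ROI 0
    from dataclasses import replace
    d = replace(d, n_roi=2)
    rec = generate_subject(d, "control", 77)
    a = pac_map(rec)
    b = pac_map(rec)
    np.testing.assert_array_equal(a.mi, b.mi)
    assert a.mi[0] > a.mi[1]
    assert np.all((a.mi >= 0) & (a.mi <= 1))


def test_mi_table_stacks_subjects():
    d = pac_design(0.5, 9)
    recs = [generate_subject(d, "control", s, subject_id=f"s{s}") for s in (1, 2)]
    tab = mi_table([pac_map(r) for r in recs])
    assert tab.shape == (2, 1)
    assert list(tab.index) == ["s1", "s2"]
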