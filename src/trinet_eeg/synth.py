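"""Synthetic resting-state cohorts with known, recoverable ground truth.

Every downstream estimator in this package (lagged coherence, theta-gamma
modulation index, permutation group tests, SVM connection ranking) is
validated against cohorts produced here, because the generator plants its
effects in exactly the form those estimators are built to detect:

* **Band-limited oscillators** — narrowband-filtered Gaussian noise placed
  in a declared band, so spectral placement is checkable by periodogram.
* **Lagged coupling** (:class:`CouplingSpec`) — a shared narrowband
  component injected into both ROIs of a pair, with the second copy rotated
  by a constant phase via its analytic signal. With coupling strength
  ``m`` the pair signals are ``m*s + sqrt(1-m^2)*own``, so the band
  coherence magnitude is ~``m^2`` and the planted lag makes it visible to
  the *lagged* (imaginary-part) coherence specifically: a zero lag plants
  purely instantaneous coupling that lagged coherence must ignore.
* **Phase-amplitude coupling** (:class:`PACSpec`) — a narrowband gamma
  carrier whose envelope is scaled by ``(1 + depth*cos(theta_phase))/(1+depth)``,
  plus the theta component itself so the phase is observable. ``depth`` is
  the Tort-style modulation depth; 0 plants nothing, 1 silences the carrier
  at the anti-preferred phase.
* **Two-group designs** (:class:`CohortDesign`) — an effect table maps each
  planted coupling/PAC spec to group-specific strengths/depths, planting
  e.g. a connectivity reduction in the impaired group.

Determinism: every subject's stream is seeded by a SHA-256 hash of
``(design.seed, group, subject index)`` reduced below 2**31, so cohorts are
bit-reproducible across runs and platforms and subjects never share a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .bands import BandSpec, CFC_AMP_BAND, CFC_PHASE_BAND
from .preprocess import bandpass_sos
from .recording import EpochedRecording

GROUP_IMPAIRED = "impaired"
GROUP_CONTROL = "control"

#: seconds of padding generated at each end and discarded after filtering,
#: so planted narrowband components carry no filter edge transients.
_EDGE_PAD_S = 2.0


@dataclass(frozen=True)
class OscillatorSpec:
    """Background band-limited oscillation in one ROI."""

    center_freq: float
    bandwidth: float
    amplitude: float
    roi_index: int

    def __post_init__(self) -> None:
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    @property
    def band(self) -> BandSpec:
        half = self.bandwidth / 2.0
        lo = max(self.center_freq - half, 1e-3)
        return BandSpec("osc", lo, self.center_freq + half)


@dataclass(frozen=True)
class CouplingSpec:
    """Lagged narrowband coupling between two ROIs.

    ``phase_lag`` (radians, in (-pi, pi]) is applied to the second ROI's
    copy of the shared component; ``strength`` in [0, 1] is the mixing
    proportion of the shared component within each ROI's band signal.
    """

    roi_pair: tuple[int, int]
    band: BandSpec
    phase_lag: float = np.pi / 2
    strength: float = 0.5
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        i, j = self.roi_pair
        if i == j:
            raise ValueError("coupling requires two distinct ROIs")
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must lie in [0, 1]")
        if not (-np.pi < self.phase_lag <= np.pi):
            raise ValueError("phase_lag must lie in (-pi, pi]")


@dataclass(frozen=True)
class PACSpec:
    """Theta-phase -> gamma-amplitude modulation planted in one ROI."""

    roi_index: int
    depth: float = 0.5
    phase_band: BandSpec = CFC_PHASE_BAND
    amp_band: BandSpec = CFC_AMP_BAND
    phase_amplitude: float = 1.0
    carrier_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.depth <= 1:
            raise ValueError("depth must lie in [0, 1]")
        if self.phase_band.hi >= self.amp_band.lo:
            raise ValueError("phase band must lie strictly below amplitude band")


@dataclass(frozen=True)
class GroupEffect:
    """Group-specific override of a planted effect's magnitude.

    ``values`` maps group label -> strength (for a CouplingSpec) or depth
    (for a PACSpec); groups absent from the map use the spec's own value.
    """

    spec: CouplingSpec | PACSpec
    values: dict[str, float] = field(default_factory=dict)

    def realized(self, group: str) -> CouplingSpec | PACSpec:
        if group not in self.values:
            return self.spec
        v = self.values[group]
        if isinstance(self.spec, CouplingSpec):
            return replace(self.spec, strength=v)
        return replace(self.spec, depth=v)


@dataclass(frozen=True)
class CohortDesign:
    """Study conditions for a two-group synthetic cohort.

    Defaults emulate roughly five minutes of retained 2-s segments per
    subject at 500 Hz, the scale of a single-session pediatric
    resting-state recording after artifact rejection.
    """

    n_per_group: int = 20
    n_roi: int = 24
    effects: tuple[GroupEffect, ...] = ()
    oscillators: tuple[OscillatorSpec, ...] = ()
    noise_sd: float = 1.0
    sampling_rate: float = 500.0
    epoch_len: float = 2.0
    n_epochs: int = 150
    seed: int = 0
    group_labels: tuple[str, str] = (GROUP_IMPAIRED, GROUP_CONTROL)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if self.n_epochs < 1:
            raise ValueError("need at least one epoch")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        hi = max(self._band_edges(), default=0.0)
        if self.sampling_rate < 2 * hi:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz below Nyquist for "
                f"planted content up to {hi} Hz"
            )
        for eff in self.effects:
            self._check_roi(eff.spec)
        for osc in self.oscillators:
            if not 0 <= osc.roi_index < self.n_roi:
                raise ValueError("oscillator ROI index out of range")

    def _check_roi(self, spec: CouplingSpec | PACSpec) -> None:
        if isinstance(spec, CouplingSpec):
            for r in spec.roi_pair:
                if not 0 <= r < self.n_roi:
                    raise ValueError("coupling ROI index out of range")
        else:
            if not 0 <= spec.roi_index < self.n_roi:
                raise ValueError("PAC ROI index out of range")

    def _band_edges(self) -> list[float]:
        edges = []
        for eff in self.effects:
            s = eff.spec
            if isinstance(s, CouplingSpec):
                edges.append(s.band.hi)
            else:
                edges.append(s.amp_band.hi)
        edges.extend(o.band.hi for o in self.oscillators)
        return edges


def subject_seed(master_seed: int, group: str, index: int) -> int:
    """Stable per-subject seed below 2**31 (SHA-256 of the identifiers)."""
    digest = hashlib.sha256(f"{master_seed}:{group}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _narrowband(rng: np.random.Generator, n: int, band: BandSpec,
                sfreq: float) -> np.ndarray:
    """Unit-variance narrowband Gaussian noise in ``band``."""
    x = rng.standard_normal(n)
    sos = bandpass_sos(band, sfreq)
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _phase_rotate(x: np.ndarray, lag: float) -> np.ndarray:
    """Constant phase rotation of a narrowband signal via its analytic form."""
    return np.real(sps.hilbert(x) * np.exp(-1j * lag))


def generate_subject(design: CohortDesign, group: str, subj_seed: int,
                     subject_id: str | None = None) -> EpochedRecording:
    """One subject's epochs with the design's effects realized for ``group``."""
    if group not in design.group_labels:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subj_seed)
    sfreq = design.sampling_rate
    pad = int(round(_EDGE_PAD_S * sfreq))
    n_keep = int(round(design.epoch_len * sfreq)) * design.n_epochs
    n = n_keep + 2 * pad

    x = np.zeros((design.n_roi, n))
    if design.noise_sd > 0:
        x += design.noise_sd * rng.standard_normal((design.n_roi, n))

    for osc in design.oscillators:
        x[osc.roi_index] += osc.amplitude * _narrowband(rng, n, osc.band, sfreq)

    for eff in design.effects:
        spec = eff.realized(group)
        if isinstance(spec, CouplingSpec):
            i, j = spec.roi_pair
            m = spec.strength
            shared = _narrowband(rng, n, spec.band, sfreq)
            own_i = _narrowband(rng, n, spec.band, sfreq)
            own_j = _narrowband(rng, n, spec.band, sfreq)
            mix = np.sqrt(max(1.0 - m * m, 0.0))
            x[i] += spec.amplitude * (m * shared + mix * own_i)
            x[j] += spec.amplitude * (
                m * _phase_rotate(shared, spec.phase_lag) + mix * own_j
            )
        else:
            theta = _narrowband(rng, n, spec.phase_band, sfreq)
            phase = np.angle(sps.hilbert(theta))
            carrier = _narrowband(rng, n, spec.amp_band, sfreq)
            envelope = (1.0 + spec.depth * np.cos(phase)) / (1.0 + spec.depth)
            x[spec.roi_index] += (
                spec.phase_amplitude * theta
                + spec.carrier_amplitude * carrier * envelope
            )

    kept = x[:, pad:pad + n_keep]
    n_samp = int(round(design.epoch_len * sfreq))
    data = kept.reshape(design.n_roi, design.n_epochs, n_samp).swapaxes(0, 1)
    return EpochedRecording(
        data=np.ascontiguousarray(data),
        sfreq=sfreq,
        ch_names=[f"roi{i:02d}" for i in range(design.n_roi)],
        subject_id=subject_id,
        group=group,
    )


def generate_cohort(design: CohortDesign) -> list[EpochedRecording]:
    """2 * n_per_group labelled subjects with reproducible per-subject seeds."""
    cohort: list[EpochedRecording] = []
    seen: set[str] = set()
    for group in design.group_labels:
        for k in range(design.n_per_group):
            sid = f"{group}_{k:03d}"
            if sid in seen:
                raise ValueError(f"duplicate subject identifier {sid}")
            seen.add(sid)
            cohort.append(
                generate_subject(
                    design, group, subject_seed(design.seed, group, k), sid
                )
            )
    return cohort


def save_cohort(cohort: list[EpochedRecording], directory, design: CohortDesign | None = None):
    """Write one text-format subject directory per recording, plus ground truth."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        rec.save_txt(directory / str(rec.subject_id))
    if design is not None:
        truth = {
            "seed": design.seed,
            "n_per_group": design.n_per_group,
            "sampling_rate": design.sampling_rate,
            "epoch_len": design.epoch_len,
            "n_epochs": design.n_epochs,
            "noise_sd": design.noise_sd,
            "effects": [
                {
                    "kind": type(e.spec).__name__,
                    "spec": {k: (list(v) if isinstance(v, tuple) else
                                 v if not isinstance(v, BandSpec) else
                                 [v.name, v.lo, v.hi])
                             for k, v in e.spec.__dict__.items()},
                    "values": e.values,
                }
                for e in design.effects
            ],
        }
        (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return directory
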