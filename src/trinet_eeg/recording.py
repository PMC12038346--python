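"""Epoched multichannel recordings and their plain-text on-disk layout.

An :class:`EpochedRecording` holds one subject's fixed-length epochs as an
``(n_epochs, n_channels, n_samples)`` array with sampling-rate metadata.
Channels may be scalp electrodes or, after source reconstruction / synthetic
generation, atlas ROI time series — downstream stages only require the
channel-name list to match the atlas they are given.

On disk a subject is a directory of whitespace-separated text matrices, one
file per epoch (rows = channels), plus a JSON sidecar with sampling rate,
channel names and labels. This mirrors the common practice of exporting
cleaned EEG segments to plain text for downstream analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

SIDECAR_NAME = "recording.json"


@dataclass
class EpochedRecording:
    """Fixed-length epochs of multichannel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_epochs, n_channels, n_samples)``.
    sfreq
        Sampling rate in Hz.
    ch_names
        One name per channel/ROI.
    subject_id, group
        Optional labels carried through the pipeline.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str] = field(default_factory=list)
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_epochs, n_channels, n_samples), got shape {self.data.shape}"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length does not match channel axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_len(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.sfreq

    def copy_with(self, **kwargs) -> "EpochedRecording":
        return replace(self, **kwargs)

    def continuous(self) -> np.ndarray:
        """Epochs concatenated along time: ``(n_channels, n_epochs * n_samples)``."""
        return np.concatenate(list(self.data), axis=1)

    # ------------------------------------------------------------------ I/O

    def save_txt(self, directory: str | Path) -> Path:
        """Write one whitespace-separated text file per epoch plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for e in range(self.n_epochs):
            np.savetxt(directory / f"epoch_{e:04d}.txt", self.data[e], fmt="%.10g")
        sidecar = {
            "sfreq": self.sfreq,
            "ch_names": self.ch_names,
            "subject_id": self.subject_id,
            "group": self.group,
            "n_epochs": self.n_epochs,
            "n_samples": self.n_samples,
        }
        (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
        return directory


def load_txt(directory: str | Path) -> EpochedRecording:
    """Read a subject directory written by :meth:`EpochedRecording.save_txt`."""
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    epoch_files = sorted(directory.glob("epoch_*.txt"))
    if not epoch_files:
        raise FileNotFoundError(f"no epoch files in {directory}")
    epochs = [np.atleast_2d(np.loadtxt(f)) for f in epoch_files]
    data = np.stack(epochs)
    return EpochedRecording(
        data=data,
        sfreq=float(meta["sfreq"]),
        ch_names=list(meta["ch_names"]),
        subject_id=meta.get("subject_id"),
        group=meta.get("group"),
    )


def load_matrix(path: str | Path, sfreq: float, epoch_len: float | None = None,
                ch_names: list[str] | None = None) -> EpochedRecording:
    """Read a generic channels x samples text/CSV matrix as a recording.

    If ``epoch_len`` is given the continuous matrix is cut into consecutive
    non-overlapping epochs (trailing remainder discarded); otherwise the
    whole matrix becomes a single epoch.
    """
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else None
    mat = np.atleast_2d(np.loadtxt(path, delimiter=delim))
    if epoch_len is None:
        data = mat[None]
    else:
        n = int(round(epoch_len * sfreq))
        if n <= 0:
            raise ValueError("epoch_len must be positive")
        k = mat.shape[1] // n
        data = np.stack([mat[:, i * n:(i + 1) * n] for i in range(k)]) if k else \
            np.empty((0, mat.shape[0], n))
    return EpochedRecording(data=data, sfreq=sfreq, ch_names=ch_names or [])
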