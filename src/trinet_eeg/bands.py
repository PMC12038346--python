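"""Frequency-band definitions.

Two canonical tables are used at different stages. The analysis table tiles
1-44 Hz into the five classical EEG rhythms and is used for band-wise
connectivity and classification. The cross-frequency-coupling (CFC) table
uses the slightly different theta 4-7 Hz / gamma 30-45 Hz edges conventional
for theta-gamma phase-amplitude coupling. Both are exposed; stages pick the
table that applies to them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges: {self.lo}-{self.hi} Hz")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, freq: float) -> bool:
        return self.lo <= freq <= self.hi


#: Five-band analysis table (connectivity, classification).
ANALYSIS_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 44.0),
)

#: Phase/amplitude bands for theta-gamma coupling.
CFC_PHASE_BAND = BandSpec("theta", 4.0, 7.0)
CFC_AMP_BAND = BandSpec("gamma", 30.0, 45.0)


def band_table() -> dict[str, BandSpec]:
    """Analysis bands keyed by name."""
    return {b.name: b for b in ANALYSIS_BANDS}


def get_band(name: str) -> BandSpec:
    try:
        return band_table()[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of "
            f"{[b.name for b in ANALYSIS_BANDS]}"
        ) from None
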