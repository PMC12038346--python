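"""Region-of-interest atlas and the canonical connection (pair) ordering.

The packaged 24-ROI atlas expands 12 bilateral Brodmann-area regions into
left/right ROIs named ``L_<abbr>`` / ``R_<abbr>``, grouped into five
networks: visual (VN), auditory (AN), default-mode (DMN), salience (SN)
and central-executive (CEN).

Connection features are ordered by the upper triangle of the ROI x ROI
matrix, row-major with i < j over the atlas ROI order. This ordering is
fixed so that ranked classifier weights refer to a stable, documented
feature list (24 ROIs -> 276 pairs). Pair names join the two ROI names
with ``--``, e.g. ``"L_V2--R_INS"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

PAIR_SEP = "--"


@dataclass(frozen=True)
class Atlas:
    """An ordered set of named ROIs with network membership."""

    roi_names: tuple[str, ...]
    networks: dict[str, str] = field(default_factory=dict)  # roi -> network
    region_info: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("duplicate ROI names in atlas")
        missing = [r for r in self.networks if r not in self.roi_names]
        if missing:
            raise ValueError(f"network map references unknown ROIs: {missing}")

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    @property
    def n_pairs(self) -> int:
        n = self.n_roi
        return n * (n - 1) // 2

    def pairs(self) -> list[tuple[int, int]]:
        """Upper-triangle (i, j) index pairs, row-major, i < j."""
        n = self.n_roi
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def pair_names(self) -> list[str]:
        names = self.roi_names
        return [f"{names[i]}{PAIR_SEP}{names[j]}" for i, j in self.pairs()]

    def network_of(self, roi: str) -> str:
        try:
            return self.networks[roi]
        except KeyError:
            raise KeyError(f"ROI {roi!r} has no network assignment") from None

    def network_pair(self, pair_name: str) -> tuple[str, str]:
        """Unordered (sorted) network pair of a named connection."""
        a, b = split_pair(pair_name)
        na, nb = self.network_of(a), self.network_of(b)
        return tuple(sorted((na, nb)))  # type: ignore[return-value]

    def index(self, roi: str) -> int:
        return self.roi_names.index(roi)


def split_pair(pair_name: str) -> tuple[str, str]:
    parts = pair_name.split(PAIR_SEP)
    if len(parts) != 2:
        raise ValueError(f"malformed pair name {pair_name!r}")
    return parts[0], parts[1]


def load_atlas(path: str | Path | None = None) -> Atlas:
    """Load an atlas from a JSON resource.

    With no argument, loads the packaged 24-ROI triple-network atlas.
    The JSON lists bilateral regions; each expands to ``L_`` and ``R_``
    ROIs in table order (left before right within each region).
    """
    if path is None:
        text = (
            resources.files("trinet_eeg.data").joinpath("atlas24.json").read_text()
        )
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"atlas file not found: {path}")
        text = path.read_text()
    spec = json.loads(text)

    roi_names: list[str] = []
    networks: dict[str, str] = {}
    info: list[dict] = []
    for region in spec["regions"]:
        for side in ("L", "R"):
            roi = f"{side}_{region['abbr']}"
            roi_names.append(roi)
            networks[roi] = region["network"]
            info.append({**region, "side": side, "roi": roi})
    return Atlas(tuple(roi_names), networks, tuple(info))


def toy_atlas(n_roi: int, n_networks: int = 2) -> Atlas:
    """Small synthetic atlas (``ROI00``...) for tests and demos."""
    names = tuple(f"ROI{i:02d}" for i in range(n_roi))
    nets = {name: f"NET{i % n_networks}" for i, name in enumerate(names)}
    return Atlas(names, nets)
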