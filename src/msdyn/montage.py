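"""Electrode montage: channel names and 2-D head-circle positions.

Positions use the schematic top-view layout standard in EEG topographic
plotting: the head is the unit circle, +x is the subject's right, +y is
anterior. Only relative geometry matters here (template construction and
bad-channel interpolation); no forward model is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "standard_montage"]

# 10-20 / 10-10 names of a 32-channel cap minus the two mastoids.
# Circle electrodes are parameterized by their angle on the head outline.
_CIRCLE = {
    "Fp1": 108.0, "Fp2": 72.0,
    "F7": 144.0, "F8": 36.0,
    "FT7": 162.0, "FT8": 18.0,
    "T7": 180.0, "T8": 0.0,
    "TP7": 198.0, "TP8": -18.0,
    "P7": 216.0, "P8": -36.0,
    "O1": 252.0, "O2": -72.0,
    "Oz": 270.0,
}
_INNER = {
    "F3": (-0.40, 0.55), "Fz": (0.0, 0.55), "F4": (0.40, 0.55),
    "FC3": (-0.45, 0.28), "FCz": (0.0, 0.28), "FC4": (0.45, 0.28),
    "C3": (-0.50, 0.0), "Cz": (0.0, 0.0), "C4": (0.50, 0.0),
    "CP3": (-0.45, -0.28), "CPz": (0.0, -0.28), "CP4": (0.45, -0.28),
    "P3": (-0.40, -0.55), "Pz": (0.0, -0.55), "P4": (0.40, -0.55),
}
# Mastoids sit below/behind the ears, outside the schematic circle.
_MASTOIDS = {"M1": (-1.15, -0.40), "M2": (1.15, -0.40)}


@dataclass
class Montage:
    """Channel labels with 2-D projected positions.

    Parameters
    ----------
    ch_names
        Unique channel labels.
    pos
        Array of shape (n_channels, 2), finite head-circle coordinates.
    mastoids
        Labels of the two mastoid reference electrodes, if present in
        ``ch_names``.
    """

    ch_names: list[str]
    pos: np.ndarray
    mastoids: tuple[str, str] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if len(self.ch_names) != len(set(self.ch_names)):
            raise ValueError("channel labels must be unique")
        if self.pos.shape != (len(self.ch_names), 2):
            raise ValueError("pos must be (n_channels, 2)")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("positions must be finite")
        if self.mastoids is not None:
            for m in self.mastoids:
                if m not in self.ch_names:
                    raise ValueError(f"mastoid {m!r} not in channel list")
        self._index = {name: i for i, name in enumerate(self.ch_names)}

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def index(self, name: str) -> int:
        return self._index[name]

    def scalp_names(self) -> list[str]:
        """Channel labels excluding the mastoids."""
        drop = set(self.mastoids or ())
        return [c for c in self.ch_names if c not in drop]

    def subset(self, names: list[str]) -> "Montage":
        idx = [self._index[n] for n in names]
        mast = self.mastoids if self.mastoids and all(m in names for m in self.mastoids) else None
        return Montage(list(names), self.pos[idx], mast)


def standard_montage(include_mastoids: bool = False) -> Montage:
    """The 30-channel 10-20 scalp montage used throughout the package.

    This is a 32-channel cap with M1/M2 reserved for referencing; with
    ``include_mastoids=True`` the two mastoids are appended.
    """
    names: list[str] = []
    pos: list[tuple[float, float]] = []
    for name, ang in _CIRCLE.items():
        a = math.radians(ang)
        names.append(name)
        pos.append((math.cos(a), math.sin(a)))
    for name, xy in _INNER.items():
        names.append(name)
        pos.append(xy)
    mastoids = None
    if include_mastoids:
        for name, xy in _MASTOIDS.items():
            names.append(name)
            pos.append(xy)
        mastoids = ("M1", "M2")
    return Montage(names, np.array(pos), mastoids)
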