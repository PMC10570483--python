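"""The in-memory container for one multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

__all__ = ["Recording", "SubjectExcluded", "merge_intervals"]


class SubjectExcluded(Exception):
    """Raised when a recording fails a subject-level quality rule
    (more than three damaged channels)."""


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open sample intervals, sorted and non-overlapping."""
    out: list[tuple[int, int]] = []
    for start, end in sorted((int(a), int(b)) for a, b in intervals):
        if start >= end:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class Recording:
    """Channels x samples voltage matrix with metadata.

    ``annotations`` are bad-segment intervals in half-open 0-based sample
    coordinates; they are kept as a mask rather than spliced out so sample
    indices stay aligned with any ground truth. ``bad_channels`` lists
    damaged channels awaiting interpolation.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    annotations: list[tuple[int, int]] = field(default_factory=list)
    bad_channels: list[str] = field(default_factory=list)
    subject_id: str = ""
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("row count must equal number of channel labels")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        for start, end in self.annotations:
            if not (0 <= start <= end <= self.n_samples):
                raise ValueError(f"annotation [{start}, {end}) outside recording")
        for ch in self.bad_channels:
            if ch not in self.ch_names:
                raise ValueError(f"bad channel {ch!r} not in channel list")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def good_mask(self) -> np.ndarray:
        """Boolean per-sample mask, True where no bad segment covers the sample."""
        mask = np.ones(self.n_samples, dtype=bool)
        for start, end in self.annotations:
            mask[start:end] = False
        return mask

    def usable_seconds(self) -> float:
        return float(self.good_mask().sum()) / self.sfreq

    def copy(self, **changes) -> "Recording":
        rec = replace(self, **changes)
        if "data" not in changes:
            rec.data = self.data.copy()
        rec.annotations = list(rec.annotations)
        rec.bad_channels = list(rec.bad_channels)
        return rec
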