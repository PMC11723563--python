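"""Shared domain types: frequency bands, HFO pulse trains, recordings.

All signal amplitudes in this package are in microvolts (uV), times in
seconds and frequencies in Hz unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BandSpec",
    "RIPPLE",
    "FAST_RIPPLE",
    "Pulse",
    "HfoTrain",
    "ChannelTruth",
    "Recording",
]


@dataclass(frozen=True)
class BandSpec:
    """A detection frequency band.

    The two canonical bands are the ripple band (80-250 Hz) and the fast
    ripple band (250-500 Hz).
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(f"invalid band limits ({self.low}, {self.high})")

    def validate_fs(self, fs: float) -> None:
        # the upper edge may sit exactly at Nyquist (fs=1000 with FR 250-500);
        # anything beyond that is unrepresentable
        if self.high > fs / 2 + 1e-9:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz exceeds Nyquist "
                f"({fs / 2} Hz)"
            )


RIPPLE = BandSpec("ripple", 80.0, 250.0)
FAST_RIPPLE = BandSpec("fast_ripple", 250.0, 500.0)

_BANDS = {b.name: b for b in (RIPPLE, FAST_RIPPLE)}


def get_band(name_or_band) -> BandSpec:
    if isinstance(name_or_band, BandSpec):
        return name_or_band
    try:
        return _BANDS[str(name_or_band)]
    except KeyError:
        raise ValueError(
            f"unknown band {name_or_band!r}; expected one of {sorted(_BANDS)}"
        ) from None


@dataclass(frozen=True)
class Pulse:
    """One injected oscillatory burst."""

    onset: float  # s from record start
    duration: float  # s
    amplitude: float  # uV, peak of the envelope
    f0: float  # Hz, intra-burst oscillation frequency
    phase: float = 0.0  # rad

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class HfoTrain:
    """A sorted train of injected HFO pulses on one channel."""

    pulses: list[Pulse]
    band: str = "fast_ripple"

    def __post_init__(self) -> None:
        onsets = [p.onset for p in self.pulses]
        if onsets != sorted(onsets):
            raise ValueError("pulses must be sorted by onset")

    def __len__(self) -> int:
        return len(self.pulses)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [onset, offset] in seconds."""
        if not self.pulses:
            return np.empty((0, 2))
        return np.array([[p.onset, p.offset] for p in self.pulses])


@dataclass
class ChannelTruth:
    """Ground truth attached to one simulated channel."""

    trains: list[HfoTrain]
    rho_hfog: float


@dataclass
class Recording:
    """Multichannel time series in uV.

    data is (n_channels, n_samples); ``ground_truth`` (when the recording
    came from the simulator) holds one :class:`ChannelTruth` per channel.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    layout: Optional[object] = None  # GridLayout, kept loose to avoid cycles
    ground_truth: Optional[list[ChannelTruth]] = None
    electrode_area: Optional[float] = None  # mm^2, effective contact area
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.ground_truth is not None:
            dur = self.duration
            for truth in self.ground_truth:
                for train in truth.trains:
                    for p in train.pulses:
                        if p.offset > dur + 1e-9:
                            raise ValueError("ground-truth pulse beyond record end")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)

    def copy_with(self, data: np.ndarray, channel_ids: Sequence[str] | None = None,
                  **meta_updates) -> "Recording":
        meta = dict(self.meta, **meta_updates)
        return Recording(
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            channel_ids=list(channel_ids) if channel_ids is not None else list(self.channel_ids),
            layout=self.layout,
            ground_truth=None,
            electrode_area=self.electrode_area,
            meta=meta,
        )
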