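"""HFO characteristics: amplitude, peak frequency, rates, spatial spread.

Amplitude is the mean of the upper Hilbert (analytic-signal) envelope over
the event.  Peak frequency is the in-band argmax of the Fourier magnitude
after whitening (first difference by default).  Spread S counts the
distinct channels of a group of temporally overlapping events.  The global
rate per area divides the number of unique event groups per minute by the
summed physical contact area of the grid, which is identical across
shorting schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.signal import windows as _windows

from .core import BandSpec, get_band
from .detect import HfoEvent
from .grid import ShortingScheme

__all__ = [
    "EventGroup",
    "RateSummary",
    "event_amplitude",
    "event_peak_frequency",
    "group_events",
    "channel_rates",
    "global_rate_per_area",
]


@dataclass
class EventGroup:
    """A connected component of temporally overlapping events."""

    members: list[HfoEvent]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group needs at least one member")

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.members), max(e.end for e in self.members))

    @property
    def spread(self) -> int:
        """S: number of distinct channels in which the event was observed."""
        return len({e.channel for e in self.members})


@dataclass
class RateSummary:
    per_channel: dict[str, float]  # events/min
    global_rate: float  # unique groups / min
    global_rate_per_area: float  # events/min/mm^2
    band: str
    config_label: str = ""


def event_amplitude(ev: HfoEvent, xf: np.ndarray, fs: float,
                    pad: float = 0.050) -> float:
    """Mean upper Hilbert envelope over the event (uV).

    The analytic signal is computed over the event plus >= 50 ms padding on
    each side to limit edge effects, then cropped back to the event.
    Events at the record edge are padded by reflection and flagged.
    """
    xf = np.asarray(xf, dtype=float)
    n_pad = int(round(pad * fs))
    lo = ev.start - n_pad
    hi = ev.end + n_pad
    seg = xf[max(0, lo):min(len(xf), hi)]
    pre = -lo if lo < 0 else 0
    post = hi - len(xf) if hi > len(xf) else 0
    if pre or post:
        seg = np.pad(seg, (pre, post), mode="reflect")
        if "edge_padded" not in ev.flags:
            ev.flags.append("edge_padded")
    env = np.abs(hilbert(seg))
    start_in_seg = ev.start - lo
    return float(np.mean(env[start_in_seg:start_in_seg + (ev.end - ev.start)]))


def event_peak_frequency(ev: HfoEvent, x: np.ndarray, fs: float,
                         band: BandSpec | str, whiten: str = "diff",
                         min_resolution: float = 1.0) -> float:
    """In-band spectral argmax after whitening; NaN for too-short events.

    An event must span at least two cycles of the band's lower edge for the
    peak to be resolvable.  Whitening is a first-order difference by
    default ("spectral" divides the magnitude by a smoothed version of
    itself instead).
    """
    band = get_band(band)
    seg = np.asarray(x[ev.start:ev.end], dtype=float)
    if len(seg) / fs < 2.0 / band.low:
        return float("nan")
    if whiten == "diff":
        seg = np.diff(seg)
    seg = seg * _windows.hann(len(seg), sym=True)
    nfft = max(int(np.ceil(fs / min_resolution)), len(seg))
    spec = np.abs(np.fft.rfft(seg, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    if whiten == "spectral":
        smooth = np.convolve(spec, np.ones(25) / 25, mode="same")
        spec = spec / np.maximum(smooth, 1e-12)
    in_band = (freqs >= band.low) & (freqs <= band.high)
    return float(freqs[in_band][np.argmax(spec[in_band])])


def group_events(events: list[HfoEvent]) -> list[EventGroup]:
    """Connected components of the temporal-overlap graph.

    Intervals overlap iff their intersection has strictly positive length;
    chaining is transitive (A-B and B-C join A and C even if A and C are
    disjoint).  A single sorted sweep suffices because interval graphs'
    components are contiguous in start order.
    """
    if not events:
        return []
    order = sorted(events, key=lambda e: (e.start, e.end))
    groups: list[EventGroup] = [EventGroup([order[0]])]
    reach = order[0].end
    for ev in order[1:]:
        if ev.start < reach:  # strictly positive intersection
            groups[-1].members.append(ev)
            reach = max(reach, ev.end)
        else:
            groups.append(EventGroup([ev]))
            reach = ev.end
    return groups


def channel_rates(events: list[HfoEvent], duration_min: float,
                  channel_ids: list[str] | None = None) -> dict[str, float]:
    """Events per minute per channel; channels without events report 0."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    ids = list(channel_ids) if channel_ids is not None else sorted({e.channel for e in events})
    counts = {cid: 0 for cid in ids}
    for ev in events:
        counts.setdefault(ev.channel, 0)
        counts[ev.channel] += 1
    return {cid: n / duration_min for cid, n in counts.items()}


def global_rate_per_area(groups: list[EventGroup], duration_min: float,
                         scheme: ShortingScheme) -> float:
    """Unique events per minute per mm^2 of summed physical contact area.

    Overlapping duplicates across channels were already collapsed into
    groups, so each group counts once; the summed physical area (64 x 1.08
    = 69.12 mm^2 on the default grid) is the same for every scheme.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return len(groups) / duration_min / scheme.total_area
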