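"""Two-threshold RMS HFO detector with artifact rejection.

Stage 1 marks candidate events where the 3 ms sliding-window RMS envelope
stays above T1 = mean + n_sd * SD for at least 6 ms (candidates closer than
``merge_gap`` merge first).  Stage 2 keeps candidates whose rectified
band-passed signal shows at least ``min_peaks`` (default 6) local maxima
above a second threshold T2 = mean + n_sd * SD of the rectified signal.
Thresholds are recomputed per channel per one-minute segment.  Detections
are invariant under uniform positive scaling of a segment because both
thresholds are linear in the data.

Artifact rejection removes (a) events that co-occur with detections on the
common-average-reference signal and (b) events whose wide-band surroundings
contain a DC step or whose band-limited energy is dominated by a single
sample-to-sample jump (fast transient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .core import BandSpec, Recording, get_band

__all__ = [
    "DetectorParams",
    "HfoEvent",
    "preprocess",
    "rms_envelope",
    "stage1_candidates",
    "stage2_qualify",
    "reject_artifacts",
    "detect_hfos",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    rms_window: float = 0.003  # s, sliding RMS window
    min_duration: float = 0.006  # s, minimum supra-threshold duration
    n_sd: float = 3.0  # SD multiplier for both thresholds
    min_peaks: int = 6  # rectified peaks above T2 required
    merge_gap: float = 0.020  # s, candidates closer than this merge
    segment_length: float = 60.0  # s, thresholds recomputed per segment
    threshold_reference: str = "rms"  # "rms": T1 from the envelope; "rectified": from |xf|
    peak_mode: str = "crossings"  # "crossings": upward T2 crossings; "maxima": strict local maxima
    bp_order: int = 6  # Butterworth band-pass order (applied zero-phase)
    notch_q: float = 35.0  # quality factor of the line-harmonic notches
    # artifact-rejection constants (approximations of published criteria)
    step_window: float = 0.100  # s, wide-band context examined around an event
    step_block: float = 0.010  # s, block length for step level estimation
    step_n_sd: float = 5.0  # step threshold in wide-band segment SDs
    spike_energy_fraction: float = 0.2  # max single-jump share of diff energy

    def __post_init__(self) -> None:
        if min(self.rms_window, self.min_duration, self.n_sd, self.merge_gap,
               self.segment_length) <= 0:
            raise ValueError("detector parameters must be positive")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")
        if self.threshold_reference not in ("rms", "rectified"):
            raise ValueError("threshold_reference must be 'rms' or 'rectified'")
        if self.peak_mode not in ("crossings", "maxima"):
            raise ValueError("peak_mode must be 'crossings' or 'maxima'")


@dataclass
class HfoEvent:
    """One detected (or injected-and-recovered) HFO.

    start/end are 0-based half-open sample indices in the full record.
    """

    channel: str
    band: str
    start: int
    end: int
    fs: float
    amplitude: float = np.nan  # uV, mean Hilbert envelope over the event
    peak_frequency: float = np.nan  # Hz
    n_peaks: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")

    @property
    def start_s(self) -> float:
        return self.start / self.fs

    @property
    def end_s(self) -> float:
        return self.end / self.fs

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fs

    def overlaps(self, other: "HfoEvent") -> bool:
        """Strictly positive temporal intersection (half-open intervals)."""
        return self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# preprocessing


def _design_bandpass(band: BandSpec, fs: float, order: int):
    high = band.high
    if high >= 0.98 * fs / 2:
        # upper edge at (or within 2% of) Nyquist: band-pass degenerates to
        # a high-pass, which is the representable equivalent
        return signal.butter(order, band.low, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, [band.low, high], btype="bandpass", fs=fs, output="sos")


def _line_harmonics(band: BandSpec, fs: float, mains: float = 60.0) -> list[float]:
    """Odd mains harmonics that fall strictly inside the band (and below Nyquist)."""
    out = []
    k = 1
    while True:
        f = mains * (2 * k - 1)
        if f >= fs / 2:
            break
        if band.low < f < band.high:
            out.append(f)
        k += 1
    return out


def preprocess(rec: Recording, band: BandSpec | str,
               params: DetectorParams | None = None) -> Recording:
    """Zero-phase band-pass plus notches at in-band odd 60 Hz harmonics."""
    band = get_band(band)
    params = params or DetectorParams()
    band.validate_fs(rec.fs)
    if rec.fs < 2 * band.low:
        raise ValueError("sampling rate too low for this band")
    sos = _design_bandpass(band, rec.fs, params.bp_order)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    for f in _line_harmonics(band, rec.fs):
        b, a = signal.iirnotch(f, params.notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return rec.copy_with(out, band=band.name)


def rms_envelope(x: np.ndarray, fs: float, window: float = 0.003) -> np.ndarray:
    """Centered sliding-window RMS, same length as x; edges use truncated windows."""
    x = np.asarray(x, dtype=float)
    w = int(round(window * fs))
    if w < 2:
        raise ValueError("RMS window must span at least 2 samples")
    kernel = np.ones(w)
    num = signal.convolve(x**2, kernel, mode="same")
    den = signal.convolve(np.ones_like(x), kernel, mode="same")
    return np.sqrt(num / den)


# ---------------------------------------------------------------------------
# detection stages


def _threshold(ref: np.ndarray, n_sd: float) -> float | None:
    sd = float(np.std(ref))
    if sd == 0.0:
        return None
    return float(np.mean(ref)) + n_sd * sd


def _supra_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open (start, end) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def stage1_candidates(env: np.ndarray, fs: float, params: DetectorParams,
                      rectified: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Supra-T1 runs of the RMS envelope lasting >= min_duration.

    T1 is mean + n_sd * SD of the envelope itself (default), or of the
    rectified band-passed signal when threshold_reference == "rectified".
    Runs separated by gaps shorter than merge_gap merge before the
    duration test.  A zero-variance segment yields no candidates.
    """
    ref = env if params.threshold_reference == "rms" else rectified
    if ref is None:
        raise ValueError("threshold_reference='rectified' requires the rectified signal")
    t1 = _threshold(ref, params.n_sd)
    if t1 is None:
        logger.warning("zero-variance segment: skipping stage-1 detection")
        return []
    runs = _supra_runs(np.asarray(env) > t1)
    if not runs:
        return []
    gap = params.merge_gap * fs
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = params.min_duration * fs
    return [(s, e) for s, e in merged if e - s >= min_len]


def _count_peaks_above(r: np.ndarray, thresh: float, mode: str = "crossings") -> int:
    """Supra-threshold peaks of the rectified signal r.

    "crossings" counts upward crossings of the threshold (one per rectified
    half-wave that exceeds it), which stays reliable down to ~2 samples per
    cycle.  "maxima" counts strict sample-level local maxima above the
    threshold; plateaus count once (leftmost sample).
    """
    if mode == "crossings":
        above = np.asarray(r) > thresh
        return int(np.count_nonzero(above[1:] & ~above[:-1]) + (1 if above[0] else 0))
    n = len(r)
    count = 0
    i = 1
    while i < n - 1:
        if r[i] > r[i - 1]:
            j = i
            while j < n - 1 and r[j + 1] == r[i]:
                j += 1
            if j < n - 1 and r[j + 1] < r[i] and r[i] > thresh:
                count += 1
            i = j + 1
        else:
            i += 1
    return count


def stage2_qualify(xf: np.ndarray, candidates: Sequence[tuple[int, int]], fs: float,
                   params: DetectorParams, channel: str = "E00",
                   band: str = "fast_ripple", offset: int = 0) -> list[HfoEvent]:
    """Keep candidates with >= min_peaks rectified peaks above T2.

    T2 is mean + n_sd * SD of the rectified signal over the whole segment.
    ``offset`` shifts local candidate indices to absolute sample coordinates.
    """
    r = np.abs(np.asarray(xf, dtype=float))
    t2 = _threshold(r, params.n_sd)
    if t2 is None:
        return []
    events = []
    for s, e in candidates:
        n_peaks = _count_peaks_above(r[s:e], t2, params.peak_mode)
        if n_peaks >= params.min_peaks:
            events.append(HfoEvent(channel=channel, band=band, start=s + offset,
                                   end=e + offset, fs=fs, n_peaks=n_peaks))
    return events


# ---------------------------------------------------------------------------
# artifact rejection


def _has_dc_step(x_wide: np.ndarray, ev: HfoEvent, fs: float,
                 params: DetectorParams, seg_sd: float) -> bool:
    """Adjacent block-mean jump > step_n_sd * segment SD near the event."""
    pad = int(round(params.step_window * fs))
    lo = max(0, ev.start - pad)
    hi = min(len(x_wide), ev.end + pad)
    block = max(2, int(round(params.step_block * fs)))
    seg = x_wide[lo:hi]
    n_blocks = len(seg) // block
    if n_blocks < 2 or seg_sd == 0:
        return False
    means = seg[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return bool(np.max(np.abs(np.diff(means))) > params.step_n_sd * seg_sd)


def _is_spike(x_wide: np.ndarray, ev: HfoEvent, params: DetectorParams) -> bool:
    """Single sample-to-sample jump carrying > spike_energy_fraction of the
    event's first-difference energy marks a fast transient."""
    d = np.diff(x_wide[ev.start:ev.end])
    total = float(np.sum(d**2))
    if total == 0:
        return False
    return float(np.max(d**2)) / total > params.spike_energy_fraction


def _detect_events_raw(x: np.ndarray, fs: float, band: BandSpec,
                       params: DetectorParams, channel: str) -> list[HfoEvent]:
    """stage1 + stage2 per segment on one already-filtered channel."""
    events: list[HfoEvent] = []
    for s0, s1 in _segment_bounds(len(x), fs, params.segment_length):
        seg = x[s0:s1]
        env = rms_envelope(seg, fs, params.rms_window)
        rect = np.abs(seg)
        cands = stage1_candidates(env, fs, params, rectified=rect)
        events.extend(stage2_qualify(seg, cands, fs, params, channel=channel,
                                     band=band.name, offset=s0))
    return events


def reject_artifacts(events: Sequence[HfoEvent], rec_wideband: Recording,
                     car_signal: np.ndarray | None, band: BandSpec | str,
                     params: DetectorParams | None = None) -> list[HfoEvent]:
    """Drop CAR-coincident events, DC-step contexts and single-sample spikes."""
    band = get_band(band)
    params = params or DetectorParams()
    car_events: list[HfoEvent] = []
    if car_signal is not None:
        car_rec = Recording(np.asarray(car_signal)[np.newaxis, :], rec_wideband.fs, ["CAR"])
        car_f = preprocess(car_rec, band, params)
        car_events = _detect_events_raw(car_f.data[0], car_rec.fs, band, params, "CAR")
    else:
        logger.info("no CAR signal supplied: skipping CAR-coincidence rule")

    seg_len = params.segment_length
    kept: list[HfoEvent] = []
    for ev in events:
        ch = rec_wideband.channel_index(ev.channel)
        x_wide = rec_wideband.data[ch]
        bounds = _segment_bounds(len(x_wide), ev.fs, seg_len)
        s0, s1 = next((b for b in bounds if b[0] <= ev.start < b[1]), bounds[-1])
        seg_sd = float(np.std(x_wide[s0:s1]))
        if any(ev.overlaps(ce) for ce in car_events):
            ev.flags.append("car")
        if _has_dc_step(x_wide, ev, ev.fs, params, seg_sd):
            ev.flags.append("dc_step")
        if _is_spike(x_wide, ev, params):
            ev.flags.append("spike")
        if not ev.flags:
            kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# top level


def _segment_bounds(n: int, fs: float, segment_length: float) -> list[tuple[int, int]]:
    """One-minute (by default) segments; a short tail merges into the
    previous segment when it is under a tenth of the segment length."""
    step = int(round(segment_length * fs))
    bounds = [(s, min(s + step, n)) for s in range(0, n, step)]
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < step // 10:
        bounds[-2] = (bounds[-2][0], n)
        bounds.pop()
    return bounds


def detect_hfos(rec: Recording, band: BandSpec | str,
                params: DetectorParams | None = None,
                car_signal: np.ndarray | None = None,
                reject: bool = True,
                compute_features: bool = True) -> list[HfoEvent]:
    """Full per-channel, per-segment detection pipeline.

    Returns events in absolute sample coordinates with amplitude (mean
    Hilbert envelope), peak frequency and peak count attached.  The whole
    chain is deterministic.
    """
    band = get_band(band)
    params = params or DetectorParams()
    if rec.duration < params.segment_length:
        logger.info("record shorter than one segment: processing as a single segment")
    filtered = preprocess(rec, band, params)
    events: list[HfoEvent] = []
    for ch, cid in enumerate(rec.channel_ids):
        events.extend(_detect_events_raw(filtered.data[ch], rec.fs, band, params, cid))
    if reject:
        events = reject_artifacts(events, rec, car_signal, band, params)
    if compute_features:
        from . import features  # local import: features depends on HfoEvent

        for ev in events:
            xf = filtered.data[rec.channel_index(ev.channel)]
            ev.amplitude = features.event_amplitude(ev, xf, rec.fs)
            ev.peak_frequency = features.event_peak_frequency(ev, xf, rec.fs, band)
    events.sort(key=lambda e: (e.start, e.channel))
    return events
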