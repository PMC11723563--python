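"""Readers/writers: EDF+, HDF5 container with ground truth, event tables.

EDF is the clinical interchange format for iEEG; it is 16-bit, so a write/
read round trip is exact only to one quantization step.  The HDF5 container
is lossless and additionally carries the simulator's ground-truth event
table and configuration.  Reading EDF goes through :mod:`mne`; writing uses
a self-contained minimal EDF+ encoder (1-second data records, zero-padded
tail).
"""

from __future__ import annotations

import datetime as _dt
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .core import ChannelTruth, HfoTrain, Pulse, Recording
from .detect import HfoEvent

__all__ = [
    "write_edf",
    "read_edf",
    "write_container",
    "read_container",
    "read_recording",
    "events_to_frame",
    "frame_to_events",
    "write_events",
    "write_groups",
    "write_rate_summary",
    "rate_heatmap_frame",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# EDF+


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF+ (physical units uV).

    Uses 1-second data records; the final partial record is zero-padded, so
    a reader may return up to fs-1 trailing padding samples.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_sig, n_records * fs))
    data[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.0001
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii(now.strftime("%d.%m.%y"), 8),
        _ascii(now.strftime("%H.%M.%S"), 8),
        _ascii(256 * (1 + n_sig), 8),
        _ascii("EDF+C", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(n_sig, 4),
    ])
    fields = [
        [_ascii(cid, 16) for cid in rec.channel_ids],
        [_ascii("AgAgCl electrode", 80)] * n_sig,
        [_ascii("uV", 8)] * n_sig,
        [_ascii(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_sig)],
        [_ascii(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_sig)],
        [_ascii(dig_min, 8)] * n_sig,
        [_ascii(dig_max, 8)] * n_sig,
        [_ascii("", 80)] * n_sig,
        [_ascii(fs, 8)] * n_sig,
        [_ascii("", 32)] * n_sig,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            for i in range(n_sig):
                chunk = data[i, r * fs:(r + 1) * fs]
                dig = np.round((chunk - phys_min[i]) * scale[i] + dig_min)
                fh.write(struct.pack(f"<{fs}h", *dig.astype(np.int16)))


def read_edf(path: str | Path, layout=None) -> Recording:
    """Read an EDF/EDF+ file through mne; signals returned in uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> uV
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_ids=[c.strip() for c in raw.ch_names],
        layout=layout,
    )


# ---------------------------------------------------------------------------
# HDF5 container

_TRUTH_COLS = ["channel", "onset_s", "duration_s", "amplitude_uV", "f0_hz",
               "phase_rad", "band", "rho_hfog"]


def ground_truth_frame(rec: Recording) -> pd.DataFrame:
    """Flatten per-channel ground truth into one table."""
    rows = []
    if rec.ground_truth:
        for cid, truth in zip(rec.channel_ids, rec.ground_truth):
            for train in truth.trains:
                for p in train.pulses:
                    rows.append((cid, p.onset, p.duration, p.amplitude, p.f0,
                                 p.phase, train.band, truth.rho_hfog))
    return pd.DataFrame(rows, columns=_TRUTH_COLS)


def write_container(rec: Recording, path: str | Path, config: dict | None = None) -> None:
    """Lossless HDF5 container with embedded ground-truth table."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["fs"] = rec.fs
        f.attrs["channel_ids"] = json.dumps(rec.channel_ids)
        if rec.electrode_area is not None:
            f.attrs["electrode_area"] = rec.electrode_area
        f.attrs["meta"] = json.dumps(rec.meta, default=float)
        if config is not None:
            f.attrs["config"] = json.dumps(config, default=float)
        gt = ground_truth_frame(rec)
        grp = f.create_group("ground_truth")
        for col in _TRUTH_COLS:
            vals = gt[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)


def read_container(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        channel_ids = json.loads(f.attrs["channel_ids"])
        meta = json.loads(f.attrs.get("meta", "{}"))
        area = float(f.attrs["electrode_area"]) if "electrode_area" in f.attrs else None
        grp = f["ground_truth"]
        cols = {c: grp[c][()] for c in _TRUTH_COLS}
    n = len(cols["onset_s"])
    truth = None
    if n or True:
        by_channel: dict[str, dict] = {cid: {} for cid in channel_ids}
        for i in range(n):
            cid = cols["channel"][i].decode()
            band = cols["band"][i].decode()
            by_channel[cid].setdefault("rho", float(cols["rho_hfog"][i]))
            by_channel[cid].setdefault("trains", {}).setdefault(band, []).append(
                Pulse(
                    onset=float(cols["onset_s"][i]),
                    duration=float(cols["duration_s"][i]),
                    amplitude=float(cols["amplitude_uV"][i]),
                    f0=float(cols["f0_hz"][i]),
                    phase=float(cols["phase_rad"][i]),
                )
            )
        truth = []
        for cid in channel_ids:
            entry = by_channel[cid]
            trains = [HfoTrain(pulses=ps, band=b)
                      for b, ps in entry.get("trains", {}).items()]
            truth.append(ChannelTruth(trains=trains, rho_hfog=entry.get("rho", np.nan)))
    return Recording(data=data, fs=fs, channel_ids=channel_ids,
                     ground_truth=truth, electrode_area=area, meta=meta)


def read_recording(path: str | Path, format: str | None = None, layout=None) -> Recording:
    """Dispatch on format ("edf" | "container") or file suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() in (".edf", ".rec") else "container"
    if format == "edf":
        return read_edf(path, layout=layout)
    if format == "container":
        return read_container(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# event / group / rate tables

_EVENT_COLS = ["channel", "band", "start_s", "end_s", "duration_ms",
               "amplitude_uV", "peak_freq_hz", "n_peaks", "artifact_flags"]


def events_to_frame(events: list[HfoEvent]) -> pd.DataFrame:
    rows = [
        (e.channel, e.band, e.start_s, e.end_s, e.duration_s * 1e3,
         e.amplitude, e.peak_frequency, e.n_peaks, "|".join(e.flags))
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLS)


def frame_to_events(df: pd.DataFrame, fs: float) -> list[HfoEvent]:
    events = []
    for row in df.itertuples(index=False):
        flags = [f for f in str(row.artifact_flags).split("|") if f and f != "nan"]
        events.append(HfoEvent(
            channel=row.channel, band=row.band,
            start=int(round(row.start_s * fs)), end=int(round(row.end_s * fs)),
            fs=fs, amplitude=row.amplitude_uV, peak_frequency=row.peak_freq_hz,
            n_peaks=int(row.n_peaks), flags=flags,
        ))
    return events


def write_events(events: list[HfoEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def write_groups(groups, fs: float, path: str | Path) -> None:
    rows = []
    for gid, g in enumerate(groups):
        s0, s1 = g.span
        rows.append((gid, s0 / fs, s1 / fs, g.spread, len(g.members),
                     "|".join(f"{e.channel}:{e.start}" for e in g.members)))
    pd.DataFrame(rows, columns=["group_id", "span_start_s", "span_end_s",
                                "spread", "n_members", "member_ids"]).to_csv(path, index=False)


def write_rate_summary(summary, path: str | Path) -> None:
    d = {
        "band": summary.band,
        "config_label": summary.config_label,
        "global_rate": summary.global_rate,
        "global_rate_per_area": summary.global_rate_per_area,
        "per_channel": summary.per_channel,
    }
    Path(path).write_text(json.dumps(d, indent=2))


def rate_heatmap_frame(rates: dict[str, float], layout) -> pd.DataFrame:
    """Per-channel rates as an n_rows x n_cols matrix (grid coordinates)."""
    mat = np.full((layout.n_rows, layout.n_cols), np.nan)
    for cid, rate in rates.items():
        r, c = layout.positions[cid]
        mat[r, c] = rate
    return pd.DataFrame(mat)


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline stage reproducibly."""

    stage: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
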