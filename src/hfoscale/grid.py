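"""8x8 high-density grid geometry, virtual electrode shorting and CAR.

Electrically shorting adjacent contacts averages their signals, mimicking a
single larger contact: pairs of 1.08 mm^2 contacts act as 2.16 mm^2, 2x2
quads as 4.32 mm^2.  The summed physical area of the grid (64 x 1.08 =
69.12 mm^2) is invariant across schemes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import Recording

__all__ = [
    "GridLayout",
    "ShortingScheme",
    "make_shorting_scheme",
    "apply_shorting",
    "common_average_reference",
]


def _default_channel_id(row: int, col: int, n_cols: int) -> str:
    return f"E{row * n_cols + col:02d}"


@dataclass
class GridLayout:
    """Rectangular subdural grid; default 8x8, 1.08 mm^2 contacts, 3 mm pitch."""

    n_rows: int = 8
    n_cols: int = 8
    pitch: float = 3.0  # mm, center-to-center
    electrode_area: float = 1.08  # mm^2 per contact
    positions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pitch <= 0 or self.electrode_area <= 0:
            raise ValueError("pitch and electrode_area must be > 0")
        if not self.positions:
            self.positions = {
                _default_channel_id(r, c, self.n_cols): (r, c)
                for r in range(self.n_rows)
                for c in range(self.n_cols)
            }
        cells = sorted(self.positions.values())
        expected = sorted((r, c) for r in range(self.n_rows) for c in range(self.n_cols))
        if cells != expected:
            raise ValueError("positions must map channels bijectively onto grid cells")

    @property
    def channel_ids(self) -> list[str]:
        # row-major order
        return [cid for cid, _ in sorted(self.positions.items(), key=lambda kv: kv[1])]

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def total_area(self) -> float:
        return self.n_channels * self.electrode_area

    def channel_at(self, row: int, col: int) -> str:
        for cid, rc in self.positions.items():
            if rc == (row, col):
                return cid
        raise KeyError((row, col))


@dataclass
class ShortingScheme:
    """Partition of grid channels into shorted groups of equal size."""

    groups: list[list[str]]
    effective_area: float  # mm^2 per (equal-sized) group
    label: str
    electrode_area: float = 1.08
    centroids: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        flat = [ch for g in self.groups for ch in g]
        if len(flat) != len(set(flat)):
            raise ValueError("shorting groups must be disjoint")

    @property
    def group_ids(self) -> list[str]:
        return [g[0] for g in self.groups]

    @property
    def total_area(self) -> float:
        """Summed physical contact area over all groups (scheme-invariant)."""
        return self.electrode_area * sum(len(g) for g in self.groups)

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "effective_area": self.effective_area,
                "electrode_area": self.electrode_area,
                "groups": self.groups,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ShortingScheme":
        d = json.loads(text)
        return cls(
            groups=d["groups"],
            effective_area=d["effective_area"],
            label=d["label"],
            electrode_area=d.get("electrode_area", 1.08),
        )


_TILES = {"small": (1, 1), "pair": (1, 2), "quad": (2, 2)}


def make_shorting_scheme(layout: GridLayout, label: str,
                         orientation: str = "horizontal") -> ShortingScheme:
    """Tile the grid into shorted groups.

    "small" keeps 64 singletons, "pair" shorts 1x2 neighbours (horizontal by
    default), "quad" shorts 2x2 blocks; tiling starts at the top-left corner.
    """
    if label not in _TILES:
        raise ValueError(f"unknown scheme label {label!r}; expected {sorted(_TILES)}")
    tr, tc = _TILES[label]
    if label == "pair" and orientation == "vertical":
        tr, tc = tc, tr
    if layout.n_rows % tr or layout.n_cols % tc:
        raise ValueError(
            f"{layout.n_rows}x{layout.n_cols} grid not divisible by {tr}x{tc} tile"
        )
    groups: list[list[str]] = []
    centroids: dict[str, tuple[float, float]] = {}
    for r0 in range(0, layout.n_rows, tr):
        for c0 in range(0, layout.n_cols, tc):
            members = [
                layout.channel_at(r, c)
                for r in range(r0, r0 + tr)
                for c in range(c0, c0 + tc)
            ]
            groups.append(members)
            rows_cols = [layout.positions[m] for m in members]
            centroids[members[0]] = (
                float(np.mean([rc[0] for rc in rows_cols])),
                float(np.mean([rc[1] for rc in rows_cols])),
            )
    return ShortingScheme(
        groups=groups,
        effective_area=layout.electrode_area * tr * tc,
        label=label,
        electrode_area=layout.electrode_area,
        centroids=centroids,
    )


def apply_shorting(rec: Recording, scheme: ShortingScheme) -> Recording:
    """Average each shorted group's member channels into one output channel."""
    missing = {ch for g in scheme.groups for ch in g} - set(rec.channel_ids)
    if missing:
        raise ValueError(f"scheme references channels absent from recording: {sorted(missing)}")
    out = np.empty((len(scheme.groups), rec.n_samples))
    ids = []
    for k, group in enumerate(scheme.groups):
        idx = [rec.channel_index(ch) for ch in group]
        out[k] = rec.data[idx].mean(axis=0)
        ids.append(group[0])
    shorted = rec.copy_with(out, channel_ids=ids, scheme=scheme.label)
    shorted.electrode_area = scheme.effective_area
    return shorted


def common_average_reference(rec: Recording) -> tuple[Recording, np.ndarray]:
    """Subtract the across-channel mean; returns (re-referenced, CAR signal)."""
    if rec.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    car = rec.data.mean(axis=0)
    return rec.copy_with(rec.data - car, reference="car"), car
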