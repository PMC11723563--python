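"""Statistical comparisons and the electrode-size experiment runner.

The size experiment re-measures each simulated source at several contact
areas (1.08, 2.16, 4.32 mm^2 by default), runs the detector, and compares
feature distributions between adjacent sizes with a Wilcoxon rank-sum
test.  Rate per area is a per-record quantity (each record contributes one
value); amplitude, duration and peak frequency are properties of
individual detected events and are compared at the event level.
Per-record medians of the event features are retained alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

from .detect import DetectorParams, HfoEvent, detect_hfos
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "rank_sum_test",
    "SizeExperimentResult",
    "run_size_experiment",
    "band_rate_comparison",
    "summarize_spread",
    "DEFAULT_AREAS",
]

DEFAULT_AREAS = (1.08, 2.16, 4.32)  # mm^2: small, pair, quad


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    Returns (U statistic of x, p).  For combined n <= exact_max_n the
    p-value is computed by full enumeration of all C(n, n_x) group
    assignments of the pooled mid-ranks (ties handled naturally; two
    completely tied samples give p = 1).  Larger samples use the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _sstats.rankdata(pooled)
    w = float(ranks[:nx].sum())
    u = w - nx * (nx + 1) / 2.0
    if np.ptp(pooled) == 0:
        return u, 1.0
    n = nx + ny
    if n <= exact_max_n:
        mu = nx * (n + 1) / 2.0
        obs = abs(w - mu)
        total = math.comb(n, nx)
        extreme = sum(
            1 for comb in itertools.combinations(range(n), nx)
            if abs(sum(ranks[i] for i in comb) - mu) >= obs - 1e-9
        )
        return u, extreme / total
    res = _sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


@dataclass
class SizeExperimentResult:
    """Per-area feature distributions plus adjacent-pair rank-sum tests."""

    areas: tuple[float, ...]
    band: str
    n_per_area: int
    seed: int
    # canonical distributions, keyed by area: rate_per_area is per record,
    # the other three are per detected event
    rate_per_area: dict[float, np.ndarray] = field(default_factory=dict)  # ev/min/mm^2
    amplitude: dict[float, np.ndarray] = field(default_factory=dict)  # uV
    duration_ms: dict[float, np.ndarray] = field(default_factory=dict)
    peak_frequency: dict[float, np.ndarray] = field(default_factory=dict)
    record_amplitude: dict[float, np.ndarray] = field(default_factory=dict)  # record medians
    record_duration_ms: dict[float, np.ndarray] = field(default_factory=dict)
    record_peak_frequency: dict[float, np.ndarray] = field(default_factory=dict)
    n_events: dict[float, int] = field(default_factory=dict)
    pairwise_p: dict[str, dict[tuple[float, float], float]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    FEATURES = ("rate_per_area", "amplitude", "duration_ms", "peak_frequency")

    def medians(self, feature: str) -> list[float]:
        vals = getattr(self, feature)
        return [float(np.median(vals[a])) if len(vals[a]) else float("nan")
                for a in self.areas]

    def to_dict(self) -> dict:
        return {
            "areas": list(self.areas),
            "band": self.band,
            "n_per_area": self.n_per_area,
            "seed": self.seed,
            "medians": {f: self.medians(f) for f in self.FEATURES},
            "n_events": {str(a): self.n_events[a] for a in self.areas},
            "pairwise_p": {
                f: {f"{a1}->{a2}": p for (a1, a2), p in d.items()}
                for f, d in self.pairwise_p.items()
            },
            "config": self.config,
        }


def run_size_experiment(cfg: SimulationConfig,
                        areas: Sequence[float] = DEFAULT_AREAS,
                        n_per_area: int = 50,
                        detector: DetectorParams | None = None,
                        seed: int = 0) -> SizeExperimentResult:
    """Simulate, detect and compare across contact areas; fully seeded.

    Per record and area, the event count divided by duration and contact
    area gives the (single-electrode) rate per area; amplitude, duration
    and peak frequency are collected per detected event.  Adjacent areas
    are compared per feature with the two-sided rank-sum test.
    """
    detector = detector or DetectorParams()
    areas = tuple(areas)
    res = SizeExperimentResult(areas=areas, band=cfg.band, n_per_area=n_per_area,
                               seed=seed, config=cfg.to_dict())
    per_rec: dict[float, dict[str, list[float]]] = {
        a: {"rate": [], "amp": [], "dur": [], "pf": []} for a in areas
    }
    pooled: dict[float, dict[str, list[float]]] = {
        a: {"amp": [], "dur": [], "pf": []} for a in areas
    }
    duration_min = cfg.duration / 60.0
    for rec in simulate_cohort(cfg, areas, n_per_area, seed):
        area = rec.meta["area"]
        events = detect_hfos(rec, cfg.band, detector)
        per_rec[area]["rate"].append(len(events) / duration_min / area)
        if events:
            amps = [e.amplitude for e in events]
            durs = [e.duration_s * 1e3 for e in events]
            pfs = [e.peak_frequency for e in events if np.isfinite(e.peak_frequency)]
            per_rec[area]["amp"].append(float(np.median(amps)))
            per_rec[area]["dur"].append(float(np.median(durs)))
            if pfs:
                per_rec[area]["pf"].append(float(np.median(pfs)))
            pooled[area]["amp"].extend(amps)
            pooled[area]["dur"].extend(durs)
            pooled[area]["pf"].extend(pfs)
    for a in areas:
        res.rate_per_area[a] = np.asarray(per_rec[a]["rate"])
        res.amplitude[a] = np.asarray(pooled[a]["amp"])
        res.duration_ms[a] = np.asarray(pooled[a]["dur"])
        res.peak_frequency[a] = np.asarray(pooled[a]["pf"])
        res.record_amplitude[a] = np.asarray(per_rec[a]["amp"])
        res.record_duration_ms[a] = np.asarray(per_rec[a]["dur"])
        res.record_peak_frequency[a] = np.asarray(per_rec[a]["pf"])
        res.n_events[a] = len(pooled[a]["amp"])
    feature_map = {
        "rate_per_area": res.rate_per_area,
        "amplitude": res.amplitude,
        "duration_ms": res.duration_ms,
        "peak_frequency": res.peak_frequency,
    }
    for fname, dist in feature_map.items():
        res.pairwise_p[fname] = {}
        for a1, a2 in zip(areas[:-1], areas[1:]):
            if len(dist[a1]) and len(dist[a2]):
                _, p = rank_sum_test(dist[a1], dist[a2])
            else:
                p = float("nan")
            res.pairwise_p[fname][(a1, a2)] = p
    return res


def band_rate_comparison(events_by_band: dict[str, list[HfoEvent]],
                         duration_min: float,
                         channel_ids: Sequence[str]) -> dict:
    """Per-channel rates for two bands plus the rank-sum comparison."""
    from .features import channel_rates

    bands = list(events_by_band)
    rates = {
        b: np.array([channel_rates(events_by_band[b], duration_min, list(channel_ids))[c]
                     for c in channel_ids])
        for b in bands
    }
    out: dict = {"rates": rates, "duration_min": duration_min}
    if len(bands) == 2:
        u, p = rank_sum_test(rates[bands[0]], rates[bands[1]])
        out["statistic"] = u
        out["p"] = p
        out["mean_rates"] = {b: float(rates[b].mean()) for b in bands}
    return out


def summarize_spread(groups_by_label: dict[str, list]) -> dict[str, dict[str, int]]:
    """Counts of S = 1 vs S > 1 groups per electrode-size label."""
    out = {}
    for label, groups in groups_by_label.items():
        s1 = sum(1 for g in groups if g.spread == 1)
        out[label] = {"s1": s1, "s_gt1": len(groups) - s1, "total": len(groups)}
    return out
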