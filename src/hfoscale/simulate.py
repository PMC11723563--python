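"""Synthetic iEEG generation: HFO pulse trains in 1/f background, measured
through the lumped electrode model.

A channel is composed as

    v_tissue = p * (hfo + bg_covered) + (1 - p) * bg_rest,   p = min(rho, 1)

where rho (rho_HFOG) is the ratio of HFO-generating tissue area to contact
area, drawn once per record, and the two background processes are
independent equal-variance 1/f^alpha draws.  The tissue potential is then
passed through the electrode divider H(f) with optional interface Johnson
noise.  When the same source is re-measured at a larger contact area A the
coverage fraction becomes p = min(rho * A0 / A, 1): a fixed patch of
HFO-generating tissue covers less of a bigger contact, which is the
mechanism by which rate and amplitude fall with electrode size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import yaml
from scipy.signal import windows

from . import dists
from .core import ChannelTruth, HfoTrain, Pulse, Recording, get_band
from .dists import DistSpec
from .electrode import ElectrodeModel, synthesize_from_psd
from .grid import GridLayout

__all__ = [
    "SimulationConfig",
    "default_config",
    "sample_hfo_train",
    "render_hfo_signal",
    "generate_background",
    "mix_sources",
    "electrode_transfer",
    "simulate_recording",
    "simulate_cohort",
    "simulate_grid_recording",
]


def _default_dists(band: str) -> dict[str, DistSpec]:
    # f0 stays clear of Nyquist: above ~400 Hz at fs=1000 the rectified
    # waveform's hump rate |fs - 2 f0| drops below what the six-peak
    # validation stage can count within a typical event duration
    f0 = dists.uniform(260.0, 400.0) if band == "fast_ripple" else dists.uniform(90.0, 240.0)
    return {
        "dist_s": dists.exponential(5.0),          # inter-pulse gap, s
        "dist_d": dists.gamma_mean(4.0, 0.050),    # pulse duration, s
        "dist_K": dists.truncnorm(20.0, 10.0, 1.0, 60.0),  # pulse amplitude, uV
        "dist_rho": dists.uniform(0.05, 3.0),      # HFO-area proportion
        "dist_f0": f0,                             # intra-burst frequency, Hz
    }


@dataclass
class SimulationConfig:
    """Everything that drives one simulated channel; fully serializable."""

    fs: float = 1000.0
    duration: float = 1200.0  # s (clinical-scale records are 20 min)
    band: str = "fast_ripple"
    dist_s: DistSpec | None = None
    dist_d: DistSpec | None = None
    dist_K: DistSpec | None = None
    dist_rho: DistSpec | None = None
    dist_f0: DistSpec | None = None
    bg_sigma: float = 15.0  # uV broadband RMS
    bg_exponent: float = 1.0  # spectral slope alpha of 1/f^alpha
    electrode: ElectrodeModel = field(default_factory=ElectrodeModel)
    seed: int = 0
    envelope: str = "tukey"  # "tukey" (flat top, raised-cosine ramps) or "hann"
    envelope_ramp: float = 0.005  # s, ramp length for the tukey envelope
    measurement_noise: bool = True

    def __post_init__(self) -> None:
        defaults = _default_dists(self.band)
        for name, spec in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, spec)
        self.validate()

    def validate(self) -> None:
        band = get_band(self.band)
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.fs < 2 * band.high:
            raise ValueError(f"fs={self.fs} cannot represent band {self.band}")
        if self.bg_sigma < 0:
            raise ValueError("bg_sigma must be >= 0")
        for name in ("dist_s", "dist_d"):
            spec = getattr(self, name)
            lo, hi = spec.support()
            if lo == hi == 0:
                raise ValueError(f"{name} is degenerate at zero")
            if hi <= 0:
                raise ValueError(f"{name} must have positive support")
        k_lo, _ = self.dist_K.support()
        if k_lo < 0:
            raise ValueError("dist_K support must be non-negative")
        r_lo, r_hi = self.dist_rho.support()
        if r_lo <= 0 or r_hi > 3.0:
            raise ValueError("dist_rho support must lie in (0, 3]")
        f_lo, f_hi = self.dist_f0.support()
        if f_lo < band.low or f_hi > band.high:
            raise ValueError("dist_f0 support must lie within the band limits")
        if self.envelope not in ("tukey", "hann"):
            raise ValueError("envelope must be 'tukey' or 'hann'")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "fs": self.fs,
            "duration": self.duration,
            "band": self.band,
            "bg_sigma": self.bg_sigma,
            "bg_exponent": self.bg_exponent,
            "seed": self.seed,
            "envelope": self.envelope,
            "envelope_ramp": self.envelope_ramp,
            "measurement_noise": self.measurement_noise,
            "electrode": {
                "area": self.electrode.area,
                "c_dl": self.electrode.c_dl,
                "r_ct": self.electrode.r_ct,
                "tissue_resistivity": self.electrode.tissue_resistivity,
                "z_in": list(self.electrode.z_in),
                "temperature": self.electrode.temperature,
                "material": self.electrode.material,
            },
        }
        for name in ("dist_s", "dist_d", "dist_K", "dist_rho", "dist_f0"):
            d[name] = getattr(self, name).to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        em = d.pop("electrode", None)
        if em is not None:
            em = dict(em)
            em["z_in"] = tuple(em.get("z_in", (100e6, 10e-12)))
            d["electrode"] = ElectrodeModel(**em)
        for name in ("dist_s", "dist_d", "dist_K", "dist_rho", "dist_f0"):
            if d.get(name) is not None and not isinstance(d[name], DistSpec):
                d[name] = DistSpec.from_dict(d[name])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


def default_config(band: str = "fast_ripple", **overrides) -> SimulationConfig:
    return SimulationConfig(band=band, **overrides)


# ---------------------------------------------------------------------------


def sample_hfo_train(cfg: SimulationConfig, rng: np.random.Generator) -> HfoTrain:
    """Alternate gap/pulse draws until the record duration is exhausted.

    A pulse whose offset would overrun the record end is dropped (and the
    train ends there, since gaps are non-negative).
    """
    for name in ("dist_s", "dist_d"):
        lo, hi = getattr(cfg, name).support()
        if lo == hi == 0:
            raise ValueError(f"{name} is degenerate at zero")
    pulses: list[Pulse] = []
    t = 0.0
    while True:
        gap = float(cfg.dist_s.sample(rng))
        onset = t + gap
        d = float(cfg.dist_d.sample(rng))
        k = float(cfg.dist_K.sample(rng))
        f0 = float(cfg.dist_f0.sample(rng))
        phase = float(rng.uniform(0.0, 2 * np.pi))
        if onset + d > cfg.duration:
            break
        pulses.append(Pulse(onset=onset, duration=d, amplitude=k, f0=f0, phase=phase))
        t = onset + d
    return HfoTrain(pulses=pulses, band=cfg.band)


def _envelope(n: int, fs: float, kind: str, ramp: float) -> np.ndarray:
    if kind == "hann":
        return windows.hann(n, sym=True)
    # tukey: raised-cosine ramps of fixed length, flat plateau between
    d = n / fs
    alpha = min(2.0 * ramp / d, 1.0) if d > 0 else 1.0
    return windows.tukey(n, alpha=alpha, sym=True)


def render_hfo_signal(train: HfoTrain, fs: float, duration: float,
                      envelope: str = "tukey", ramp: float = 0.005) -> np.ndarray:
    """Render a pulse train as K * w(t) * sin(2 pi f0 t + phi), zero between."""
    n = int(round(duration * fs))
    out = np.zeros(n)
    for p in train.pulses:
        i0 = int(round(p.onset * fs))
        i1 = min(int(round(p.offset * fs)), n)
        m = i1 - i0
        if m <= 0:
            continue
        t = np.arange(m) / fs
        w = _envelope(m, fs, envelope, ramp)
        out[i0:i1] += p.amplitude * w * np.sin(2 * np.pi * p.f0 * t + p.phase)
    return out


def generate_background(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian background, rescaled to exactly bg_sigma RMS.

    The power-law shape is flattened below 1 Hz (no DC) so alpha >= 1 stays
    integrable over the record length.
    """
    n = int(round(cfg.duration * cfg.fs))
    if cfg.bg_sigma == 0:
        # keep the stream position moving so sigma=0 stays draw-compatible
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-cfg.bg_exponent)
    x = synthesize_from_psd(shape, n, cfg.fs, rng)
    rms = np.sqrt(np.mean(x**2))
    return x * (cfg.bg_sigma / rms)


def mix_sources(hfo: np.ndarray, bg_hfo_region: np.ndarray, bg_rest: np.ndarray,
                rho_hfog: float) -> np.ndarray:
    """Area-weighted mixture of covered and uncovered tissue potentials.

    Coverage saturates at full-contact coverage: p = min(rho, 1), so rho = 1
    and rho = 3 produce identical mixtures.
    """
    if rho_hfog <= 0:
        raise ValueError("rho_hfog must be > 0")
    if not (len(hfo) == len(bg_hfo_region) == len(bg_rest)):
        raise ValueError("source waveforms must have equal length")
    p = min(float(rho_hfog), 1.0)
    return p * (np.asarray(hfo) + np.asarray(bg_hfo_region)) + (1.0 - p) * np.asarray(bg_rest)


def electrode_transfer(potential: np.ndarray, em: ElectrodeModel, fs: float,
                       rng: np.random.Generator | None = None,
                       add_noise: bool = True) -> np.ndarray:
    """Measure a tissue potential through the electrode divider."""
    return em.apply(potential, fs, rng=rng, add_noise=add_noise)


# ---------------------------------------------------------------------------


def _compose_channel(cfgs: Sequence[SimulationConfig], rng: np.random.Generator,
                     area: float | None = None, rho_scale: float = 1.0,
                     ) -> tuple[np.ndarray, ChannelTruth]:
    """Draw one channel's sources and measure them.

    ``cfgs`` may hold one config per band; trains are rendered per config
    and summed, backgrounds and rho are drawn once (from cfgs[0]).  The draw
    order is fixed so a shared seed reproduces the channel bit-identically.
    """
    base = cfgs[0]
    trains = [sample_hfo_train(cfg, rng) for cfg in cfgs]
    rho = float(base.dist_rho.sample(rng))
    bg_cov = generate_background(base, rng)
    bg_rest = generate_background(base, rng)
    hfo = np.zeros_like(bg_cov)
    for cfg, train in zip(cfgs, trains):
        hfo += render_hfo_signal(train, cfg.fs, cfg.duration, cfg.envelope, cfg.envelope_ramp)
    em = base.electrode if area is None else base.electrode.with_area(area)
    pot = mix_sources(hfo, bg_cov, bg_rest, min(rho * rho_scale, 3.0))
    meas = em.apply(pot, base.fs, rng=rng, add_noise=base.measurement_noise)
    return meas, ChannelTruth(trains=trains, rho_hfog=rho)


def simulate_recording(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> Recording:
    """One single-channel record with embedded ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    meas, truth = _compose_channel([cfg], rng)
    return Recording(
        data=meas[np.newaxis, :],
        fs=cfg.fs,
        channel_ids=["E00"],
        ground_truth=[truth],
        electrode_area=cfg.electrode.area,
        meta={"band": cfg.band, "rho_hfog": truth.rho_hfog},
    )


def simulate_cohort(cfg: SimulationConfig, areas: Sequence[float], n_per_area: int,
                    base_seed: int) -> Iterator[Recording]:
    """Re-measure each source realization at every contact area.

    For record index i the injected train, rho and background draws are
    identical across areas (shared seed), so area is the only varying
    factor.  rho is defined relative to the smallest (reference) area A0;
    at area A the coverage fraction is p = min(rho * A0 / A, 1).  Yields
    records record-major: (record 0, area 0), (record 0, area 1), ...
    """
    if len(areas) == 0:
        raise ValueError("areas must be non-empty")
    ref_area = min(areas)
    for i in range(n_per_area):
        src_rng = np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(i,)))
        train = sample_hfo_train(cfg, src_rng)
        rho = float(cfg.dist_rho.sample(src_rng))
        bg_cov = generate_background(cfg, src_rng)
        bg_rest = generate_background(cfg, src_rng)
        hfo = render_hfo_signal(train, cfg.fs, cfg.duration, cfg.envelope, cfg.envelope_ramp)
        truth = ChannelTruth(trains=[train], rho_hfog=rho)
        for j, area in enumerate(areas):
            p = min(rho * ref_area / area, 1.0)
            pot = p * (hfo + bg_cov) + (1.0 - p) * bg_rest
            em = cfg.electrode.with_area(area)
            meas_rng = np.random.default_rng(
                np.random.SeedSequence(base_seed, spawn_key=(i, j + 1))
            )
            meas = em.apply(pot, cfg.fs, rng=meas_rng, add_noise=cfg.measurement_noise)
            yield Recording(
                data=meas[np.newaxis, :],
                fs=cfg.fs,
                channel_ids=["E00"],
                ground_truth=[truth],
                electrode_area=area,
                meta={
                    "band": cfg.band,
                    "record_index": i,
                    "area": area,
                    "rho_hfog": rho,
                    "coverage": p,
                },
            )


def simulate_grid_recording(cfgs: SimulationConfig | Sequence[SimulationConfig],
                            seed: int,
                            layout: GridLayout | None = None) -> Recording:
    """Independent channels across a grid; one or more band configs per channel."""
    if isinstance(cfgs, SimulationConfig):
        cfgs = [cfgs]
    base = cfgs[0]
    for cfg in cfgs[1:]:
        if cfg.fs != base.fs or cfg.duration != base.duration:
            raise ValueError("all band configs must share fs and duration")
    if layout is None:
        layout = GridLayout()
    ids = layout.channel_ids
    n = int(round(base.duration * base.fs))
    data = np.empty((len(ids), n))
    truths: list[ChannelTruth] = []
    for ch in range(len(ids)):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ch,)))
        data[ch], truth = _compose_channel(cfgs, rng)
        truths.append(truth)
    return Recording(
        data=data,
        fs=base.fs,
        channel_ids=ids,
        layout=layout,
        ground_truth=truths,
        electrode_area=base.electrode.area,
        meta={"bands": [c.band for c in cfgs]},
    )
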