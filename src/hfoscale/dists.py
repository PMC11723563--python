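"""Serializable one-dimensional distribution specifications.

The simulator is driven entirely by distributions (inter-pulse gap s, pulse
duration d, pulse amplitude K, HFO-area proportion rho, intra-burst
frequency f0).  A :class:`DistSpec` names one of a small family of scipy
distributions plus a degenerate point mass, carries its parameters as plain
floats, and can round-trip through YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["DistSpec", "constant", "exponential", "gamma_mean", "truncnorm", "uniform"]


@dataclass(frozen=True)
class DistSpec:
    """name in {constant, exponential, gamma, truncnorm, uniform} + params."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.name!r}")
        _FAMILIES[self.name].validate(self.params)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        return _FAMILIES[self.name].sample(self.params, rng, size)

    def mean(self) -> float:
        return _FAMILIES[self.name].mean(self.params)

    def support(self) -> tuple[float, float]:
        return _FAMILIES[self.name].support(self.params)

    @property
    def is_point_mass(self) -> bool:
        lo, hi = self.support()
        return lo == hi

    def to_dict(self) -> dict:
        return {"name": self.name, **{k: float(v) for k, v in self.params.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "DistSpec":
        d = dict(d)
        return cls(d.pop("name"), d)


class _Family:
    keys: tuple[str, ...] = ()

    @classmethod
    def validate(cls, p: dict) -> None:
        missing = set(cls.keys) - set(p)
        extra = set(p) - set(cls.keys)
        if missing or extra:
            raise ValueError(
                f"{cls.__name__}: wrong parameters (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
        for v in p.values():
            if not np.isfinite(v):
                raise ValueError("distribution parameters must be finite")


class _Constant(_Family):
    keys = ("value",)

    @staticmethod
    def sample(p, rng, size):
        if size is None:
            return float(p["value"])
        return np.full(size, float(p["value"]))

    @staticmethod
    def mean(p):
        return float(p["value"])

    @staticmethod
    def support(p):
        return (float(p["value"]), float(p["value"]))


class _Exponential(_Family):
    keys = ("mean",)

    @classmethod
    def validate(cls, p):
        super().validate(p)
        if p["mean"] <= 0:
            raise ValueError("exponential mean must be > 0")

    @staticmethod
    def sample(p, rng, size):
        return rng.exponential(p["mean"], size=size)

    @staticmethod
    def mean(p):
        return float(p["mean"])

    @staticmethod
    def support(p):
        return (0.0, np.inf)


class _Gamma(_Family):
    keys = ("shape", "mean")

    @classmethod
    def validate(cls, p):
        super().validate(p)
        if p["shape"] <= 0 or p["mean"] <= 0:
            raise ValueError("gamma shape and mean must be > 0")

    @staticmethod
    def sample(p, rng, size):
        scale = p["mean"] / p["shape"]
        return rng.gamma(p["shape"], scale, size=size)

    @staticmethod
    def mean(p):
        return float(p["mean"])

    @staticmethod
    def support(p):
        return (0.0, np.inf)


class _TruncNorm(_Family):
    keys = ("mean", "sd", "low", "high")

    @classmethod
    def validate(cls, p):
        super().validate(p)
        if p["sd"] < 0 or p["low"] >= p["high"]:
            raise ValueError("truncnorm needs sd >= 0 and low < high")

    @staticmethod
    def _frozen(p):
        a = (p["low"] - p["mean"]) / p["sd"]
        b = (p["high"] - p["mean"]) / p["sd"]
        return stats.truncnorm(a, b, loc=p["mean"], scale=p["sd"])

    @classmethod
    def sample(cls, p, rng, size):
        if p["sd"] == 0:
            return _Constant.sample({"value": p["mean"]}, rng, size)
        out = cls._frozen(p).rvs(size=size if size is not None else 1, random_state=rng)
        return float(out[0]) if size is None else out

    @classmethod
    def mean(cls, p):
        if p["sd"] == 0:
            return float(p["mean"])
        return float(cls._frozen(p).mean())

    @staticmethod
    def support(p):
        if p["sd"] == 0:
            return (float(p["mean"]), float(p["mean"]))
        return (float(p["low"]), float(p["high"]))


class _Uniform(_Family):
    keys = ("low", "high")

    @classmethod
    def validate(cls, p):
        super().validate(p)
        if p["low"] > p["high"]:
            raise ValueError("uniform needs low <= high")

    @staticmethod
    def sample(p, rng, size):
        return rng.uniform(p["low"], p["high"], size=size)

    @staticmethod
    def mean(p):
        return float(p["low"] + p["high"]) / 2.0

    @staticmethod
    def support(p):
        return (float(p["low"]), float(p["high"]))


_FAMILIES = {
    "constant": _Constant,
    "exponential": _Exponential,
    "gamma": _Gamma,
    "truncnorm": _TruncNorm,
    "uniform": _Uniform,
}


def constant(value: float) -> DistSpec:
    return DistSpec("constant", {"value": value})


def exponential(mean: float) -> DistSpec:
    return DistSpec("exponential", {"mean": mean})


def gamma_mean(shape: float, mean: float) -> DistSpec:
    return DistSpec("gamma", {"shape": shape, "mean": mean})


def truncnorm(mean: float, sd: float, low: float, high: float = np.inf) -> DistSpec:
    if not np.isfinite(high):
        high = mean + 20 * sd if sd > 0 else mean + 1.0
    return DistSpec("truncnorm", {"mean": mean, "sd": sd, "low": low, "high": high})


def uniform(low: float, high: float) -> DistSpec:
    return DistSpec("uniform", {"low": low, "high": high})
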