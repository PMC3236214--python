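"""Probabilistic sensitivity analysis core: uncertain-input distributions,
seeded Monte Carlo sampling, and simulation summaries.

Every uncertain model input is declared as a :class:`DistributionSpec` —
a point estimate, a triangular distribution (min / best estimate / max),
or a uniform distribution — and propagated through the cost and DALY
models by Monte Carlo simulation.  Simulated quantities are reported as a
mean with an empirical 95% percentile interval (2.5th and 97.5th
percentiles), the standard convention in probabilistic sensitivity
analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistributionSpec",
    "SimulationResult",
    "child_seed",
    "sample",
    "summarize",
    "widen",
]

_KINDS = ("point", "triangular", "uniform")

#: Default number of Monte Carlo draws for reporting runs.
DEFAULT_DRAWS = 10_000


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of one uncertain model input.

    Parameters
    ----------
    kind:
        One of ``"point"``, ``"triangular"``, ``"uniform"``.
    low, mode, high:
        Bounds and best estimate.  For a point estimate all three are
        equal; for a uniform distribution ``mode`` is stored as the
        midpoint and plays no role in sampling.
    """

    kind: str
    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        for name in ("low", "mode", "high"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.kind == "point":
            if not (self.low == self.mode == self.high):
                raise ValueError(
                    "point spec requires low == mode == high, got "
                    f"low={self.low}, mode={self.mode}, high={self.high}"
                )
        elif self.kind == "triangular":
            if not (self.low <= self.mode <= self.high):
                raise ValueError(
                    "triangular spec requires low <= mode <= high, got "
                    f"low={self.low}, mode={self.mode}, high={self.high}"
                )
        elif self.kind == "uniform":
            if not self.low < self.high:
                raise ValueError(
                    f"uniform spec requires low < high, got low={self.low}, high={self.high}"
                )

    # -- constructors -------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", value, value, value)

    @classmethod
    def triangular(cls, low: float, mode: float, high: float) -> "DistributionSpec":
        if low == mode == high:
            return cls.point(low)
        return cls("triangular", low, mode, high)

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls("uniform", low, (low + high) / 2.0, high)

    # -- analytics ----------------------------------------------------
    @property
    def mean(self) -> float:
        """Analytic mean of the distribution."""
        if self.kind == "point":
            return self.mode
        if self.kind == "triangular":
            return (self.low + self.mode + self.high) / 3.0
        return (self.low + self.high) / 2.0

    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw ``n`` independent samples.

        ``rng`` may be a :class:`numpy.random.Generator` or an integer
        seed; the same seed always reproduces the same draws.
        """
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if self.kind == "point":
            return np.full(n, self.mode, dtype=float)
        if self.kind == "triangular":
            if self.low == self.high:
                return np.full(n, self.mode, dtype=float)
            return rng.triangular(self.low, self.mode, self.high, size=n)
        return rng.uniform(self.low, self.high, size=n)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {"kind": self.kind, "low": self.low, "mode": self.mode, "high": self.high}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        extra = set(d) - {"kind", "low", "mode", "high"}
        if extra:
            raise ValueError(f"unknown distribution keys: {sorted(extra)}")
        if "kind" not in d:
            raise ValueError("distribution spec requires a 'kind' key")
        kind = d["kind"]
        if kind == "point":
            if "mode" not in d:
                raise ValueError("point spec requires 'mode'")
            return cls.point(float(d["mode"]))
        if kind == "uniform":
            return cls.uniform(float(d["low"]), float(d["high"]))
        return cls("triangular", float(d["low"]), float(d["mode"]), float(d["high"]))


@dataclass(frozen=True)
class SimulationResult:
    """Mean and 95% percentile interval of a simulated quantity."""

    mean: float
    ci_low: float
    ci_high: float
    draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError(f"draws must be >= 1, got {self.draws}")

    def scaled(self, factor: float) -> "SimulationResult":
        """The result of multiplying every underlying draw by ``factor``."""
        lo, hi = self.ci_low * factor, self.ci_high * factor
        if factor < 0:
            lo, hi = hi, lo
        return SimulationResult(self.mean * factor, lo, hi, self.draws, self.seed)


def sample(spec: DistributionSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Functional form of :meth:`DistributionSpec.sample`."""
    return spec.sample(n, seed)


def widen(best: float, fraction: float = 0.25) -> DistributionSpec:
    """Turn a best estimate into a triangular spec spanning ``±fraction``.

    A zero best estimate stays a point mass at zero (costs cannot be
    negative, so there is nothing to widen).
    """
    if best < 0:
        raise ValueError(f"best estimate must be non-negative, got {best}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if best == 0:
        return DistributionSpec.point(0.0)
    return DistributionSpec.triangular(best * (1 - fraction), best, best * (1 + fraction))


def _percentile(sorted_draws: np.ndarray, q: float) -> float:
    # linear interpolation in the a + (b - a) * g form so that a vector of
    # identical values returns that value bit-exactly
    pos = q / 100.0 * (sorted_draws.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, sorted_draws.size - 1)
    g = pos - lo
    a, b = sorted_draws[lo], sorted_draws[hi]
    return float(a + (b - a) * g)


def summarize(draws: np.ndarray, seed: int | None = None) -> SimulationResult:
    """Mean and empirical 2.5th/97.5th percentiles (linear interpolation)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    s = np.sort(draws)
    if s[0] == s[-1]:  # degenerate: summary is the constant itself, exactly
        v = float(s[0])
        return SimulationResult(v, v, v, int(draws.size), seed)
    lo, hi = _percentile(s, 2.5), _percentile(s, 97.5)
    return SimulationResult(float(draws.mean()), lo, hi, int(draws.size), seed)


def child_seed(root_seed: int, name: str) -> int:
    """Deterministic per-component seed derived from one root seed.

    Each pipeline component draws from its own stream keyed by name, so
    adding or reordering components never perturbs another component's
    draws.  The result is always below 2**31.
    """
    h = zlib.crc32(name.encode("utf-8"))
    return (int(root_seed) * 2654435761 + h) % (2**31 - 1)
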