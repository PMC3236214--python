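"""Age-weighted, discounted DALY engine (YLL + YLD).

Years of life lost (YLL) for a death at age ``a`` are the discounted,
age-weighted stream of the ``L`` residual life-years:

    YLL(a) = integral from a to a+L of
             [ K*C*x*exp(-beta*x) + (1-K) ] * exp(-r*(x-a)) dx

with discount rate ``r``, age-weighting modulation ``K`` (K=1 fully
age-weighted, K=0 unweighted), and the standard global-burden
age-weighting constants ``C`` and ``beta``.  The integral is evaluated in
closed form; the ``r=0`` and ``K=0`` limits are handled analytically.

Years lived with disability (YLD) for neonatal morbidity apply a
disability weight over a short (stochastic) duration, age-weighted and
discounted over that duration from the onset age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psa import DEFAULT_DRAWS, DistributionSpec, SimulationResult, summarize

__all__ = [
    "DALYParameters",
    "DeathEvent",
    "DisabilityEvent",
    "cohort_dalys",
    "yld",
    "yll",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class DALYParameters:
    """Discounting and age-weighting parameters.

    r : annual discount rate (default 3%).
    K : age-weighting modulation in [0, 1]; 1 = fully age-weighted.
    C, beta : age-weighting function constants ``C*x*exp(-beta*x)``.
    L : residual life expectancy at birth, years.
    """

    r: float = 0.03
    K: float = 1.0
    C: float = 0.1658
    beta: float = 0.04
    L: float = 68.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"discount rate r must be >= 0, got {self.r}")
        if not 0 <= self.K <= 1:
            raise ValueError(f"age-weighting modulation K must be in [0, 1], got {self.K}")
        if self.C <= 0:
            raise ValueError(f"age-weighting constant C must be > 0, got {self.C}")
        if self.beta <= 0:
            raise ValueError(f"age-weighting exponent beta must be > 0, got {self.beta}")
        if self.L <= 0:
            raise ValueError(f"life expectancy L must be > 0, got {self.L}")


@dataclass(frozen=True)
class DeathEvent:
    """An expected number of deaths at a given age (counts may be fractional)."""

    age_at_death: float
    count: float

    def __post_init__(self) -> None:
        if self.age_at_death < 0:
            raise ValueError(f"age_at_death must be >= 0, got {self.age_at_death}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class DisabilityEvent:
    """A disability episode: weight, stochastic duration (days), onset age."""

    onset_age: float = 0.0
    duration_days: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.uniform(2.0, 21.0)
    )
    weight: float = 0.256
    count: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError(f"disability weight must be in [0, 1], got {self.weight}")
        if self.duration_days.low < 0:
            raise ValueError("disability duration must be non-negative")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


def _burden(age: float | np.ndarray, span: float | np.ndarray, p: DALYParameters):
    """Closed form of the discounted age-weighted burden integral.

    Integral from ``age`` to ``age + span`` of
    ``[K*C*x*exp(-beta*x) + (1-K)] * exp(-r*(x - age)) dx``.
    Vectorised over ``age`` and ``span``.
    """
    a = np.asarray(age, dtype=float)
    d = np.asarray(span, dtype=float)
    b = p.r + p.beta  # > 0 since beta > 0

    # age-weighted part: C * exp(r*a) * [G(a) - G(a+d)], G(x) = (x/b + 1/b^2) exp(-b x)
    def g(x):
        return (x / b + 1.0 / b**2) * np.exp(-b * x)

    weighted = p.C * np.exp(p.r * a) * (g(a) - g(a + d))
    # unweighted part: plain annuity of d years at rate r
    if p.r > 0:
        flat = (1.0 - np.exp(-p.r * d)) / p.r
    else:
        flat = d
    out = p.K * weighted + (1.0 - p.K) * flat
    return out if out.ndim else float(out)


def yll(age_at_death: float, params: DALYParameters = DALYParameters()) -> float:
    """Years of life lost per death at ``age_at_death``."""
    if age_at_death < 0:
        raise ValueError(f"age_at_death must be >= 0, got {age_at_death}")
    return _burden(age_at_death, params.L, params)


def yld(
    event: DisabilityEvent,
    params: DALYParameters = DALYParameters(),
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> SimulationResult:
    """Years lived with disability for one episode type, Monte Carlo over duration.

    Per affected person the YLD is the disability weight applied to the
    discounted, age-weighted stream of the episode duration (in years)
    from the onset age; the total scales by ``event.count``.
    """
    durations = event.duration_days.sample(n_draws, seed) / DAYS_PER_YEAR
    per_person = event.weight * _burden(event.onset_age, durations, params)
    return summarize(event.count * np.asarray(per_person), seed=seed)


def cohort_dalys(
    deaths: list[DeathEvent],
    disabilities: list[DisabilityEvent],
    params: DALYParameters = DALYParameters(),
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> SimulationResult:
    """Total DALYs for lists of death and disability events.

    The YLL part is deterministic (closed form per event); the YLD part
    is Monte Carlo over episode durations.  The percentile interval
    reflects only the stochastic YLD component.
    """
    yll_total = float(sum(ev.count * yll(ev.age_at_death, params) for ev in deaths))
    draws = np.full(n_draws, yll_total, dtype=float)
    rng = np.random.default_rng(seed)
    for ev in disabilities:
        durations = ev.duration_days.sample(n_draws, rng) / DAYS_PER_YEAR
        draws = draws + ev.count * ev.weight * np.asarray(
            _burden(ev.onset_age, durations, params)
        )
    return summarize(draws, seed=seed)
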