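"""The study's two statistical models.

1. Log-linear regression of household routine-care cost on birth weight:
   ``log(cost) = intercept + slope * weight_kg``, fitted by OLS.  Costs
   are log-transformed because household cost distributions are strongly
   right-skewed.  The slope is per kilogram of birth weight; the
   percentage effect of a 100 g increase is reported both as the linear
   approximation (-10% of the slope, in percent) and as the exact
   log-scale effect ``100*(1 - exp(0.1*slope))``.

2. Poisson regression of first-year hospital admission counts on LBW
   status (birth weight < 2.5 kg), with fixed one-infant-year exposure;
   the exponentiated coefficient is the admission rate ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "LogLinearFit",
    "PoissonFit",
    "fit_loglinear",
    "fit_poisson",
    "percent_change_per_100g",
]

LBW_THRESHOLD_G = 2500.0


@dataclass(frozen=True)
class LogLinearFit:
    """OLS fit of log cost (US$) on birth weight (kg)."""

    intercept: float
    slope: float
    se_slope: float
    se_intercept: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"need at least 3 records, got {self.n}")
        for name in ("intercept", "slope", "se_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    def ci_slope(self, z: float = 1.96) -> tuple[float, float]:
        return (self.slope - z * self.se_slope, self.slope + z * self.se_slope)


@dataclass(frozen=True)
class PoissonFit:
    """Poisson regression of admission counts on an LBW indicator."""

    baseline_log_rate: float
    log_rate_ratio: float
    se_log_rate_ratio: float
    p_value: float
    n: int

    @property
    def rate_ratio(self) -> float:
        return float(np.exp(self.log_rate_ratio))

    def ci_rate_ratio(self, z: float = 1.96) -> tuple[float, float]:
        return (
            float(np.exp(self.log_rate_ratio - z * self.se_log_rate_ratio)),
            float(np.exp(self.log_rate_ratio + z * self.se_log_rate_ratio)),
        )


def fit_loglinear(
    df: pd.DataFrame,
    cost_col: str = "total",
    weight_col: str = "birth_weight_g",
) -> LogLinearFit:
    """OLS of log(cost) on birth weight in kg.

    Negative costs are an error; zero-cost records cannot be
    log-transformed and are dropped with a warning (the survey's minimum
    observed cost was strictly positive, so none are expected in
    practice).
    """
    cost = df[cost_col].to_numpy(dtype=float)
    if (cost < 0).any():
        bad = df.index[cost < 0].tolist()
        raise ValueError(f"negative costs at records {bad}")
    keep = cost > 0
    if not keep.all():
        log.warning("dropping %d zero-cost records from log-linear fit", (~keep).sum())
    cost = cost[keep]
    weight_kg = df[weight_col].to_numpy(dtype=float)[keep] / 1000.0
    if cost.size < 3:
        raise ValueError(f"need at least 3 positive-cost records, got {cost.size}")
    X = sm.add_constant(weight_kg)
    res = sm.OLS(np.log(cost), X).fit()
    return LogLinearFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_slope=float(res.bse[1]),
        se_intercept=float(res.bse[0]),
        n=int(cost.size),
    )


def percent_change_per_100g(fit: LogLinearFit) -> dict[str, float]:
    """Percent cost reduction for a 100 g birth-weight increase.

    ``linear_approx`` reads the log-scale coefficient directly as a
    percentage (-100 * 0.1 * slope); ``exact`` converts it to the exact
    multiplicative effect ``100 * (1 - exp(0.1 * slope))``.  For a steep
    negative slope the two differ materially; both are reported.
    """
    d = 0.1 * fit.slope  # log-cost change per +100 g
    return {
        "exact": 100.0 * (1.0 - np.exp(d)),
        "linear_approx": -100.0 * d,
    }


def fit_poisson(
    df: pd.DataFrame,
    count_col: str = "n_admissions",
    weight_col: str = "birth_weight_g",
) -> PoissonFit:
    """Poisson GLM of first-year admissions on LBW status.

    Exposure is fixed at one infant-year per child.  With a single
    binary covariate the model is saturated, so the fitted rate ratio
    equals the ratio of the two groups' sample mean admission counts.
    """
    y = df[count_col].to_numpy(dtype=float)
    if (y < 0).any() or np.any(y % 1 != 0):
        raise ValueError("admission counts must be non-negative integers")
    lbw = (df[weight_col].to_numpy(dtype=float) < LBW_THRESHOLD_G).astype(float)
    if lbw.min() == lbw.max():
        raise ValueError("need both LBW and non-LBW infants to fit a rate ratio")
    X = sm.add_constant(lbw)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return PoissonFit(
        baseline_log_rate=float(res.params[0]),
        log_rate_ratio=float(res.params[1]),
        se_log_rate_ratio=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n=int(y.size),
    )
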