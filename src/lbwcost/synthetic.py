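"""Synthetic exit-survey and follow-up-cohort generator.

No microdata from the original exit survey were ever published, so this
module generates survey records and a one-year follow-up cohort with the
statistical structure the analysis assumes:

* routine-arm interviews (default 87) with LBW birth weights averaging
  2.26 kg, total household costs following the log-linear
  cost-weight law ``cost = exp(13.58 - 5.30 * weight_kg)`` with
  multiplicative log-normal noise, a small VLBW tail that produces a
  high-cost referral-type outlier, and 84% housewife caretakers;
* admission-arm interviews (default 46) with mean total cost 8.50 US$
  of which ~75% is indirect;
* a follow-up cohort (default 990 infants, 117 LBW) with Poisson
  admission counts at baseline rate 0.235/infant-year and rate ratio
  1.52 for LBW, and death flags from the LBW/VLBW case-fatality rates.

Generation is fully deterministic given (config, seed): the same pair
always yields byte-identical CSV output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .household import SURVEY_COLUMNS, HouseholdCostConfig

__all__ = [
    "COHORT_COLUMNS",
    "SyntheticConfig",
    "generate_cohort",
    "generate_survey",
    "truncated_normal",
    "write_provenance",
    "write_table",
]

COHORT_COLUMNS = ["birth_weight_g", "lbw_flag", "n_admissions", "died_flag"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Calibration of the synthetic survey and cohort generators.

    Counts, shares and regression coefficients default to the study's
    reported figures; the birth-weight SD and the log-cost noise SD are
    free calibration choices (only the weight mean and cost-curve
    coefficients were reported).
    """

    n_routine: int = 87
    n_admission: int = 46
    weight_mean_g: float = 2260.0
    weight_sd_g: float = 200.0
    weight_low_g: float = 1000.0
    weight_high_g: float = 2500.0
    female_share: float = 0.69
    vlbw_share: float = 1.0 / 87.0
    cost_intercept: float = 13.58
    cost_slope_per_kg: float = -5.30
    cost_noise_sd_log: float = 1.0
    admission_mean_total: float = 8.50
    admission_indirect_share: float = 0.75
    housewife_share: float = 0.84
    cohort_n: int = 990
    cohort_lbw: int = 117
    cohort_vlbw_share: float = 0.01
    cfr_lbw: float = 0.12
    cfr_vlbw: float = 0.80
    admission_rate_non_lbw: float = 0.235
    admission_rate_ratio: float = 1.52
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "female_share",
            "vlbw_share",
            "admission_indirect_share",
            "housewife_share",
            "cohort_vlbw_share",
            "cfr_lbw",
            "cfr_vlbw",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_routine", "n_admission", "cohort_n", "cohort_lbw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cohort_lbw > self.cohort_n:
            raise ValueError("cohort_lbw cannot exceed cohort_n")
        if not 0 < self.weight_low_g < self.weight_high_g <= 2500.0:
            raise ValueError("LBW weight bounds must satisfy 0 < low < high <= 2500")
        if self.weight_sd_g <= 0 or self.cost_noise_sd_log < 0:
            raise ValueError("scale parameters must be positive")
        if self.admission_rate_non_lbw < 0 or self.admission_rate_ratio <= 0:
            raise ValueError("admission rates must be positive")


# ---------------------------------------------------------------------------
# Truncated-normal sampling with a calibrated mean
# ---------------------------------------------------------------------------

def _truncnorm(loc: float, sd: float, low: float, high: float) -> stats.rv_continuous:
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


@lru_cache(maxsize=128)
def _calibrated_loc(target_mean: float, sd: float, low: float, high: float) -> float:
    """Location parameter whose truncated-normal mean equals ``target_mean``.

    Truncation shifts the realised mean away from the location parameter
    (here the 2.5 kg LBW cutoff sits ~1.2 SD above the mean), so the
    location is solved for rather than set to the target.
    """
    if not low < target_mean < high:
        raise ValueError("target mean must lie strictly inside the truncation bounds")

    def gap(loc: float) -> float:
        return _truncnorm(loc, sd, low, high).mean() - target_mean

    span = 10.0 * sd
    return float(optimize.brentq(gap, target_mean - span, target_mean + span, xtol=1e-8))


def truncated_normal(
    mean: float,
    sd: float,
    low: float,
    high: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draws from a truncated normal whose *realised* mean is ``mean``."""
    loc = _calibrated_loc(mean, sd, low, high)
    return _truncnorm(loc, sd, low, high).rvs(size=n, random_state=rng)


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

def _split_costs(
    total: np.ndarray,
    indirect_share: np.ndarray,
    occupation: np.ndarray,
    rng: np.random.Generator,
    hh: HouseholdCostConfig,
) -> pd.DataFrame:
    """Decompose per-record totals into the survey's cost fields.

    The split is constructed so that the household model reconstructs
    the same direct/indirect/total values from the raw fields: housewife
    indirect cost is encoded as hours lost at the minimum-wage rate,
    wage-earner indirect cost as reported income loss.
    """
    indirect = total * indirect_share
    direct = total - indirect
    user_fees = np.minimum(hh.user_fee, direct)
    rest = direct - user_fees
    transport_frac = rng.uniform(0.35, 0.65, size=total.size)
    accom_frac = rng.uniform(0.0, 0.2, size=total.size)
    wage_per_hour = hh.minimum_monthly_wage / hh.monthly_working_hours
    housewife = occupation == "housewife"
    return pd.DataFrame(
        {
            "transport_cost": rest * transport_frac,
            "food_cost": rest * (1.0 - transport_frac - accom_frac),
            "accommodation_cost": rest * accom_frac,
            "user_fees": user_fees,
            "hours_lost": np.where(housewife, indirect / wage_per_hour, 0.0),
            "reported_income_loss": np.where(housewife, 0.0, indirect),
        }
    )


def generate_survey(
    config: SyntheticConfig = SyntheticConfig(),
    seed: int | None = None,
    household_config: HouseholdCostConfig = HouseholdCostConfig(),
) -> pd.DataFrame:
    """Generate the exit-survey microdata (routine + admission arms)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # --- routine arm ---------------------------------------------------
    n = config.n_routine
    n_vlbw = max(1, round(config.vlbw_share * n)) if config.vlbw_share > 0 else 0
    vlbw_mean = min(1400.0, config.weight_mean_g)
    w_vlbw = truncated_normal(vlbw_mean, 100.0, config.weight_low_g, 1500.0, n_vlbw, rng)
    # compensate the VLBW tail so the arm-level mean stays on target
    rest_target = (n * config.weight_mean_g - n_vlbw * vlbw_mean) / (n - n_vlbw)
    w_rest = truncated_normal(
        rest_target, config.weight_sd_g, 1500.0, config.weight_high_g, n - n_vlbw, rng
    )
    weights = np.concatenate([w_vlbw, w_rest])

    eps = (
        rng.normal(0.0, config.cost_noise_sd_log, size=n)
        if config.cost_noise_sd_log > 0
        else np.zeros(n)
    )
    totals = np.exp(
        config.cost_intercept + config.cost_slope_per_kg * weights / 1000.0 + eps
    )
    occupation = np.where(
        rng.random(n) < config.housewife_share, "housewife", "wage_earner"
    )
    share = rng.beta(2.0, 2.0, size=n)
    routine = _split_costs(totals, share, occupation, rng, household_config)
    routine.insert(0, "id", [f"R{i + 1:03d}" for i in range(n)])
    routine.insert(1, "arm", "routine")
    routine.insert(2, "birth_weight_g", weights)
    routine.insert(
        3, "sex", np.where(rng.random(n) < config.female_share, "female", "male")
    )
    routine.insert(4, "occupation", occupation)
    routine["n_admissions"] = rng.poisson(
        config.admission_rate_non_lbw * config.admission_rate_ratio, size=n
    )

    # --- admission arm -------------------------------------------------
    m = config.n_admission
    w_adm = truncated_normal(
        config.weight_mean_g, config.weight_sd_g, config.weight_low_g,
        config.weight_high_g, m, rng,
    )
    shape = 2.0
    totals_adm = rng.gamma(shape, config.admission_mean_total / shape, size=m)
    occ_adm = np.where(
        rng.random(m) < config.housewife_share, "housewife", "wage_earner"
    )
    # Beta with mean = admission_indirect_share, concentration 8
    conc = 8.0
    share_adm = rng.beta(
        conc * config.admission_indirect_share,
        conc * (1.0 - config.admission_indirect_share),
        size=m,
    )
    admission = _split_costs(totals_adm, share_adm, occ_adm, rng, household_config)
    admission.insert(0, "id", [f"A{i + 1:03d}" for i in range(m)])
    admission.insert(1, "arm", "admission")
    admission.insert(2, "birth_weight_g", w_adm)
    admission.insert(
        3, "sex", np.where(rng.random(m) < config.female_share, "female", "male")
    )
    admission.insert(4, "occupation", occ_adm)
    admission["n_admissions"] = 1 + rng.poisson(0.2, size=m)

    df = pd.concat([routine, admission], ignore_index=True)[SURVEY_COLUMNS]
    return df


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(), seed: int | None = None
) -> pd.DataFrame:
    """Generate the one-year follow-up cohort table.

    ``cohort_lbw`` of ``cohort_n`` infants are LBW (including a VLBW
    subgroup); admission counts are Poisson with the configured baseline
    rate and LBW rate ratio; death flags follow the LBW/VLBW
    case-fatality rates (non-LBW background mortality is not modelled —
    it cancels from every incremental quantity).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, n_lbw = config.cohort_n, config.cohort_lbw
    n_vlbw = min(round(config.cohort_vlbw_share * n), n_lbw)

    w_vlbw = truncated_normal(1400.0, 100.0, 1000.0, 1500.0, n_vlbw, rng)
    w_lbw = truncated_normal(
        config.weight_mean_g, config.weight_sd_g, 1500.0, 2500.0, n_lbw - n_vlbw, rng
    )
    w_non = truncated_normal(3100.0, 450.0, 2500.0, 5000.0, n - n_lbw, rng)
    weights = np.concatenate([w_vlbw, w_lbw, w_non])
    lbw_flag = np.concatenate(
        [np.ones(n_lbw, dtype=bool), np.zeros(n - n_lbw, dtype=bool)]
    )

    rate = np.where(
        lbw_flag,
        config.admission_rate_non_lbw * config.admission_rate_ratio,
        config.admission_rate_non_lbw,
    )
    admissions = rng.poisson(rate)
    death_p = np.zeros(n)
    death_p[:n_vlbw] = config.cfr_vlbw
    death_p[n_vlbw:n_lbw] = config.cfr_lbw
    died = rng.random(n) < death_p

    df = pd.DataFrame(
        {
            "birth_weight_g": weights,
            "lbw_flag": lbw_flag,
            "n_admissions": admissions,
            "died_flag": died,
        }
    )
    # randomise row order (reproducibly) so LBW status is not positional
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a generated table to CSV (deterministic byte output)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def write_provenance(
    config: SyntheticConfig, seed: int, csv_path: str | Path, out_path: str | Path
) -> Path:
    """Record the generating config, seed and a content hash of the CSV."""
    csv_path, out_path = Path(csv_path), Path(out_path)
    digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    payload = {
        "config": asdict(config),
        "seed": int(seed),
        "file": csv_path.name,
        "sha256": digest,
    }
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out_path
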