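"""Health-system cost model: eight-component Monte Carlo simulation of the
cost of routine LBW care and excess morbidity per birth cohort.

For a reference cohort of 1000 live births (by default 12% LBW, 1% VLBW)
the model prices, per Monte Carlo draw:

* iron and multivitamin supplementation for all LBW babies (90 days),
* incremental nights of admission after delivery at the district
  hospital (sampled nights minus the one night attributed to delivery),
* transport of transferred newborns to the referral hospital,
* their admission there (14-21 nights at the referral bed-day cost),
* weekly weighing visits priced as nurse time,
* one excess all-cause admission episode per surviving LBW baby during
  the first year of life, and
* kangaroo-mother-care training, again as nurse time.

Prevalences and unit costs are drawn from their declared distributions;
baby counts are kept fractional (expected-value semantics).  The total is
the per-draw sum of the components, so additivity holds draw by draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .household import WeightGainTable, visit_counts
from .psa import (
    DEFAULT_DRAWS,
    DistributionSpec,
    SimulationResult,
    child_seed,
    summarize,
)

__all__ = [
    "COMPONENT_ORDER",
    "CohortSpec",
    "ComponentBreakdown",
    "HealthSystemInputs",
    "per_baby_costs",
    "scale_to_population",
    "simulate_cohort_costs",
]

#: Reporting order of the eight cost components.
COMPONENT_ORDER = [
    "iron",
    "multivitamins",
    "admission_after_delivery",
    "transport_referral",
    "admission_referral",
    "routine_visits",
    "excess_admissions",
    "kmc_training",
]


@dataclass(frozen=True)
class CohortSpec:
    """Birth-cohort composition and fate assumptions (per ``n_births`` births)."""

    n_births: int = 1000
    lbw_prevalence: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(0.10, 0.12, 0.14)
    )
    vlbw_prevalence: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(0.008, 0.01, 0.012)
    )
    cfr_lbw: float = 0.12
    cfr_vlbw: float = 0.80
    #: transfers to the referral hospital per n_births births (all VLBW plus
    #: ~30% of the 1.5-2.0 kg band)
    n_transferred: float = 33.0
    #: LBW babies with one excess admission episode in the first year
    n_excess_admission_babies: float = 112.0
    #: mean and SD of the LBW birth-weight distribution, used for the
    #: weighing-visit schedule
    lbw_weight_mean_g: float = 2260.0
    lbw_weight_sd_g: float = 200.0

    def __post_init__(self) -> None:
        if self.n_births <= 0:
            raise ValueError("n_births must be positive")
        if self.vlbw_prevalence.mode > self.lbw_prevalence.mode:
            raise ValueError("VLBW prevalence cannot exceed LBW prevalence")
        for name in ("cfr_lbw", "cfr_vlbw"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_transferred", "n_excess_admission_babies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_lbw_mode(self) -> float:
        return self.n_births * self.lbw_prevalence.mode


@dataclass(frozen=True)
class HealthSystemInputs:
    """Unit costs, quantities and distributions of the eight components."""

    bed_day_district: float = 17.28
    bed_day_referral: float = 51.84
    nights_after_delivery: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.uniform(2.0, 4.0)
    )
    nights_referral: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.uniform(14.0, 21.0)
    )
    nights_per_admission: float = 6.0
    iron_tablet_price: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(0.0013, 0.0072, 0.0171)
    )
    iron_tablet_fraction: float = 0.25  # quarter tablet per day
    iron_days: float = 90.0
    multivitamin_price: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(0.0018, 0.0044, 0.0777)
    )
    multivitamin_days: float = 90.0
    nurse_monthly_wage: float = 324.0
    nurse_per_minute: float = 0.03375
    visit_minutes: float = 5.0
    kmc_minutes: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(5.0, 7.0, 15.0)
    )
    kmc_proportion: float = 0.5
    fuel_price: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(0.60, 1.0, 1.35)
    )
    distance_km: float = 80.0
    fuel_litres_per_km: float = 0.12
    driver_hours: float = 3.0
    driver_hourly: float = 0.27
    #: calibrated all-inclusive cost per transfer (vehicle, staff, overheads);
    #: the bare fuel+driver ingredients are reported alongside for comparison
    transport_per_transfer: float = 147.56
    #: optional Metical/US$ exchange-rate uncertainty, multiplicative
    exchange_rate: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.point(1.0)
    )

    def __post_init__(self) -> None:
        for name in (
            "bed_day_district",
            "bed_day_referral",
            "nights_per_admission",
            "nurse_monthly_wage",
            "nurse_per_minute",
            "visit_minutes",
            "distance_km",
            "driver_hours",
            "driver_hourly",
            "transport_per_transfer",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.kmc_proportion <= 1:
            raise ValueError("kmc_proportion must be in [0, 1]")


@dataclass(frozen=True)
class ComponentBreakdown:
    """Per-component simulation summaries plus the per-draw total."""

    components: dict[str, SimulationResult]
    total: SimulationResult
    component_draws: dict[str, np.ndarray]
    total_draws: np.ndarray
    n_births: float
    seed: int | None
    #: transport cost re-estimated from bare ingredients (fuel + driver time)
    transport_ingredient: SimulationResult | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENT_ORDER if c not in self.components]
        if missing:
            raise ValueError(f"component set incomplete, missing: {missing}")


def simulate_cohort_costs(
    cohort: CohortSpec = CohortSpec(),
    inputs: HealthSystemInputs = HealthSystemInputs(),
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    gains: WeightGainTable = WeightGainTable(),
    visit_weight_panel_size: int = 200,
) -> ComponentBreakdown:
    """Monte Carlo simulation of the eight health-system cost components.

    Each uncertain input draws from its own deterministic child stream of
    ``seed``, so components are independent and adding one never
    perturbs another.  Baby counts are fractional expected values.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    def draw(spec: DistributionSpec, name: str) -> np.ndarray:
        return spec.sample(n_draws, child_seed(seed, name))

    n_lbw = cohort.n_births * draw(cohort.lbw_prevalence, "lbw_prevalence")

    comp: dict[str, np.ndarray] = {}
    comp["iron"] = (
        n_lbw * inputs.iron_days * inputs.iron_tablet_fraction
        * draw(inputs.iron_tablet_price, "iron_price")
    )
    comp["multivitamins"] = (
        n_lbw * inputs.multivitamin_days * draw(inputs.multivitamin_price, "multi_price")
    )
    nights_delivery = draw(inputs.nights_after_delivery, "nights_after_delivery")
    comp["admission_after_delivery"] = (
        n_lbw * np.maximum(nights_delivery - 1.0, 0.0) * inputs.bed_day_district
    )
    comp["transport_referral"] = np.full(
        n_draws, cohort.n_transferred * inputs.transport_per_transfer
    )
    comp["admission_referral"] = (
        cohort.n_transferred
        * draw(inputs.nights_referral, "nights_referral")
        * inputs.bed_day_referral
    )
    comp["routine_visits"] = (
        n_lbw
        * _mean_visits(cohort, gains, n_draws, seed, visit_weight_panel_size)
        * inputs.visit_minutes
        * inputs.nurse_per_minute
    )
    comp["excess_admissions"] = np.full(
        n_draws,
        cohort.n_excess_admission_babies * inputs.nights_per_admission * inputs.bed_day_district,
    )
    comp["kmc_training"] = (
        inputs.kmc_proportion * n_lbw
        * draw(inputs.kmc_minutes, "kmc_minutes")
        * inputs.nurse_per_minute
    )

    fx = draw(inputs.exchange_rate, "exchange_rate")
    comp = {k: v * fx for k, v in comp.items()}
    total = np.sum([comp[k] for k in COMPONENT_ORDER], axis=0)

    ingredient_per_transfer = (
        inputs.driver_hours * inputs.driver_hourly
        + draw(inputs.fuel_price, "fuel_price")
        * inputs.distance_km * inputs.fuel_litres_per_km
    )
    transport_ing = summarize(cohort.n_transferred * ingredient_per_transfer * fx, seed=seed)

    return ComponentBreakdown(
        components={k: summarize(comp[k], seed=seed) for k in COMPONENT_ORDER},
        total=summarize(total, seed=seed),
        component_draws=comp,
        total_draws=total,
        n_births=float(cohort.n_births),
        seed=seed,
        transport_ingredient=transport_ing,
    )


def _mean_visits(
    cohort: CohortSpec,
    gains: WeightGainTable,
    n_draws: int,
    seed: int,
    panel_size: int,
) -> np.ndarray:
    """Per-draw mean number of weighing visits per LBW baby.

    Uses a fixed panel of representative LBW birth weights and a per-draw
    triangular scale on the daily-gain table.
    """
    from .synthetic import truncated_normal  # local import avoids a cycle

    rng = np.random.default_rng(child_seed(seed, "visit_weights"))
    panel = truncated_normal(
        cohort.lbw_weight_mean_g, cohort.lbw_weight_sd_g, 1000.0, 2500.0, panel_size, rng
    )
    scale = gains.gain_scale_spec().sample(n_draws, child_seed(seed, "gain_scale"))
    counts = visit_counts(panel[None, :], gains, scale[:, None])
    return counts.mean(axis=1)


def scale_to_population(breakdown: ComponentBreakdown, n_births_target: float) -> ComponentBreakdown:
    """Linearly scale all monetary summaries to a different cohort size."""
    if n_births_target <= 0:
        raise ValueError(f"n_births_target must be > 0, got {n_births_target}")
    f = n_births_target / breakdown.n_births
    return ComponentBreakdown(
        components={k: v.scaled(f) for k, v in breakdown.components.items()},
        total=breakdown.total.scaled(f),
        component_draws={k: v * f for k, v in breakdown.component_draws.items()},
        total_draws=breakdown.total_draws * f,
        n_births=float(n_births_target),
        seed=breakdown.seed,
        transport_ingredient=(
            breakdown.transport_ingredient.scaled(f)
            if breakdown.transport_ingredient is not None
            else None
        ),
    )


def per_baby_costs(
    breakdown: ComponentBreakdown,
    cohort: CohortSpec = CohortSpec(),
    inputs: HealthSystemInputs = HealthSystemInputs(),
) -> dict[str, float]:
    """Average health-system cost per baby.

    ``incremental_per_lbw`` spreads the simulated cohort total over the
    best-estimate number of LBW babies; ``average_non_lbw`` is the
    routine cost of a non-LBW baby (one post-delivery bed-day plus an
    average admission episode); ``average_lbw`` is their sum.
    """
    n_lbw = cohort.n_lbw_mode
    if n_lbw <= 0:
        raise ValueError("cohort has zero LBW babies at the best estimate")
    incremental = breakdown.total.mean / n_lbw
    average_non_lbw = inputs.bed_day_district * (1.0 + inputs.nights_per_admission)
    return {
        "incremental_per_lbw": incremental,
        "average_non_lbw": average_non_lbw,
        "average_lbw": incremental + average_non_lbw,
    }
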