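"""Eight-component health-system cost simulation."""

import dataclasses

import numpy as np
import pytest

from lbwcost.health_system import (
    COMPONENT_ORDER,
    CohortSpec,
    HealthSystemInputs,
    per_baby_costs,
    scale_to_population,
    simulate_cohort_costs,
)
from lbwcost.household import WeightGainTable
from lbwcost.psa import DistributionSpec

DRAWS = 10_000


@pytest.fixture(scope="module")
def breakdown(cohort, hs_inputs):
    return simulate_cohort_costs(cohort, hs_inputs, n_draws=DRAWS, seed=1)


def all_point_setup():
    """Every uncertain input collapsed to its best estimate."""
    cohort = CohortSpec(
        lbw_prevalence=DistributionSpec.point(0.12),
        vlbw_prevalence=DistributionSpec.point(0.01),
    )
    inputs = HealthSystemInputs(
        nights_after_delivery=DistributionSpec.point(3.0),
        nights_referral=DistributionSpec.point(17.5),
        iron_tablet_price=DistributionSpec.point(0.0072),
        multivitamin_price=DistributionSpec.point(0.0044),
        kmc_minutes=DistributionSpec.point(7.0),
        fuel_price=DistributionSpec.point(1.0),
    )
    gains = WeightGainTable(variability=1e-9)
    return cohort, inputs, gains


class TestComponentMeans:
    def test_multivitamins_closed_form_mean(self, breakdown):
        # 120 LBW x 90 days x triangular-mean price
        expected = 120 * 90 * (0.0018 + 0.0044 + 0.0777) / 3
        assert breakdown.components["multivitamins"].mean == pytest.approx(expected, rel=0.02)

    def test_excess_admissions_exact_arithmetic(self, breakdown):
        res = breakdown.components["excess_admissions"]
        assert res.mean == pytest.approx(112 * 6 * 17.28, abs=1e-9)
        assert res.ci_low == res.ci_high == pytest.approx(res.mean, rel=1e-12)

    def test_referral_admission_uniform_mean(self, breakdown):
        assert breakdown.components["admission_referral"].mean == pytest.approx(
            33 * 17.5 * 51.84, rel=0.01
        )

    def test_post_delivery_incremental_nights(self, breakdown):
        # (U(2,4) - 1) averages 2 attributable nights per LBW baby
        assert breakdown.components["admission_after_delivery"].mean == pytest.approx(
            120 * 2 * 17.28, rel=0.02
        )

    def test_transport_uses_calibrated_per_transfer_cost(self, breakdown):
        res = breakdown.components["transport_referral"]
        assert res.mean == pytest.approx(33 * 147.56, abs=1e-9)
        # the bare fuel+driver ingredients are far below and reported separately
        assert breakdown.transport_ingredient.mean < res.mean

    def test_component_set_complete(self, breakdown):
        assert set(breakdown.components) == set(COMPONENT_ORDER)


class TestInvariants:
    def test_draw_level_additivity_exact(self, breakdown):
        stacked = np.sum([breakdown.component_draws[k] for k in COMPONENT_ORDER], axis=0)
        np.testing.assert_array_equal(stacked, breakdown.total_draws)

    def test_deterministic_given_seed(self, cohort, hs_inputs):
        a = simulate_cohort_costs(cohort, hs_inputs, n_draws=500, seed=9)
        b = simulate_cohort_costs(cohort, hs_inputs, n_draws=500, seed=9)
        np.testing.assert_array_equal(a.total_draws, b.total_draws)

    def test_point_collapse_gives_zero_ci_width(self):
        cohort, inputs, gains = all_point_setup()
        bd = simulate_cohort_costs(cohort, inputs, n_draws=200, seed=0, gains=gains)
        assert bd.total.ci_low == bd.total.ci_high == bd.total.mean
        for res in bd.components.values():
            assert res.ci_low == res.ci_high

    @pytest.mark.parametrize(
        "field, component",
        [
            ("bed_day_district", "excess_admissions"),
            ("bed_day_referral", "admission_referral"),
            ("nurse_per_minute", "routine_visits"),
        ],
    )
    def test_monotone_in_unit_cost(self, cohort, hs_inputs, field, component):
        bumped = dataclasses.replace(hs_inputs, **{field: getattr(hs_inputs, field) * 1.5})
        base = simulate_cohort_costs(cohort, hs_inputs, n_draws=500, seed=3)
        up = simulate_cohort_costs(cohort, bumped, n_draws=500, seed=3)
        assert up.components[component].mean > base.components[component].mean

    def test_monotone_in_cohort_size(self, cohort, hs_inputs):
        bigger = dataclasses.replace(cohort, n_births=2000)
        base = simulate_cohort_costs(cohort, hs_inputs, n_draws=500, seed=3)
        up = simulate_cohort_costs(bigger, hs_inputs, n_draws=500, seed=3)
        assert up.total.mean > base.total.mean


class TestScaling:
    def test_scale_by_one_is_identity(self, breakdown):
        scaled = scale_to_population(breakdown, breakdown.n_births)
        assert scaled.total.mean == breakdown.total.mean

    def test_scale_round_trip(self, breakdown):
        twice = scale_to_population(breakdown, 2000)
        back = scale_to_population(twice, 1000)
        assert back.total.mean == pytest.approx(breakdown.total.mean, rel=1e-12)
        np.testing.assert_allclose(back.total_draws, breakdown.total_draws)

    def test_scaling_is_linear(self, breakdown):
        scaled = scale_to_population(breakdown, 3322)
        assert scaled.total.mean == pytest.approx(breakdown.total.mean * 3.322, rel=1e-12)

    def test_non_positive_target_rejected(self, breakdown):
        with pytest.raises(ValueError):
            scale_to_population(breakdown, 0)


class TestPerBaby:
    def test_average_costs(self, breakdown, cohort, hs_inputs):
        pb = per_baby_costs(breakdown, cohort, hs_inputs)
        assert pb["average_non_lbw"] == pytest.approx(17.28 * 7)
        assert pb["incremental_per_lbw"] == pytest.approx(breakdown.total.mean / 120)
        assert pb["average_lbw"] == pytest.approx(
            pb["incremental_per_lbw"] + pb["average_non_lbw"]
        )

    def test_zero_lbw_cohort_rejected(self, breakdown, hs_inputs):
        empty = CohortSpec(lbw_prevalence=DistributionSpec.point(0.0),
                           vlbw_prevalence=DistributionSpec.point(0.0))
        with pytest.raises(ValueError):
            per_baby_costs(breakdown, empty, hs_inputs)


def test_vlbw_prevalence_cannot_exceed_lbw():
    with pytest.raises(ValueError):
        CohortSpec(
            lbw_prevalence=DistributionSpec.point(0.01),
            vlbw_prevalence=DistributionSpec.point(0.02),
        )
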