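"""Household cost model: visit schedule, cost perturbation, time valuation."""

import numpy as np
import pandas as pd
import pytest

from lbwcost.household import (
    HouseholdCostConfig,
    WeightGainTable,
    admission_household_cost,
    indirect_cost_from_time,
    record_totals,
    routine_household_cost,
    validate_survey,
    visit_count,
    visit_counts,
)

SINGLE_BAND_20 = WeightGainTable(bands=((0.0, 2500.0, 20.0),))


def make_survey(rows):
    defaults = {
        "id": "X",
        "arm": "routine",
        "birth_weight_g": 2200.0,
        "sex": "female",
        "occupation": "housewife",
        "transport_cost": 0.0,
        "food_cost": 0.0,
        "accommodation_cost": 0.0,
        "user_fees": 0.0,
        "hours_lost": 0.0,
        "reported_income_loss": 0.0,
        "n_admissions": 0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestVisitCount:
    def test_at_threshold_needs_no_visits(self):
        assert visit_count(2500.0) == 0
        assert visit_count(2600.0) == 0

    def test_one_week_closes_small_gap(self):
        # 100 g gap at 20 g/day = 140 g/week -> one (confirmatory) visit
        assert visit_count(2400.0, SINGLE_BAND_20) == 1

    def test_two_weeks_for_wider_gap(self):
        # 200 g gap at 140 g/week needs two weekly visits
        assert visit_count(2300.0, SINGLE_BAND_20) == 2

    def test_non_increasing_in_birth_weight(self):
        weights = np.arange(1000.0, 2600.0, 25.0)
        counts = visit_counts(weights)
        assert np.all(np.diff(counts) <= 0)

    def test_non_increasing_in_daily_gain(self):
        counts = [visit_count(1800.0, scale=s) for s in (0.5, 0.75, 1.0, 1.5, 2.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mean_visits_match_observed_schedule(self, survey):
        """Weights like the study arm (mean 2.26 kg) imply ~2.1 weekly visits,
        in line with the observed average of 2.13."""
        routine = survey[survey["arm"] == "routine"]
        mean_n = visit_counts(routine["birth_weight_g"].to_numpy()).mean()
        assert 1.8 < mean_n < 2.5

    def test_non_positive_weight_rejected(self):
        with pytest.raises(ValueError):
            visit_count(0.0)

    def test_band_table_must_partition(self):
        with pytest.raises(ValueError):
            WeightGainTable(bands=((0.0, 1800.0, 20.0), (2000.0, 2500.0, 25.0)))


class TestIndirectCost:
    def test_wage_earner_pass_through(self):
        assert indirect_cost_from_time(5.0, "wage_earner", 12.0) == 12.0

    def test_housewife_zero_hours(self):
        assert indirect_cost_from_time(0.0, "housewife", 99.0) == 0.0

    def test_housewife_full_month_earns_minimum_wage(self):
        # 208 h = one month at the 48 h/week convention
        assert indirect_cost_from_time(208.0, "housewife", 0.0) == pytest.approx(37.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            indirect_cost_from_time(-1.0, "housewife", 0.0)


class TestRecordTotals:
    def test_total_is_direct_plus_indirect(self, survey, hh_config):
        totals = record_totals(survey, hh_config)
        np.testing.assert_allclose(
            totals["total"], totals["direct"] + totals["indirect"], rtol=1e-12
        )
        assert (totals[["direct", "indirect"]] >= 0).to_numpy().all()

    def test_schema_validation(self, survey):
        validate_survey(survey)
        with pytest.raises(ValueError, match="missing columns"):
            validate_survey(survey.drop(columns=["user_fees"]))
        bad = survey.copy()
        bad.loc[0, "transport_cost"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            validate_survey(bad)


class TestRoutineCost:
    def test_single_record_mean_preserved(self):
        # the +/-25% triangular perturbation is mean-preserving
        df = make_survey([{"reported_income_loss": 10.0, "occupation": "wage_earner"}])
        res = routine_household_cost(df, n_draws=50_000, seed=0)
        assert res.mean == pytest.approx(10.0, rel=0.005)
        assert 7.5 <= res.ci_low < res.ci_high <= 12.5

    def test_synthetic_cohort_is_positively_skewed(self, survey, hh_config):
        totals = record_totals(survey, hh_config)
        routine = totals[totals["arm"] == "routine"]["total"]
        assert routine.mean() > 2 * routine.median()

    def test_identical_records_ci_width_from_perturbation_only(self):
        df = make_survey(
            [{"id": f"r{i}", "reported_income_loss": 8.0, "occupation": "wage_earner"}
             for i in range(40)]
        )
        res = routine_household_cost(df, n_draws=20_000, seed=1)
        # mean of 40 iid triangular perturbations: CI half-width ~ 2*sd/sqrt(40)
        sd_one = 8.0 * 0.25 / np.sqrt(6)
        half = 1.96 * sd_one / np.sqrt(40)
        assert res.ci_high - res.ci_low == pytest.approx(2 * half, rel=0.1)

    def test_empty_arm_rejected(self):
        df = make_survey([{"arm": "admission"}])
        with pytest.raises(ValueError, match="routine"):
            routine_household_cost(df)


class TestAdmissionCost:
    def test_all_direct_records_have_zero_indirect_share(self):
        df = make_survey([{"arm": "admission", "transport_cost": 4.0}])
        res, share = admission_household_cost(df, n_draws=2000, seed=0)
        assert share == 0.0
        assert res.mean == pytest.approx(4.0, rel=0.02)

    def test_single_record_share(self):
        df = make_survey(
            [{"arm": "admission", "transport_cost": 2.0,
              "reported_income_loss": 6.0, "occupation": "wage_earner"}]
        )
        res, share = admission_household_cost(df, n_draws=50_000, seed=0)
        assert share == pytest.approx(0.75, abs=0.01)
        assert res.mean == pytest.approx(8.0, rel=0.01)

    def test_synthetic_cohort_recovers_generator_moments(self, survey, hh_config):
        res, share = admission_household_cost(survey, hh_config, n_draws=20_000, seed=2)
        assert res.mean == pytest.approx(8.50, rel=0.25)
        assert share == pytest.approx(0.75, abs=0.08)
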