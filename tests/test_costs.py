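"""Cost conversions, event models, line splitting, cost accumulation."""

import numpy as np
import pytest

from psmcea.config import CostInputs, DrugSpec
from psmcea.costs import (
    EventModel,
    accumulate_costs,
    build_bm_trace,
    line_split,
    monthly_to_weekly,
    weekly_ae_probability,
    weekly_drug_cost,
)
from psmcea.engine import ModelSettings, OccupancyTrace, compute_occupancy
from psmcea.survival import SurvivalCurve

from .test_survival import exponential_fit


def flat_curve(n_weeks, value=1.0):
    surv = np.ones(n_weeks + 1)
    surv[1:] = value
    return SurvivalCurve(surv)


def simple_cost_inputs(**overrides):
    base = dict(
        chemo_admin_per_session=0.0,
        monitoring_first_line={"a": 0.0},
        monitoring_second_line=0.0,
        monitoring_third_line=0.0,
        management_weekly_pfs=0.0,
        management_weekly_pps=0.0,
        bm_weekly=0.0,
        transport_round_trip=0.0,
        ae_event_costs={},
        ae_cost_multiplier={"a": 1.0},
        ae_reweighting={"a": 1.0},
        second_line_duration_weeks=50.1,
        first_line_drug={"a": "drug1"},
        second_line_mix={"a": {"drug1": 1.0}},
        third_line_mix={"a": {"drug1": 1.0}},
    )
    base.update(overrides)
    return CostInputs(**base)


DRUGS = {"drug1": DrugSpec(kind="oral", monthly_cost=1000.0)}


class TestConversions:
    def test_bm_monthly_cost_matches_published_weekly(self):
        assert round(monthly_to_weekly(495.31), 2) == 114.30

    def test_zero(self):
        assert monthly_to_weekly(0.0) == 0.0

    def test_alectinib_monthly(self):
        assert monthly_to_weekly(4993.63) == pytest.approx(1152.38, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            monthly_to_weekly(-1.0)

    def test_iv_drug_weekly_cost_spreads_session_over_interval(self):
        drug = DrugSpec(kind="iv", session_cost=1350.0, session_interval_days=21.0)
        assert weekly_drug_cost(drug, 419.57) == pytest.approx((1350.0 + 419.57) * 7 / 21)


class TestWeeklyAeProbability:
    def test_zero_incidence(self):
        assert weekly_ae_probability(0.0, 16.7) == 0.0

    def test_published_worked_example(self):
        # AST elevation 13.9% over a 16.7-month mean duration
        p = weekly_ae_probability(0.139, 16.7)
        r = 0.139 / (16.7 * 52 / 12)
        assert r == pytest.approx(0.0019208, abs=1e-6)
        assert p == pytest.approx(0.0019189, abs=1e-6)

    def test_probability_below_rate_and_converges(self):
        for inc in (0.01, 0.1, 0.5, 0.99):
            r = inc / (10 * 52 / 12)
            assert weekly_ae_probability(inc, 10) < r
        tiny = weekly_ae_probability(1e-8, 12)
        assert tiny == pytest.approx(1e-8 / (12 * 52 / 12), rel=1e-6)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            weekly_ae_probability(1.2, 10)
        with pytest.raises(ValueError):
            weekly_ae_probability(0.1, 0.0)


class TestBmTrace:
    def test_constant_baseline_without_incidence(self):
        settings = ModelSettings(horizon_years=2.0)
        flat = SurvivalCurve(np.ones(105))
        prev = build_bm_trace(settings, 0.25, flat, None, 78)
        np.testing.assert_allclose(prev, 0.25)

    def test_constant_weekly_hazard_closed_form(self):
        settings = ModelSettings(horizon_years=2.0)
        h = 0.01
        grid = np.arange(105)
        trial = SurvivalCurve((1 - h) ** grid)
        tail = exponential_fit(-np.log(1 - h))
        prev = build_bm_trace(settings, 0.0, trial, tail, 104)
        np.testing.assert_allclose(prev, 1 - (1 - h) ** np.arange(105), rtol=1e-10)

    def test_absorbing_non_decreasing(self):
        settings = ModelSettings()
        rng = np.random.default_rng(0)
        surv = np.concatenate([[1.0], np.sort(rng.random(80))[::-1]])
        prev = build_bm_trace(settings, 0.1, SurvivalCurve(surv), exponential_fit(0.002), 78)
        assert np.all(np.diff(prev) >= -1e-12)
        assert prev.size == settings.n_weeks + 1

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            build_bm_trace(ModelSettings(), 1.5, SurvivalCurve(np.ones(80)), None, 78)


class TestLineSplit:
    def test_layers_sum_to_pps(self):
        settings = ModelSettings()
        pfs = SurvivalCurve(np.exp(-0.03 * np.arange(521)))
        os_ = SurvivalCurve(np.exp(-0.008 * np.arange(521)))
        trace = compute_occupancy(pfs, os_, settings)
        second, third = line_split(trace, 50.1)
        np.testing.assert_allclose(second + third, trace.pps, atol=1e-12)
        assert np.all(second >= -1e-12) and np.all(third >= -1e-12)

    def test_no_progression_no_layers(self):
        settings = ModelSettings(horizon_years=1.0)
        s = SurvivalCurve(np.ones(53))
        trace = compute_occupancy(s, s, settings)
        second, third = line_split(trace, 50.1)
        assert np.allclose(second, 0) and np.allclose(third, 0)

    def test_everything_recent_is_second_line(self):
        # all progression in week 0, window longer than the horizon
        settings = ModelSettings(horizon_years=1.0)
        surv = np.ones(53)
        surv[1:] = 0.4
        pfs = SurvivalCurve(surv)
        os_ = SurvivalCurve(np.ones(53))
        trace = compute_occupancy(pfs, os_, settings)
        second, third = line_split(trace, 100.0)
        np.testing.assert_allclose(second, trace.pps, atol=1e-12)

    def test_window_expiry_moves_mass_to_third_line(self):
        settings = ModelSettings(horizon_years=1.0)
        surv = np.ones(53)
        surv[1:] = 0.4
        pfs = SurvivalCurve(surv)
        os_ = SurvivalCurve(np.ones(53))
        trace = compute_occupancy(pfs, os_, settings)
        second, third = line_split(trace, 10.0)
        # beyond week 11 every progressor has exhausted the 10-week window
        assert np.allclose(second[12:], 0.0)
        np.testing.assert_allclose(third[12:], trace.pps[12:], atol=1e-12)


class TestAccumulateCosts:
    def make_world(self, n_years=1.0, pfs_level=1.0, **cost_overrides):
        settings = ModelSettings(
            horizon_years=n_years, discount_rate_annual=0.0, half_cycle_correction=False
        )
        n = settings.n_weeks
        surv = np.ones(n + 1)
        surv[1:] = pfs_level
        pfs = SurvivalCurve(surv)
        os_ = SurvivalCurve(np.ones(n + 1))
        trace = compute_occupancy(pfs, os_, settings)
        inputs = simple_cost_inputs(**cost_overrides)
        events = EventModel(
            weekly_ae_probs={}, reweighting=1.0, bm_prevalence=np.zeros(n + 1)
        )
        duration = SurvivalCurve(np.ones(n + 1))
        return settings, trace, duration, inputs, events

    def test_acquisition_only_one_year_is_twelve_monthly_costs(self):
        settings, trace, duration, inputs, events = self.make_world()
        costs = accumulate_costs(trace, duration, "a", inputs, DRUGS, events, settings)
        assert costs.treatment_acquisition == pytest.approx(12 * 1000.0, rel=1e-12)
        assert costs.total == pytest.approx(12 * 1000.0, rel=1e-12)

    def test_dead_cohort_incurs_no_costs(self):
        settings = ModelSettings(horizon_years=1.0)
        n = settings.n_weeks
        dead = np.ones(n + 1)
        dead[0] = 0.0
        trace = OccupancyTrace(pfs=1 - dead, pps=np.zeros(n + 1), dead=dead)
        inputs = simple_cost_inputs(
            monitoring_first_line={"a": 23.76},
            management_weekly_pfs=25.0,
            management_weekly_pps=50.0,
        )
        events = EventModel(weekly_ae_probs={}, reweighting=1.0, bm_prevalence=np.zeros(n + 1))
        duration = SurvivalCurve(np.ones(n + 1))
        costs = accumulate_costs(trace, duration, "a", inputs, DRUGS, events, settings)
        # only the first half-cycle (cohort alive at entry) leaves a trace
        assert costs.total < 600.0

    def test_total_equals_category_sum_exactly(self, model, base_case):
        for arm_result in (base_case.intervention, base_case.comparator):
            c = arm_result.costs
            assert c.total == (
                c.treatment_acquisition
                + c.administration_monitoring
                + c.ae_management
                + c.management_pfs
                + c.management_pps
                + c.brain_metastases
            )

    def test_doubling_unit_costs_doubles_total(self):
        settings, trace, duration, inputs, events = self.make_world(
            monitoring_first_line={"a": 10.0}, management_weekly_pfs=5.0, bm_weekly=3.0
        )
        events.bm_prevalence = np.full(settings.n_weeks + 1, 0.25)
        drugs2 = {"drug1": DrugSpec(kind="oral", monthly_cost=2000.0)}
        inputs2 = simple_cost_inputs(
            monitoring_first_line={"a": 20.0}, management_weekly_pfs=10.0, bm_weekly=6.0
        )
        c1 = accumulate_costs(trace, duration, "a", inputs, DRUGS, events, settings)
        c2 = accumulate_costs(trace, duration, "a", inputs2, drugs2, events, settings)
        assert c2.total == pytest.approx(2 * c1.total, rel=1e-12)

    def test_zero_bm_cost_zeroes_only_bm_category(self):
        settings, trace, duration, inputs, events = self.make_world(
            monitoring_first_line={"a": 10.0}, management_weekly_pfs=5.0, bm_weekly=3.0
        )
        events.bm_prevalence = np.full(settings.n_weeks + 1, 0.25)
        inputs0 = simple_cost_inputs(
            monitoring_first_line={"a": 10.0}, management_weekly_pfs=5.0, bm_weekly=0.0
        )
        c1 = accumulate_costs(trace, duration, "a", inputs, DRUGS, events, settings)
        c0 = accumulate_costs(trace, duration, "a", inputs0, DRUGS, events, settings)
        assert c1.brain_metastases > 0 and c0.brain_metastases == 0.0
        assert c0.treatment_acquisition == c1.treatment_acquisition
        assert c0.administration_monitoring == c1.administration_monitoring
        assert c0.management_pfs == c1.management_pfs

    def test_costs_monotone_in_discount_rate(self, model):
        totals = []
        for r in (0.0, 0.04, 0.08):
            res = model.evaluate({"settings.discount_rate_annual": r})
            totals.append(res.intervention.costs.total)
        assert totals[0] > totals[1] > totals[2]

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simple_cost_inputs(second_line_mix={"a": {"drug1": 0.5}})
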