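"""Discounting, cost schedules, QALY/cost accumulation and ICERs."""

import numpy as np
import pytest

import markovcea as m
from markovcea.economics import discount_factor, intervention_cost_schedule
from markovcea.markov import CohortTrace, N_STATES, run_cohort
from markovcea.scenarios import make_scenario


class TestDiscounting:
    def test_first_cycle_is_undiscounted_by_default(self):
        assert discount_factor(0.03, 1) == 1.0

    def test_second_cycle(self):
        assert discount_factor(0.03, 2) == pytest.approx(0.970874, abs=1e-6)

    def test_zero_rate_never_discounts(self):
        assert discount_factor(0.0, 17) == 1.0

    def test_alternative_convention_discounts_from_cycle_one(self):
        assert discount_factor(0.03, 1, first_cycle_undiscounted=False) == (
            pytest.approx(1 / 1.03)
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)
        with pytest.raises(ValueError):
            discount_factor(0.03, 0)


class TestInterventionCostSchedule:
    def test_pedometer_years_are_1_6_11_16(self, params):
        schedule = intervention_cost_schedule(params, 20)
        assert [t + 1 for t in np.where(schedule == 35.0)[0]] == [1, 6, 11, 16]
        assert np.all(schedule[schedule != 35.0] == 21.30)

    def test_five_year_horizon_buys_one_pedometer(self, params):
        schedule = intervention_cost_schedule(params, 5)
        assert schedule[0] == 35.0 and np.all(schedule[1:] == 21.30)

    def test_twice_yearly_scenario_doubles_the_yearly_cost(self, params):
        s2 = make_scenario("s2")
        schedule = intervention_cost_schedule(params, 20, s2)
        assert schedule[0] == 70.0 and schedule[1] == 42.60

    def test_twice_yearly_non_pedometer_rule(self, params):
        p = params.copy()
        p.options.twice_yearly_doubles = "non_pedometer"
        schedule = intervention_cost_schedule(p, 20, make_scenario("s2"))
        assert schedule[0] == pytest.approx(35.0 + 21.30)
        assert schedule[1] == pytest.approx(2 * 21.30)


class TestAccumulate:
    def test_static_cohort_closed_form_under_each_reward_convention(
        self, zero_rate_params
    ):
        # a cohort that never leaves the at-risk state earns u per reward
        # row, discounted at 1.5%
        u, r = 0.71, 0.015
        expected = {
            "end": u * sum((1 + r) ** -(t - 1) for t in (1, 2)),      # 1.40951
            "start": u * sum((1 + r) ** -(t - 1) for t in (1, 2)),
            "both": u * sum((1 + r) ** -t for t in (0, 1, 2)),
        }
        for convention, value in expected.items():
            p = zero_rate_params.copy()
            p.horizon = 2
            p.options.cycle_rewards = convention
            trace = run_cohort(p, "control", sex="men", start_age=40)
            out = m.accumulate(trace, p, "control")
            assert out.qalys == pytest.approx(value, abs=1e-9), convention
        assert expected["end"] == pytest.approx(1.40951, abs=1e-5)

    def test_everyone_dead_earns_and_costs_nothing(self, params):
        occ = np.zeros((4, N_STATES))
        occ[:, -1] = 1.0
        trace = CohortTrace(occ, "control", "men", 40, 3)
        out = m.accumulate(trace, params, "control")
        assert out.qalys == 0.0 and out.costs == 0.0 and out.life_years == 0.0

    def test_zero_rates_make_discounted_equal_undiscounted(self, params):
        p = params.copy()
        p.costs.discount_rate = 0.0
        p.utilities.discount_rate = 0.0
        trace = run_cohort(p, "intervention", sex="men", start_age=42)
        out = m.accumulate(trace, p, "intervention")
        assert out.qalys == pytest.approx(out.qalys_undiscounted)
        assert out.costs == pytest.approx(out.costs_undiscounted)
        assert out.life_years == pytest.approx(out.life_years_undiscounted)

    def test_discounted_never_exceeds_undiscounted(self, params):
        trace = run_cohort(params, "intervention", sex="women", start_age=43)
        out = m.accumulate(trace, params, "intervention")
        assert out.qalys <= out.qalys_undiscounted
        assert out.costs <= out.costs_undiscounted
        assert out.qalys <= out.life_years  # utilities are at most 1

    def test_qalys_monotone_in_state_utilities(self, params):
        trace = run_cohort(params, "control", sex="men", start_age=42)
        base = m.accumulate(trace, params, "control").qalys
        richer = params.copy()
        richer.utilities.utilities["diabetes"] = (0.70, 0.06)
        assert m.accumulate(trace, richer, "control").qalys > base

    def test_costs_monotone_in_state_costs(self, params):
        trace = run_cohort(params, "control", sex="men", start_age=42)
        base = m.accumulate(trace, params, "control").costs
        dearer = params.copy()
        dearer.costs.state_costs["diabetes"] = (5000.0, 331.0)
        assert m.accumulate(trace, dearer, "control").costs > base

    def test_zero_effect_and_zero_programme_cost_give_exact_zero_increments(
        self, params
    ):
        p = params.copy()
        p.effects.bmi_change = 0.0
        p.costs.pedometer = p.costs.staff = p.costs.admin = p.costs.manual = 0.0
        res = m.run_comparison(p, "base", sex="men", start_age=42)
        assert res.icer.delta_qaly == 0.0
        assert res.icer.delta_cost == 0.0
        assert res.icer.label == "indeterminate"

    def test_scenario3_adds_utility_only_to_intervention_at_risk(self, params):
        s3 = make_scenario("s3")
        res_base = m.run_comparison(params, "base", sex="men", start_age=42)
        res_s3 = m.run_comparison(params, s3, sex="men", start_age=42)
        assert res_s3.control.qalys == pytest.approx(res_base.control.qalys)
        assert res_s3.intervention.qalys > res_base.intervention.qalys
        assert res_s3.icer.delta_cost == pytest.approx(res_base.icer.delta_cost)


class TestICER:
    def test_ratio(self, params):
        trace = run_cohort(params, "control", sex="men", start_age=42)
        a = m.accumulate(trace, params, "control")
        b = m.accumulate(trace, params, "control")
        b.costs = a.costs + 100.0
        b.qalys = a.qalys + 0.01
        res = m.compute_icer(b, a)
        assert res.icer == pytest.approx(10_000.0)
        assert res.label == "icer"

    def test_identical_outcomes_are_indeterminate(self, params):
        trace = run_cohort(params, "control", sex="men", start_age=42)
        a = m.accumulate(trace, params, "control")
        res = m.compute_icer(a, a)
        assert res.icer is None and res.label == "indeterminate"

    @pytest.mark.parametrize(
        "dc, dq, label",
        [(-50.0, 0.01, "dominant"), (50.0, -0.01, "dominated"), (50.0, 0.01, "icer")],
    )
    def test_dominance_quadrants(self, params, dc, dq, label):
        trace = run_cohort(params, "control", sex="men", start_age=42)
        a = m.accumulate(trace, params, "control")
        b = m.accumulate(trace, params, "control")
        b.costs, b.qalys = a.costs + dc, a.qalys + dq
        assert m.compute_icer(b, a).label == label

    def test_mismatched_runs_are_rejected(self, params):
        t1 = run_cohort(params, "control", sex="men", start_age=42)
        t2 = run_cohort(params, "control", sex="men", start_age=50)
        with pytest.raises(ValueError, match="start_age"):
            m.compute_icer(m.accumulate(t2, params), m.accumulate(t1, params))

    def test_reported_icer_is_internally_consistent(self, params, calibrated_ages):
        for sex in ("men", "women"):
            res = m.run_comparison(params, "base", sex=sex,
                                   start_age=calibrated_ages[sex])
            assert res.icer.icer == pytest.approx(
                res.icer.delta_cost / res.icer.delta_qaly
            )
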