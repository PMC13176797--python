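"""Costs, utilities, discounting: schedules, ledgers, perspectives."""

import numpy as np
import pytest

from warfce import Strategy, run_cohort
from warfce.economics import (
    COST_CATEGORIES,
    SOCIETAL_ONLY,
    cost_ledger,
    discount_factor,
    qaly_per_cycle,
    state_utilities,
    strategy_visits,
    visits_in_cycle,
)
from warfce import engine


class TestVisitSchedules:
    @pytest.mark.parametrize("strategy, cycle, expected", [
        (Strategy.UC, 0, 6.5),    # 3/month x 2 months + 0.5/month x month 3
        (Strategy.UC, 1, 1.5),
        (Strategy.UC, 40, 1.5),
        (Strategy.AMS, 0, 8.5),   # 4 (weeks 1-2) + 3 (to month 2) + 1.5
        (Strategy.AMS, 1, 4.5),   # months 4-6 at 1.5/month
        (Strategy.AMS, 2, 2.5),   # 5 visits per 6 months
        (Strategy.AMS, 3, 2.5),
        (Strategy.PSM, 0, 8.5),   # training follows the AMS clinic pattern
        (Strategy.PSM, 1, 0.0),
        (Strategy.PSM, 80, 0.0),
    ])
    def test_visits_per_cycle(self, params, strategy, cycle, expected):
        assert strategy_visits(params, strategy, cycle) == \
            pytest.approx(expected)

    def test_schedule_windows_partition_the_horizon(self, params):
        for sched in params.schedules.values():
            total = sum(visits_in_cycle(sched, c) for c in range(120))
            monthly = sum(sched.visits_per_month(m) for m in range(1, 361))
            assert total == pytest.approx(monthly)


class TestManagementCosts:
    def test_uc_steady_state_payer(self, params, life_table):
        """1.5 visits x (36.68 visit + 8.91 INR lab) + 0.67/day warfarin."""
        trace = run_cohort(params, life_table, Strategy.UC)
        ledger = cost_ledger(trace, params)
        alive = trace.alive()[5]
        mgmt = (ledger.loc[5, "clinic"] + ledger.loc[5, "inr_lab"]
                + ledger.loc[5, "drug"]) / alive
        assert mgmt == pytest.approx(129.5225, abs=1e-10)

    def test_uc_transport_is_round_trip(self, params, life_table):
        trace = run_cohort(params, life_table, Strategy.UC)
        ledger = cost_ledger(trace, params)
        alive = trace.alive()[5]
        assert ledger.loc[5, "transport"] / alive == pytest.approx(
            1.5 * 2 * 8.7 * 0.18, abs=1e-10)

    def test_psm_steady_state_equipment(self, params, life_table):
        """Warfarin + 13 weekly strip/lancet pairs + device amortization."""
        trace = run_cohort(params, life_table, Strategy.PSM)
        ledger = cost_ledger(trace, params)
        alive = trace.alive()[5]
        per_head = (ledger.loc[5, "psm_equipment"]
                    + ledger.loc[5, "drug"]) / alive
        assert per_head == pytest.approx(
            0.67 * 91.25 + 13 * (5.6 + 0.11) + 595 / 20, abs=1e-10)
        assert ledger.loc[5, "clinic"] == 0.0
        assert ledger.loc[5, "inr_lab"] == 0.0
        assert ledger.loc[5, "transport"] == 0.0

    def test_psm_entry_cycle_has_training_and_clinic_testing(self, params,
                                                             life_table):
        trace = run_cohort(params, life_table, Strategy.PSM)
        ledger = cost_ledger(trace, params)
        # one-time outlays on top of the AMS-pattern visits
        assert ledger.loc[0, "psm_equipment"] == pytest.approx(
            124.44 + 9.99 + 595 / 20, abs=1e-10)
        assert ledger.loc[0, "clinic"] == pytest.approx(8.5 * 11.52)
        assert ledger.loc[0, "inr_lab"] == pytest.approx(8.5 * 8.91)


class TestEventAndMaintenanceCosts:
    def test_post_stroke_maintenance_and_caregiver(self, params):
        """A cohort fully resident in minor ischemic stroke accrues the
        quarterly maintenance plus 19 h/week of informal care."""
        occ = np.zeros((2, len(engine.STATES)))
        occ[0, engine.IS_MINOR] = 1.0
        occ[1, engine.IS_MINOR] = 1.0
        trace = engine.CohortTrace(
            occupancy=occ, events=np.zeros((1, engine.N_EVENTS)),
            strategy=Strategy.UC, start_age=70, cycle_length=0.25)
        ledger = cost_ledger(trace, params)
        assert ledger.loc[0, "maintenance"] == pytest.approx(8851)
        assert ledger.loc[0, "caregiver"] == pytest.approx(19 * 13 * 23.8)
        assert (ledger.loc[0, "maintenance"] + ledger.loc[0, "caregiver"]
                ) == pytest.approx(14729.6)

    def test_new_meh_flow_costs_printed_bleed_amount(self, params):
        occ = np.zeros((2, len(engine.STATES)))
        occ[:, engine.WELL] = 1.0
        events = np.zeros((1, engine.N_EVENTS))
        f = 0.003
        events[0, engine.EVENT_INDEX["meh_nonfatal"]] = f
        trace = engine.CohortTrace(occupancy=occ, events=events,
                                   strategy=Strategy.UC, start_age=70,
                                   cycle_length=0.25)
        ledger = cost_ledger(trace, params)
        assert ledger.loc[0, "event"] == pytest.approx(f * 13_682)

    def test_all_well_cohort_has_no_event_or_maintenance_cost(self, params):
        occ = np.zeros((2, len(engine.STATES)))
        occ[:, engine.WELL] = 1.0
        trace = engine.CohortTrace(
            occupancy=occ, events=np.zeros((1, engine.N_EVENTS)),
            strategy=Strategy.UC, start_age=70, cycle_length=0.25)
        ledger = cost_ledger(trace, params)
        assert ledger.loc[0, "event"] == 0.0
        assert ledger.loc[0, "maintenance"] == 0.0
        assert ledger.loc[0, "caregiver"] == 0.0

    def test_fatal_stroke_carries_no_acute_cost(self, params):
        occ = np.zeros((2, len(engine.STATES)))
        occ[:, engine.WELL] = 1.0
        events = np.zeros((1, engine.N_EVENTS))
        events[0, engine.EVENT_INDEX["first_is_fatal"]] = 0.01
        trace = engine.CohortTrace(occupancy=occ, events=events,
                                   strategy=Strategy.UC, start_age=70,
                                   cycle_length=0.25)
        assert cost_ledger(trace, params).loc[0, "event"] == 0.0


class TestQalys:
    def test_state_utility_values(self, params):
        u = state_utilities(params)
        assert u[engine.WELL] == pytest.approx(0.81)
        assert u[engine.IS_MINOR] == pytest.approx(0.81 - 0.29)
        assert u[engine.IS_MAJOR] == pytest.approx(0.81 - 0.45)
        assert u[engine.DEAD] == 0.0

    def test_clamped_at_zero_with_warning(self, params):
        p = params.with_overrides(utility_nvaf=0.30)
        with pytest.warns(UserWarning, match="clamped"):
            u = state_utilities(p)
        assert u[engine.IS_MAJOR] == 0.0

    @pytest.mark.parametrize("state, expected", [
        (engine.WELL, 0.81 * 0.25),
        (engine.IS_MAJOR, (0.81 - 0.45) * 0.25),
        (engine.DEAD, 0.0),
    ])
    def test_cycle_qaly_for_pure_occupancy(self, params, state, expected):
        occ = np.zeros((2, len(engine.STATES)))
        occ[:, state] = 1.0
        trace = engine.CohortTrace(
            occupancy=occ, events=np.zeros((1, engine.N_EVENTS)),
            strategy=Strategy.UC, start_age=70, cycle_length=0.25)
        assert qaly_per_cycle(trace, params)[0] == pytest.approx(expected)

    def test_transient_bleed_decrement_two_weeks(self, params):
        occ = np.zeros((2, len(engine.STATES)))
        occ[:, engine.WELL] = 1.0
        events = np.zeros((1, engine.N_EVENTS))
        events[0, engine.EVENT_INDEX["meh_nonfatal"]] = 1.0
        trace = engine.CohortTrace(occupancy=occ, events=events,
                                   strategy=Strategy.UC, start_age=70,
                                   cycle_length=0.25)
        got = qaly_per_cycle(trace, params)[0]
        assert got == pytest.approx(0.81 * 0.25 - 0.181 * (2 / 13) * 0.25)


class TestDiscounting:
    @pytest.mark.parametrize("cycle, rate, expected", [
        (0, 0.03, 1.0),
        (4, 0.03, 1 / 1.03),
        (7, 0.0, 1.0),
    ])
    def test_discount_factor(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestInvariants:
    def test_discounted_not_above_undiscounted(self, base_results):
        for res in base_results.values():
            assert res.life_years <= res.life_years_undiscounted + 1e-12
            assert res.qalys <= res.qalys_undiscounted + 1e-12

    def test_payer_not_above_societal(self, base_results):
        for res in base_results.values():
            assert res.cost_payer <= res.cost_societal

    def test_societal_minus_payer_is_transport_plus_caregiver(
            self, base_results):
        for res in base_results.values():
            gap = res.cost_societal - res.cost_payer
            assert gap == pytest.approx(
                sum(res.cost_by_category[c] for c in SOCIETAL_ONLY))

    def test_qalys_bounded_by_life_years_times_baseline_utility(
            self, base_results):
        for res in base_results.values():
            assert res.qalys <= res.life_years * 0.81 + 1e-12

    def test_zero_unit_costs_give_zero_total(self, params, life_table):
        zeros = {name: 0.0 for name, p in params.items()
                 if p.group == "cost"}
        p0 = params.with_overrides(**zeros)
        trace = run_cohort(p0, life_table, Strategy.PSM)
        ledger = cost_ledger(trace, p0)
        assert ledger[list(COST_CATEGORIES)].to_numpy().sum() == 0.0
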