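"""Markov engine: elemental transforms, transition structure, cohort
traces."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from warfce import Strategy, run_cohort, events_per_10000
from warfce.demography import LifeTable
from warfce.engine import (
    DEAD,
    EVENTS,
    EVENT_INDEX,
    ICH_MINOR,
    IS_DISABLED,
    IS_MINOR,
    POST_STROKE_STATES,
    STATES,
    WELL,
    apply_relative_risk,
    build_event_dynamics,
    meh_event_flow,
    rate_to_cycle_prob,
    recurrence_transition,
    split_new_stroke,
)

SEV_IS = np.array([0.425, 0.366, 0.127, 0.082])
SEV_ICH = np.array([0.20, 0.15, 0.10, 0.53]) / 0.98


def flat_life_table(q=0.0):
    return LifeTable(np.arange(70, 101), np.full(31, float(q)))


class TestRateToCycleProb:
    @pytest.mark.parametrize("rate, expected", [
        (0.0, 0.0),
        (0.0115, 0.002870871145),   # annual stroke rate
        (0.0227, 0.005658927605),   # annual extracranial bleed rate
        (0.0272, 0.006776932316),   # annual recurrence rate
    ])
    def test_constant_hazard_conversion(self, rate, expected):
        assert rate_to_cycle_prob(rate, 0.25) == pytest.approx(expected,
                                                               abs=1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_cycle_prob(-0.1, 0.25)

    def test_agrees_with_poisson_thinning_simulation(self):
        """Stochastic oracle: fraction of unit-rate exponential event times
        falling inside the cycle."""
        rng = np.random.default_rng(17)
        times = rng.exponential(1 / 0.0115, size=2_000_000)
        frac = (times < 0.25).mean()
        expected = rate_to_cycle_prob(0.0115, 0.25)
        se = math.sqrt(expected * (1 - expected) / 2_000_000)
        assert abs(frac - expected) < 4 * se

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_rate(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert rate_to_cycle_prob(lo, 0.25) <= rate_to_cycle_prob(hi, 0.25)


class TestRelativeRisk:
    def test_identity_for_reference_strategy(self):
        assert apply_relative_risk(0.0115, 1.0) == 0.0115

    def test_hazard_scale_before_conversion(self):
        rate = apply_relative_risk(0.0115, 0.5)
        assert rate == pytest.approx(0.00575)
        assert rate_to_cycle_prob(rate, 0.25) == pytest.approx(
            0.001436467292, abs=1e-10)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            apply_relative_risk(0.0115, 0.0)


class TestSplitNewStroke:
    def test_zero_probability_gives_zero_masses(self):
        out = split_new_stroke(0.0, 0.8, SEV_IS, SEV_ICH)
        assert all(v == 0.0 for v in out.values())

    def test_example_masses(self):
        p = 0.0028708711
        out = split_new_stroke(p, 0.8, SEV_IS, SEV_ICH)
        assert out["first_is_minor"] == pytest.approx(p * 0.8 * 0.425)
        assert out["first_is_minor"] == pytest.approx(9.761e-4, rel=1e-3)
        assert out["first_is_fatal"] == pytest.approx(1.883e-4, rel=1e-3)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_total_mass_conserved(self, p, split):
        out = split_new_stroke(p, split, SEV_IS, SEV_ICH)
        assert sum(out.values()) == pytest.approx(p, abs=1e-15)

    def test_unnormalized_severity_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            split_new_stroke(0.01, 0.8, SEV_IS,
                             np.array([0.2, 0.15, 0.1, 0.53]))


class TestRecurrence:
    def test_zero_rate_leaves_no_recurrence_mass(self):
        dest = recurrence_transition(IS_MINOR, 0.0, SEV_IS, SEV_ICH, 0.25)
        assert sum(dest.values()) == 0.0

    def test_most_severe_state_progresses_only_to_itself_or_death(self):
        dest = recurrence_transition(IS_DISABLED, 0.0272, SEV_IS, SEV_ICH,
                                     0.25)
        p_rec = rate_to_cycle_prob(0.0272, 0.25)
        assert set(dest) == {IS_DISABLED, DEAD}
        assert dest[DEAD] == pytest.approx(p_rec * 0.082)
        assert p_rec == pytest.approx(0.0067772, abs=1e-6)

    @pytest.mark.parametrize("state", POST_STROKE_STATES)
    def test_never_assigns_mass_to_less_severe_states(self, state):
        dest = recurrence_transition(state, 0.0272, SEV_IS, SEV_ICH, 0.25)
        for d in dest:
            assert d == DEAD or d >= state

    def test_fatal_share_retained_after_truncation(self):
        for state, sev in ((IS_MINOR, SEV_IS), (ICH_MINOR, SEV_ICH)):
            dest = recurrence_transition(state, 0.0272, SEV_IS, SEV_ICH, 0.25)
            p_rec = rate_to_cycle_prob(0.0272, 0.25)
            assert dest[DEAD] == pytest.approx(p_rec * sev[3])

    def test_stay_in_place_rule(self):
        dest = recurrence_transition(IS_MINOR, 0.0272, SEV_IS, SEV_ICH, 0.25,
                                     progression_rule="stay-in-place")
        assert set(dest) == {IS_MINOR, DEAD}

    def test_well_state_rejected(self):
        with pytest.raises(ValueError):
            recurrence_transition(WELL, 0.0272, SEV_IS, SEV_ICH, 0.25)


class TestMehFlow:
    def test_split_example(self):
        nonfatal, fatal = meh_event_flow(0.0056589276, 0.0147)
        assert fatal == pytest.approx(8.319e-5, rel=1e-3)
        assert nonfatal == pytest.approx(5.576e-3, rel=1e-3)

    @pytest.mark.parametrize("p, ff, expected", [
        (0.0, 0.5, (0.0, 0.0)),
        (0.01, 1.0, (0.0, 0.01)),
        (0.01, 0.0, (0.01, 0.0)),
    ])
    def test_limits(self, p, ff, expected):
        assert meh_event_flow(p, ff) == pytest.approx(expected)


class TestCohortTrace:
    def test_transition_rows_stochastic(self, params):
        for strat in Strategy:
            P, F = build_event_dynamics(params, strat)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((P >= 0) & (P <= 1))
            # event flows are consistent with off-diagonal + transient mass
            assert np.all(F.sum(axis=1) <= 1.0 + 1e-12)

    def test_no_events_no_mortality_stays_well(self, params):
        p0 = params.with_overrides(rate_stroke=0.0, rate_meh=0.0,
                                   rate_recurrent_stroke=0.0)
        trace = run_cohort(p0, flat_life_table(0.0), Strategy.UC)
        assert np.all(trace.occupancy[:, WELL] == 1.0)
        assert np.all(trace.events == 0.0)

    def test_certain_mortality_absorbs_after_first_cycle(self, params):
        trace = run_cohort(params, flat_life_table(1.0), Strategy.UC)
        assert trace.occupancy[0, WELL] == 1.0
        assert trace.occupancy[1, DEAD] == pytest.approx(1.0, abs=1e-15)
        assert np.all(trace.occupancy[1:, DEAD] == trace.occupancy[1, DEAD])

    def test_conservation_and_monotone_death(self, base_traces):
        for trace in base_traces.values():
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                       atol=1e-10)
            assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-12)

    def test_zero_stroke_rr_accrues_no_stroke_events(self, params,
                                                     life_table):
        cfg = params.to_config()
        cfg["parameters"]["rr_stroke_psm"].update(
            {"base": 0.0, "low": None, "high": None, "distribution": "fixed"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            from warfce.parameters import load_parameters
            p0 = load_parameters(cfg)
        counts = events_per_10000(run_cohort(p0, life_table, Strategy.PSM))
        assert counts["stroke_total"] == 0.0
        assert counts["meh_total"] > 0.0

    def test_first_stroke_ratio_uc_vs_psm(self, base_traces):
        """Halving the stroke hazard roughly halves lifetime first strokes
        (slightly less because of longer survival under self-management)."""
        uc = events_per_10000(base_traces[Strategy.UC])["first_stroke"]
        psm = events_per_10000(base_traces[Strategy.PSM])["first_stroke"]
        assert 1.7 < uc / psm < 2.2

    def test_lower_stroke_rr_never_hurts(self, params, life_table):
        prev_strokes, prev_ly = np.inf, -np.inf
        for rr in (1.0, 0.7, 0.4, 0.1):
            p = params.with_overrides(rr_stroke_uc=rr)
            trace = run_cohort(p, life_table, Strategy.UC)
            strokes = events_per_10000(trace)["stroke_total"]
            ly = trace.alive()[:-1].sum() * 0.25
            assert strokes <= prev_strokes + 1e-9
            assert ly >= prev_ly - 1e-9
            prev_strokes, prev_ly = strokes, ly

    def test_event_tallies_populated_every_cycle(self, base_traces):
        trace = base_traces[Strategy.UC]
        assert trace.events.shape == (120, len(EVENTS))
        assert np.all(trace.events[:, EVENT_INDEX["meh_nonfatal"]] > 0)

    @given(rate_stroke=st.floats(0.0, 0.5), rate_meh=st.floats(0.0, 0.5),
           split=st.floats(0.0, 1.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_random_inputs_keep_rows_stochastic(self, params, rate_stroke,
                                                rate_meh, split):
        p = params.with_overrides(rate_stroke=rate_stroke, rate_meh=rate_meh,
                                  subtype_split_ischemic=split)
        P, _ = build_event_dynamics(p, Strategy.UC)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= -1e-15)


class TestEventsPer10000:
    def test_zero_rates_give_all_zero_counts(self, params, life_table):
        p0 = params.with_overrides(rate_stroke=0.0, rate_meh=0.0,
                                   rate_recurrent_stroke=0.0)
        counts = events_per_10000(run_cohort(p0, life_table, Strategy.UC))
        assert (counts == 0).all()

    def test_subtype_totals_partition_strokes(self, base_traces):
        counts = events_per_10000(base_traces[Strategy.UC])
        assert counts["stroke_total"] == pytest.approx(
            counts["is_total"] + counts["ich_total"])
        assert counts["stroke_total"] == pytest.approx(
            counts["first_stroke"] + counts["recurrent_stroke"])
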