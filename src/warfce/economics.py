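"""Costs, utilities, and discounting.

Per-cycle cost accounting by category and perspective, quality-adjusted
life accrual, and the discount machinery.  All amounts are 2024 USD.

Cost categories
---------------
``drug``           warfarin acquisition, 0.67 USD/day x 91.25 days/cycle.
``inr_lab``        laboratory INR tests billed per clinic visit (UC, AMS,
                   and the PSM training cycle; home testing uses strips
                   instead).
``clinic``         visit fees at the strategy's unit cost and schedule.
``psm_equipment``  training session, lancing device (one-time), INR meter
                   amortized straight-line over its 5-year lifespan and
                   recurring while alive, plus weekly strips and lancets.
``event``          acute management of each new clinical event; stroke
                   severity tiers carry their printed costs (no cost is
                   attached to immediately fatal strokes, which have no
                   printed tier), non-fatal and fatal extracranial bleeds
                   both carry the single printed bleed cost.
``maintenance``    quarterly post-stroke care by state of residence.
``transport``      round trips to the clinic at the IRS mileage rate
                   (societal perspective only).
``caregiver``      informal-care hours per week by stroke severity, valued
                   at the national hourly wage (societal only).

The payer perspective excludes ``transport`` and ``caregiver``; the
modified societal perspective includes everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .engine import CohortTrace, Strategy
from .parameters import ParameterSet, VisitScheduleSpec

__all__ = [
    "COST_CATEGORIES",
    "SOCIETAL_ONLY",
    "discount_factor",
    "visits_in_cycle",
    "strategy_visits",
    "cost_ledger",
    "qaly_per_cycle",
    "state_utilities",
]

COST_CATEGORIES = ("drug", "inr_lab", "clinic", "psm_equipment", "event",
                   "maintenance", "transport", "caregiver")
SOCIETAL_ONLY = ("transport", "caregiver")

_WEEKS_PER_CYCLE = 13.0
_DAYS_PER_CYCLE = 91.25


def discount_factor(cycle_index, annual_rate: float):
    """(1 + r)^(-t/4): discrete annual compounding with fractional-cycle
    exponents.  Accepts scalars or arrays of cycle indices."""
    if annual_rate < 0:
        raise ValueError("discount rate must be nonnegative")
    t = np.asarray(cycle_index, dtype=float)
    out = (1.0 + annual_rate) ** (-t * 0.25)
    return float(out) if np.isscalar(cycle_index) else out


def visits_in_cycle(schedule: VisitScheduleSpec, cycle_index: int) -> float:
    """Clinic visits in one 3-month cycle: the sum of the month-level
    intensities over the cycle's three calendar months."""
    if cycle_index < 0:
        raise ValueError("cycle index must be nonnegative")
    months = range(3 * cycle_index + 1, 3 * cycle_index + 4)
    return float(sum(schedule.visits_per_month(m) for m in months))


def strategy_visits(params: ParameterSet, strategy: Strategy,
                    cycle_index: int) -> float:
    """Clinic visits for a strategy at a given cycle.  Self-managing
    patients follow the AMS clinic pattern during their training window
    and make no clinic visits afterwards."""
    strategy = Strategy(strategy)
    if strategy is Strategy.PSM:
        if cycle_index < params.psm_training_cycles:
            return visits_in_cycle(params.schedules["AMS"], cycle_index)
        return 0.0
    return visits_in_cycle(params.schedules[strategy.value], cycle_index)


def state_utilities(params: ParameterSet) -> np.ndarray:
    """Utility of each health state (DEAD contributes 0); post-stroke
    states take the baseline NVAF utility minus the permanent severity
    decrement, clamped at 0 with a warning if a sampled decrement exceeds
    the baseline."""
    u0 = params.value("utility_nvaf")
    dec = (params.value("disutility_neuro_minor"),
           params.value("disutility_neuro_major"),
           params.value("disutility_neuro_disabled"))
    u = np.zeros(engine.N_STATES)
    u[engine.WELL] = u0
    for state in engine.POST_STROKE_STATES:
        val = u0 - dec[engine.SEVERITY_OF_STATE[state]]
        if val < 0:
            warnings.warn(
                f"state utility for {engine.STATES[state]} computed as "
                f"{val:.3f}; clamped at 0", UserWarning, stacklevel=2)
            val = 0.0
        u[state] = val
    return u


def qaly_per_cycle(trace: CohortTrace, params: ParameterSet) -> np.ndarray:
    """Undiscounted QALYs accrued in each cycle.

    Occupancy at the start of the cycle earns its state utility for the
    cycle's 0.25 years; each non-fatal extracranial bleed subtracts the
    transient decrement for 2 of the cycle's 13 weeks.
    """
    u = state_utilities(params)
    dt = params.value("cycle_length_years")
    occ = trace.occupancy[:-1]
    qaly = (occ @ u) * dt
    bleed_weeks = params.value("meh_disutility_weeks")
    bleed = (params.value("disutility_meh")
             * (bleed_weeks / _WEEKS_PER_CYCLE) * dt
             * trace.events[:, engine.EVENT_INDEX["meh_nonfatal"]])
    return qaly - bleed


def _event_unit_costs(params: ParameterSet) -> np.ndarray:
    """Acute cost attached to each event-flow column."""
    c = np.zeros(engine.N_EVENTS)
    tiers = ("minor", "major", "disabled")
    for sub in ("is", "ich"):
        for tier in tiers:
            cost = params.value(f"cost_event_{sub}_{tier}")
            c[engine.EVENT_INDEX[f"first_{sub}_{tier}"]] = cost
            c[engine.EVENT_INDEX[f"recur_{sub}_{tier}"]] = cost
    c[engine.EVENT_INDEX["meh_nonfatal"]] = params.value("cost_event_meh")
    c[engine.EVENT_INDEX["meh_fatal"]] = params.value("cost_event_meh")
    return c


def _maintenance_costs(params: ParameterSet) -> np.ndarray:
    m = np.zeros(engine.N_STATES)
    for sub in ("is", "ich"):
        for tier in ("minor", "major", "disabled"):
            state = getattr(engine, f"{sub.upper()}_{tier.upper()}")
            m[state] = params.value(f"cost_maint_{sub}_{tier}")
    return m


def _caregiver_costs(params: ParameterSet) -> np.ndarray:
    """Quarterly informal-care cost by state of residence (societal)."""
    wage = params.value("caregiver_wage")
    hours = (params.value("caregiver_hours_minor"),
             params.value("caregiver_hours_major"),
             params.value("caregiver_hours_disabled"))
    c = np.zeros(engine.N_STATES)
    for state in engine.POST_STROKE_STATES:
        c[state] = hours[engine.SEVERITY_OF_STATE[state]] * \
            _WEEKS_PER_CYCLE * wage
    return c


def cost_ledger(trace: CohortTrace, params: ParameterSet) -> pd.DataFrame:
    """Undiscounted per-cycle cohort costs by category (USD per entering
    patient).  Management costs accrue to the fraction alive at the start
    of each cycle; event costs follow the new-event flows; maintenance and
    caregiver costs follow post-stroke occupancy."""
    strategy = trace.strategy
    n = trace.n_cycles
    alive = trace.alive()[:-1]
    occ = trace.occupancy[:-1]

    ledger = {cat: np.zeros(n) for cat in COST_CATEGORIES}

    ledger["drug"] = params.value("cost_warfarin_day") * _DAYS_PER_CYCLE \
        * alive

    visit_cost = {Strategy.UC: params.value("cost_visit_uc"),
                  Strategy.AMS: params.value("cost_visit_ams"),
                  Strategy.PSM: params.value("cost_visit_ams")}[strategy]
    visits = np.array([strategy_visits(params, strategy, t)
                       for t in range(n)])
    ledger["clinic"] = visits * visit_cost * alive
    ledger["inr_lab"] = visits * params.value("cost_inr_lab") * alive
    ledger["transport"] = (visits * 2.0 * params.value("distance_miles")
                           * params.value("mileage_rate") * alive)

    if strategy is Strategy.PSM:
        amort_cycles = params.value("device_life_years") / \
            params.value("cycle_length_years")
        amort = params.value("cost_psm_device") / amort_cycles
        tests = params.value("psm_tests_per_week") * _WEEKS_PER_CYCLE
        consumables = tests * (params.value("cost_inr_strip")
                               + params.value("cost_lancet"))
        equip = np.full(n, amort)
        home = np.arange(n) >= params.psm_training_cycles
        equip[home] += consumables
        equip *= alive
        # one-time training-session and lancing-device outlay at entry
        equip[0] += (params.value("cost_psm_training")
                     + params.value("cost_psm_lancing_device")) * alive[0]
        ledger["psm_equipment"] = equip

    ledger["event"] = trace.events @ _event_unit_costs(params)
    ledger["maintenance"] = occ @ _maintenance_costs(params)
    ledger["caregiver"] = occ @ _caregiver_costs(params)

    df = pd.DataFrame(ledger)
    df.insert(0, "cycle", np.arange(n))
    return df
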