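"""Markov cohort engine.

Health-state space and per-cycle dynamics for a 70-year-old warfarin
cohort with non-valvular atrial fibrillation, tracked over 3-month cycles:

* ``WELL`` — anticoagulated, no prior neurological event;
* six post-stroke states: ischemic stroke (IS) or intracranial hemorrhage
  (ICH), each at severity minor / major / disabled;
* ``DEAD`` — absorbing.

Each cycle a WELL patient may suffer a first stroke (split into subtype
and severity; the fatal share goes straight to DEAD), a major extracranial
hemorrhage (MEH — transient: the non-fatal share returns to WELL within
the cycle, carrying a cost and a 2-week disutility through the event
flows), or die of background causes.  Post-stroke patients face only
recurrence (same-or-worse severity within their subtype, with the
subtype's fatal share) and background death.  Annual rates become cycle
probabilities through the constant-hazard transform 1 - exp(-r*t);
strategy relative risks act on the hazard before conversion.

Within a cycle, background death is applied first to every alive state
and clinical events are conditioned on surviving it; stroke and MEH
compete as independent constant hazards, with the combined event
probability 1 - exp(-(r_s + r_m)*t) allocated proportionally to the two
rates (the exact competing-risks solution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .demography import LifeTable, background_death_prob
from .parameters import ParameterSet

__all__ = [
    "Strategy",
    "STATES",
    "EVENTS",
    "CohortTrace",
    "rate_to_cycle_prob",
    "apply_relative_risk",
    "split_new_stroke",
    "recurrence_transition",
    "meh_event_flow",
    "build_event_dynamics",
    "run_cohort",
    "events_per_10000",
]


class Strategy(str, Enum):
    """Warfarin management strategy."""

    UC = "UC"    #: usual care by prescribing clinicians
    AMS = "AMS"  #: structured anticoagulation management service
    PSM = "PSM"  #: patient self-management with home INR testing


STATES = ("WELL", "IS_MINOR", "IS_MAJOR", "IS_DISABLED",
          "ICH_MINOR", "ICH_MAJOR", "ICH_DISABLED", "DEAD")
WELL, IS_MINOR, IS_MAJOR, IS_DISABLED, ICH_MINOR, ICH_MAJOR, ICH_DISABLED, \
    DEAD = range(8)
N_STATES = len(STATES)

#: severity tier of each post-stroke state (0 minor, 1 major, 2 disabled)
POST_STROKE_STATES = (IS_MINOR, IS_MAJOR, IS_DISABLED,
                      ICH_MINOR, ICH_MAJOR, ICH_DISABLED)
SEVERITY_OF_STATE = {IS_MINOR: 0, IS_MAJOR: 1, IS_DISABLED: 2,
                     ICH_MINOR: 0, ICH_MAJOR: 1, ICH_DISABLED: 2}
SUBTYPE_OF_STATE = {IS_MINOR: "IS", IS_MAJOR: "IS", IS_DISABLED: "IS",
                    ICH_MINOR: "ICH", ICH_MAJOR: "ICH", ICH_DISABLED: "ICH"}

EVENTS = (
    "first_is_minor", "first_is_major", "first_is_disabled", "first_is_fatal",
    "first_ich_minor", "first_ich_major", "first_ich_disabled",
    "first_ich_fatal",
    "recur_is_minor", "recur_is_major", "recur_is_disabled", "recur_is_fatal",
    "recur_ich_minor", "recur_ich_major", "recur_ich_disabled",
    "recur_ich_fatal",
    "meh_nonfatal", "meh_fatal",
)
N_EVENTS = len(EVENTS)
EVENT_INDEX = {name: i for i, name in enumerate(EVENTS)}


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def rate_to_cycle_prob(annual_rate: float, cycle_length: float) -> float:
    """Constant-hazard conversion of an annual event rate to a per-cycle
    probability: 1 - exp(-rate * cycle_length)."""
    if annual_rate < 0:
        raise ValueError(f"annual rate must be nonnegative, got {annual_rate}")
    if cycle_length <= 0:
        raise ValueError("cycle length must be positive")
    return -math.expm1(-annual_rate * cycle_length)


def apply_relative_risk(annual_rate: float, rr: float) -> float:
    """Apply a strategy relative risk on the hazard scale (before the
    rate-to-probability conversion, so probabilities stay valid for any
    positive relative risk)."""
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    return annual_rate * rr


def split_new_stroke(cycle_stroke_prob: float, subtype_split: float,
                     severity_is: np.ndarray, severity_ich: np.ndarray
                     ) -> dict[str, float]:
    """Distribute a first-stroke probability over subtype and severity.

    Returns per-destination mass keyed by event name (``first_is_minor``
    ... ``first_ich_fatal``); fatal tiers are destined for DEAD.  Total
    mass equals ``cycle_stroke_prob`` exactly.
    """
    severity_is = np.asarray(severity_is, dtype=float)
    severity_ich = np.asarray(severity_ich, dtype=float)
    for name, vec in (("ischemic", severity_is),
                      ("hemorrhagic", severity_ich)):
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{name} severity vector sums to {vec.sum():.12f}, not 1")
    if not 0.0 <= subtype_split <= 1.0:
        raise ValueError("subtype split must lie in [0, 1]")
    out: dict[str, float] = {}
    tiers = ("minor", "major", "disabled", "fatal")
    for k, tier in enumerate(tiers):
        out[f"first_is_{tier}"] = (
            cycle_stroke_prob * subtype_split * severity_is[k])
        out[f"first_ich_{tier}"] = (
            cycle_stroke_prob * (1.0 - subtype_split) * severity_ich[k])
    return out


def recurrence_transition(current_state: int, annual_recurrence_rate: float,
                          severity_is: np.ndarray, severity_ich: np.ndarray,
                          cycle_length: float,
                          progression_rule: str = "truncated-severity",
                          ) -> dict[int, float]:
    """Per-destination recurrence mass from a post-stroke state.

    ``truncated-severity`` (default): recurrent severity is drawn from the
    same subtype's severity distribution, truncated to same-or-worse than
    the current tier and renormalized so the non-fatal tiers carry
    ``1 - fatal`` of the recurrence mass; the subtype's fatal share is
    retained and routed to DEAD.  ``stay-in-place``: all non-fatal
    recurrence mass stays in the current state (fatal share unchanged).

    Destinations never include a less severe state; remaining (non-
    recurrence) mass is not represented here.
    """
    if current_state not in POST_STROKE_STATES:
        raise ValueError(f"state {current_state} is not a post-stroke state")
    p_rec = rate_to_cycle_prob(annual_recurrence_rate, cycle_length)
    subtype = SUBTYPE_OF_STATE[current_state]
    sev = np.asarray(severity_is if subtype == "IS" else severity_ich,
                     dtype=float)
    if abs(sev.sum() - 1.0) > 1e-9:
        raise ValueError("severity vector must sum to 1")
    tier = SEVERITY_OF_STATE[current_state]
    fatal = sev[3]
    dest: dict[int, float] = {DEAD: p_rec * fatal}
    base_state = IS_MINOR if subtype == "IS" else ICH_MINOR
    if progression_rule == "stay-in-place":
        dest[current_state] = dest.get(current_state, 0.0) + p_rec * (
            1.0 - fatal)
    elif progression_rule == "truncated-severity":
        weights = sev[tier:3]
        total = weights.sum()
        for j, w in zip(range(tier, 3), weights):
            dest_state = base_state + j
            if dest_state < current_state:  # defensive; cannot happen
                raise ValueError("recurrence rule assigned mass to a less "
                                 "severe state")
            dest[dest_state] = dest.get(dest_state, 0.0) + (
                p_rec * (1.0 - fatal) * w / total)
    else:
        raise ValueError(f"unknown progression rule {progression_rule!r}")
    return dest


def meh_event_flow(cycle_meh_prob: float, fatal_fraction: float
                   ) -> tuple[float, float]:
    """Split a major-extracranial-hemorrhage probability into (non-fatal,
    fatal) flows.  Non-fatal bleeds are transient within WELL — the mass
    returns to WELL the same cycle, with cost and a 2-week disutility
    recorded through the event flows; the fatal share moves to DEAD."""
    if not (0.0 <= cycle_meh_prob <= 1.0 and 0.0 <= fatal_fraction <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    fatal = cycle_meh_prob * fatal_fraction
    return cycle_meh_prob - fatal, fatal


# ---------------------------------------------------------------------------
# cycle dynamics
# ---------------------------------------------------------------------------

def build_event_dynamics(params: ParameterSet, strategy: Strategy,
                         progression_rule: str = "truncated-severity",
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Age-independent clinical-event dynamics for one strategy.

    Returns ``(P_event, F_event)`` where ``P_event`` is the row-stochastic
    state-transition matrix conditional on surviving background mortality
    for the cycle and ``F_event`` maps occupancy to per-capita new-event
    intensities (columns ordered as :data:`EVENTS`).
    """
    strategy = Strategy(strategy)
    dt = params.value("cycle_length_years")
    rr_stroke = params.value(f"rr_stroke_{strategy.value.lower()}")
    rr_meh = params.value(f"rr_meh_{strategy.value.lower()}")
    r_s = apply_relative_risk(params.value("rate_stroke"), rr_stroke) \
        if rr_stroke > 0 else 0.0
    r_m = apply_relative_risk(params.value("rate_meh"), rr_meh) \
        if rr_meh > 0 else 0.0

    sev_is = params.is_severity()
    sev_ich = params.ich_severity()
    split = params.value("subtype_split_ischemic")
    ff = params.value("meh_fatal_fraction")

    P = np.zeros((N_STATES, N_STATES))
    F = np.zeros((N_STATES, N_EVENTS))

    # WELL row: competing stroke/MEH hazards
    total = r_s + r_m
    p_any = rate_to_cycle_prob(total, dt)
    w_s = r_s / total if total > 0 else 0.0
    p_stroke = p_any * w_s
    p_meh = p_any * (1.0 - w_s)
    stroke_mass = split_new_stroke(p_stroke, split, sev_is, sev_ich)
    meh_nonfatal, meh_fatal = meh_event_flow(p_meh, ff)

    first_state = {"first_is_minor": IS_MINOR, "first_is_major": IS_MAJOR,
                   "first_is_disabled": IS_DISABLED,
                   "first_ich_minor": ICH_MINOR, "first_ich_major": ICH_MAJOR,
                   "first_ich_disabled": ICH_DISABLED,
                   "first_is_fatal": DEAD, "first_ich_fatal": DEAD}
    for ev, mass in stroke_mass.items():
        P[WELL, first_state[ev]] += mass
        F[WELL, EVENT_INDEX[ev]] += mass
    P[WELL, DEAD] += meh_fatal
    P[WELL, WELL] += (1.0 - p_any) + meh_nonfatal
    F[WELL, EVENT_INDEX["meh_nonfatal"]] = meh_nonfatal
    F[WELL, EVENT_INDEX["meh_fatal"]] = meh_fatal

    # post-stroke rows: recurrence only (treatment-independent)
    r_rec = params.value("rate_recurrent_stroke")
    for state in POST_STROKE_STATES:
        dest = recurrence_transition(state, r_rec, sev_is, sev_ich, dt,
                                     progression_rule)
        p_rec = sum(dest.values())
        P[state, state] += 1.0 - p_rec
        subtype = SUBTYPE_OF_STATE[state].lower()
        base_state = IS_MINOR if subtype == "is" else ICH_MINOR
        tiers = ("minor", "major", "disabled")
        for dest_state, mass in dest.items():
            P[state, dest_state] += mass
            if dest_state == DEAD:
                F[state, EVENT_INDEX[f"recur_{subtype}_fatal"]] += mass
            else:
                tier = tiers[dest_state - base_state]
                F[state, EVENT_INDEX[f"recur_{subtype}_{tier}"]] += mass

    P[DEAD, DEAD] = 1.0
    return P, F


@dataclass
class CohortTrace:
    """Cohort occupancy and event tallies over the model horizon.

    ``occupancy[t]`` is the state distribution at the *start* of cycle
    ``t`` (row 0 is 100% WELL; the final row is the end-of-horizon
    distribution); ``events[t]`` holds the cohort fractions experiencing
    each new clinical event during cycle ``t``.
    """

    occupancy: np.ndarray  # (n_cycles + 1, N_STATES)
    events: np.ndarray     # (n_cycles, N_EVENTS)
    strategy: Strategy
    start_age: float
    cycle_length: float

    @property
    def n_cycles(self) -> int:
        return self.events.shape[0]

    def alive(self) -> np.ndarray:
        """Fraction alive at the start of each cycle (length n_cycles+1)."""
        return 1.0 - self.occupancy[:, DEAD]

    def validate(self, occ_tol: float = 1e-10) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > occ_tol:
            raise AssertionError("cohort occupancy not conserved")
        dead = self.occupancy[:, DEAD]
        if np.any(np.diff(dead) < -occ_tol):
            raise AssertionError("DEAD occupancy not monotone")

    def occupancy_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATES)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def events_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=EVENTS)
        df.insert(0, "cycle", np.arange(self.events.shape[0]))
        return df


def cycle_death_probs(params: ParameterSet, lt: LifeTable,
                      n_cycles: int | None = None) -> np.ndarray:
    """Background per-cycle death probability for each model cycle."""
    n = params.n_cycles if n_cycles is None else n_cycles
    dt = params.value("cycle_length_years")
    start = params.value("start_age")
    mult = params.value("af_mortality_multiplier")
    return np.array([background_death_prob(lt, start + t * dt, mult, dt)
                     for t in range(n)])


def run_cohort(params: ParameterSet, lt: LifeTable,
               strategy: Strategy | str,
               progression_rule: str = "truncated-severity",
               n_cycles: int | None = None,
               validate: bool = True) -> CohortTrace:
    """Deterministic cohort trace for one strategy over the full horizon.

    The cohort enters 100% WELL.  Each cycle, background mortality (AF-
    adjusted, from the life table at the cohort's current age) is applied
    to every alive state; event dynamics conditioned on surviving it are
    given by :func:`build_event_dynamics`.
    """
    strategy = Strategy(strategy)
    P_event, F_event = build_event_dynamics(params, strategy,
                                            progression_rule)
    row_sums = P_event.sum(axis=1)
    if np.max(np.abs(row_sums - 1.0)) > 1e-12:
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise AssertionError(
            f"event transition row {STATES[bad]} sums to {row_sums[bad]!r}")
    p_bg = cycle_death_probs(params, lt, n_cycles)
    n = p_bg.size

    occ = np.zeros((n + 1, N_STATES))
    occ[0, WELL] = 1.0
    events = np.zeros((n, N_EVENTS))
    for t in range(n):
        survive = 1.0 - p_bg[t]
        cur = occ[t]
        alive = cur.copy()
        alive[DEAD] = 0.0
        nxt = survive * (alive @ P_event)
        nxt[DEAD] += cur[DEAD] + p_bg[t] * alive.sum()
        occ[t + 1] = nxt
        events[t] = survive * (alive @ F_event)

    trace = CohortTrace(occupancy=occ, events=events, strategy=strategy,
                        start_age=params.value("start_age"),
                        cycle_length=params.value("cycle_length_years"))
    if validate:
        try:
            trace.validate()
        except AssertionError as exc:
            raise AssertionError(
                f"{exc} (strategy {strategy.value})") from exc
    return trace


def events_per_10000(trace: CohortTrace) -> pd.Series:
    """Cumulative lifetime event counts per 10,000 patients.

    ``stroke_total`` counts every stroke event — first ischemic strokes,
    first intracranial hemorrhages, and recurrences, fatal included.
    """
    totals = pd.Series(trace.events.sum(axis=0) * 10_000.0, index=EVENTS)
    first_is = totals[[f"first_is_{t}"
                       for t in ("minor", "major", "disabled", "fatal")]].sum()
    first_ich = totals[[f"first_ich_{t}"
                        for t in ("minor", "major", "disabled",
                                  "fatal")]].sum()
    recur_is = totals[[f"recur_is_{t}"
                       for t in ("minor", "major", "disabled", "fatal")]].sum()
    recur_ich = totals[[f"recur_ich_{t}"
                        for t in ("minor", "major", "disabled",
                                  "fatal")]].sum()
    return pd.Series({
        "first_stroke": first_is + first_ich,
        "recurrent_stroke": recur_is + recur_ich,
        "stroke_total": first_is + first_ich + recur_is + recur_ich,
        "is_total": first_is + recur_is,
        "ich_total": first_ich + recur_ich,
        "meh_nonfatal": totals["meh_nonfatal"],
        "meh_fatal": totals["meh_fatal"],
        "meh_total": totals["meh_nonfatal"] + totals["meh_fatal"],
    })
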