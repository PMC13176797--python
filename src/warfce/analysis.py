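"""Strategy-level aggregation and incremental cost-effectiveness analysis.

Turns cohort traces into lifetime discounted/undiscounted life years,
QALYs and costs (by category and perspective), and compares strategies by
incremental cost per QALY (ICER), dominance labeling, and net monetary
benefit (NMB = WTP x QALY - cost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics
from .demography import LifeTable
from .engine import CohortTrace, Strategy, events_per_10000, run_cohort
from .parameters import ParameterSet

__all__ = [
    "StrategyResult",
    "summarize",
    "run_strategy",
    "base_case",
    "incremental_table",
    "nmb",
]


@dataclass
class StrategyResult:
    """Lifetime discounted outcomes for one strategy (per entering
    patient), plus undiscounted life years/QALYs and lifetime event counts
    per 10,000."""

    strategy: Strategy
    life_years: float
    life_years_undiscounted: float
    qalys: float
    qalys_undiscounted: float
    cost_by_category: dict[str, float]
    events_per_10000: pd.Series

    @property
    def cost_societal(self) -> float:
        return float(sum(self.cost_by_category.values()))

    @property
    def cost_payer(self) -> float:
        return float(sum(v for k, v in self.cost_by_category.items()
                         if k not in economics.SOCIETAL_ONLY))

    def cost(self, perspective: str = "societal") -> float:
        if perspective == "societal":
            return self.cost_societal
        if perspective == "payer":
            return self.cost_payer
        raise ValueError(f"unknown perspective {perspective!r}")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "life_years": self.life_years,
            "life_years_undiscounted": self.life_years_undiscounted,
            "qalys": self.qalys,
            "qalys_undiscounted": self.qalys_undiscounted,
            "cost_societal": self.cost_societal,
            "cost_payer": self.cost_payer,
            "cost_by_category": dict(self.cost_by_category),
            "events_per_10000": self.events_per_10000.to_dict(),
        }


def summarize(trace: CohortTrace, params: ParameterSet,
              half_cycle_correction: bool = False) -> StrategyResult:
    """Aggregate a cohort trace into a :class:`StrategyResult`.

    Accrual uses start-of-cycle occupancy with no half-cycle correction by
    default (the convention required to reproduce the base case); with the
    correction on, per-cycle occupancy is averaged with the following
    cycle's.
    """
    dt = params.value("cycle_length_years")
    n = trace.n_cycles
    rate = params.value("discount_rate")
    disc = economics.discount_factor(np.arange(n), rate)

    alive = trace.alive()
    occ_alive = alive[:-1]
    if half_cycle_correction:
        occ_alive = 0.5 * (alive[:-1] + alive[1:])
    ly_cycle = occ_alive * dt
    qaly_cycle = economics.qaly_per_cycle(trace, params)
    if half_cycle_correction:
        # shift state-occupancy QALYs to mid-cycle weighting as well
        u = economics.state_utilities(params)
        occ_mid = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
        qaly_cycle = qaly_cycle - (trace.occupancy[:-1] @ u) * dt \
            + (occ_mid @ u) * dt

    ledger = economics.cost_ledger(trace, params)
    cost_by_cat = {
        cat: float(ledger[cat].to_numpy() @ disc)
        for cat in economics.COST_CATEGORIES
    }

    return StrategyResult(
        strategy=trace.strategy,
        life_years=float(ly_cycle @ disc),
        life_years_undiscounted=float(ly_cycle.sum()),
        qalys=float(qaly_cycle @ disc),
        qalys_undiscounted=float(qaly_cycle.sum()),
        cost_by_category=cost_by_cat,
        events_per_10000=events_per_10000(trace),
    )


def run_strategy(params: ParameterSet, lt: LifeTable,
                 strategy: Strategy | str,
                 half_cycle_correction: bool = False) -> StrategyResult:
    """Run the cohort engine and summarize, in one step."""
    trace = run_cohort(params, lt, strategy)
    return summarize(trace, params, half_cycle_correction)


def base_case(params: ParameterSet, lt: LifeTable
              ) -> dict[Strategy, StrategyResult]:
    """Deterministic base-case results for all three strategies."""
    return {s: run_strategy(params, lt, s) for s in Strategy}


def nmb(qalys: float, cost: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    return wtp * qalys - cost


def incremental_table(results: dict[Strategy, StrategyResult],
                      reference: Strategy | str = Strategy.UC,
                      wtp: float = 100_000.0,
                      perspective: str = "societal") -> pd.DataFrame:
    """Incremental comparison of every strategy against a reference.

    Increments are computed from unrounded totals.  The ICER is reported
    only when its sign is meaningful; otherwise the row carries a
    dominance label: ``dominant`` (more effective, cheaper than the
    reference), ``dominated`` (less effective, costlier), ``equivalent``
    (identical totals).
    """
    reference = Strategy(reference)
    if reference not in results:
        raise KeyError(f"reference strategy {reference.value} missing")
    ref = results[reference]
    rows = []
    for strat, res in results.items():
        cost = res.cost(perspective)
        d_cost = cost - ref.cost(perspective)
        d_qaly = res.qalys - ref.qalys
        if strat == reference:
            icer, label = np.nan, "reference"
        elif d_qaly == 0.0 and d_cost == 0.0:
            icer, label = np.nan, "equivalent"
        elif d_qaly > 0 and d_cost < 0:
            icer, label = np.nan, "dominant"
        elif d_qaly < 0 and d_cost > 0:
            icer, label = np.nan, "dominated"
        elif d_qaly == 0.0:
            icer, label = np.nan, ("dominated" if d_cost > 0 else "dominant")
        else:
            icer, label = d_cost / d_qaly, ""
        rows.append({
            "strategy": strat.value,
            "qalys": res.qalys,
            "cost": cost,
            "incr_qalys": np.nan if strat == reference else d_qaly,
            "incr_cost": np.nan if strat == reference else d_cost,
            "icer": icer,
            "label": label,
            "nmb": nmb(res.qalys, cost, wtp),
        })
    return pd.DataFrame(rows).set_index("strategy")
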