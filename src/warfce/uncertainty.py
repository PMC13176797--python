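"""Sensitivity analysis: one-way (tornado) and probabilistic (PSA).

One-way sensitivity analysis re-runs the deterministic model with a single
parameter at its range limits, all else at base, and records the swing in
the net monetary benefit of patient self-management.  The probabilistic
analysis draws every non-fixed parameter from its derived distribution
(independently, one named random substream per parameter per draw), runs
all strategies per draw, and summarizes the joint cost/QALY uncertainty as
cost-effectiveness-plane quadrant shares and cost-effectiveness
acceptability curves (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import nmb, run_strategy
from .demography import LifeTable
from .engine import Strategy
from .parameters import ParameterSet, sample_parameter_set

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "owsa",
    "tornado",
    "psa",
    "ce_plane_quadrants",
    "ceac",
]


@dataclass
class TornadoEntry:
    """NMB of self-management with one parameter at its low/high limit."""

    parameter: str
    low: float
    high: float
    nmb_at_low: float
    nmb_at_high: float
    nmb_base: float

    @property
    def swing(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)

    @property
    def base_outside(self) -> bool:
        """True when the base-case NMB falls outside the [low, high] NMB
        interval (a non-monotone response or an inconsistent input range);
        flagged rather than assumed impossible."""
        lo, hi = sorted((self.nmb_at_low, self.nmb_at_high))
        return not lo - 1e-9 <= self.nmb_base <= hi + 1e-9


def _psm_nmb(params: ParameterSet, lt: LifeTable, wtp: float,
             perspective: str, incremental_vs_uc: bool) -> float:
    """NMB of the self-management strategy; absolute by default, or
    incremental versus usual care with the flag set."""
    res = run_strategy(params, lt, Strategy.PSM)
    value = nmb(res.qalys, res.cost(perspective), wtp)
    if incremental_vs_uc:
        ref = run_strategy(params, lt, Strategy.UC)
        value -= nmb(ref.qalys, ref.cost(perspective), wtp)
    return value


def owsa(params: ParameterSet, lt: LifeTable, parameter: str,
         wtp: float = 100_000.0, perspective: str = "societal",
         incremental_vs_uc: bool = False) -> TornadoEntry:
    """One-way sensitivity of the self-management NMB to one parameter.

    Two full deterministic runs, the parameter at its low and at its high
    limit with everything else at base.
    """
    p = params[parameter]
    if not p.has_range:
        raise ValueError(f"{parameter} has no finite (low, high) range")
    try:
        nmb_base = _psm_nmb(params, lt, wtp, perspective, incremental_vs_uc)
        nmb_low = _psm_nmb(params.with_overrides(**{parameter: p.low}),
                           lt, wtp, perspective, incremental_vs_uc)
        nmb_high = _psm_nmb(params.with_overrides(**{parameter: p.high}),
                            lt, wtp, perspective, incremental_vs_uc)
    except Exception as exc:
        raise RuntimeError(
            f"one-way sensitivity run failed for {parameter!r}") from exc
    return TornadoEntry(parameter=parameter, low=p.low, high=p.high,
                        nmb_at_low=nmb_low, nmb_at_high=nmb_high,
                        nmb_base=nmb_base)


def tornado(params: ParameterSet, lt: LifeTable, wtp: float = 100_000.0,
            perspective: str = "societal",
            parameters: list[str] | None = None,
            incremental_vs_uc: bool = False) -> pd.DataFrame:
    """Tornado table: one :func:`owsa` entry per ranged parameter, sorted
    by descending NMB swing."""
    if parameters is None:
        parameters = [name for name, p in params.items() if p.has_range]
    entries = [owsa(params, lt, name, wtp, perspective, incremental_vs_uc)
               for name in parameters]
    entries.sort(key=lambda e: e.swing, reverse=True)
    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low, "high": e.high,
        "nmb_at_low": e.nmb_at_low, "nmb_at_high": e.nmb_at_high,
        "nmb_base": e.nmb_base, "swing": e.swing,
        "base_outside": e.base_outside,
    } for e in entries])


@dataclass
class PSAResult:
    """Per-draw discounted (cost, QALY) pairs per strategy.

    ``draws`` has one row per (draw, strategy) with columns ``qalys``,
    ``cost_societal``, ``cost_payer``; fully reproducible from ``seed``.
    """

    draws: pd.DataFrame
    seed: int
    n_draws: int
    redraw_count: int = 0

    def pivot(self, column: str) -> pd.DataFrame:
        return self.draws.pivot(index="draw", columns="strategy",
                                values=column)

    def cost_column(self, perspective: str) -> str:
        if perspective not in ("societal", "payer"):
            raise ValueError(f"unknown perspective {perspective!r}")
        return f"cost_{perspective}"


def psa(params: ParameterSet, lt: LifeTable, n_draws: int, seed: int,
        strategies: tuple[Strategy, ...] = tuple(Strategy)) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Every non-fixed parameter is drawn independently from its derived
    hyperparameters (one substream per parameter per draw, so results for
    draw *i* never depend on how many draws are requested); each draw is a
    full deterministic model run per strategy.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rows = []
    total_redraws = 0
    for i in range(n_draws):
        sampled, redraws = sample_parameter_set(params, seed, i)
        total_redraws += redraws
        for strat in strategies:
            res = run_strategy(sampled, lt, strat)
            rows.append({"draw": i, "strategy": strat.value,
                         "qalys": res.qalys,
                         "cost_societal": res.cost_societal,
                         "cost_payer": res.cost_payer})
    return PSAResult(draws=pd.DataFrame(rows), seed=seed, n_draws=n_draws,
                     redraw_count=total_redraws)


def ce_plane_quadrants(result: PSAResult, strategy_a: Strategy | str,
                       strategy_b: Strategy | str,
                       perspective: str = "societal") -> pd.Series:
    """Cost-effectiveness-plane quadrant shares of strategy A versus B.

    Each draw's (dQALY, dcost) pair is classified into:
    ``dominant`` (A more effective, cheaper), ``ne`` (more effective,
    costlier), ``sw`` (less effective, cheaper), ``dominated`` (less
    effective, costlier).  Draws exactly on an axis split their mass
    equally between the adjacent quadrants; shares sum to 1.
    """
    a, b = Strategy(strategy_a).value, Strategy(strategy_b).value
    q = result.pivot("qalys")
    c = result.pivot(result.cost_column(perspective))
    dq = (q[a] - q[b]).to_numpy()
    dc = (c[a] - c[b]).to_numpy()
    n = dq.size
    shares = dict.fromkeys(("dominant", "ne", "sw", "dominated"), 0.0)
    # tie-aware membership weights per axis
    for dqi, dci in zip(dq, dc):
        wq = {"+": 1.0} if dqi > 0 else {"-": 1.0} if dqi < 0 \
            else {"+": 0.5, "-": 0.5}
        wc = {"+": 1.0} if dci > 0 else {"-": 1.0} if dci < 0 \
            else {"+": 0.5, "-": 0.5}
        quad = {("+", "-"): "dominant", ("+", "+"): "ne",
                ("-", "-"): "sw", ("-", "+"): "dominated"}
        for sq, wq_ in wq.items():
            for sc, wc_ in wc.items():
                shares[quad[(sq, sc)]] += wq_ * wc_ / n
    return pd.Series(shares)


def ceac(result: PSAResult, wtp_grid=None,
         perspective: str = "societal") -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay value, the share of draws in which each
    strategy attains the maximum net monetary benefit; exact ties split
    equally among the tied strategies, so the shares at every threshold
    sum to 1.
    """
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 200_000.0, 21)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("willingness-to-pay grid must be nonempty")
    q = result.pivot("qalys")
    c = result.pivot(result.cost_column(perspective))
    strategies = list(q.columns)
    qm = q.to_numpy()  # draws x strategies
    cm = c.to_numpy()
    rows = []
    for wtp in wtp_grid:
        nmb_m = wtp * qm - cm
        best = nmb_m.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb_m, best, rtol=0.0, atol=1e-9)
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        rows.append({"wtp": wtp,
                     **{s: probs[j] for j, s in enumerate(strategies)}})
    return pd.DataFrame(rows)
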