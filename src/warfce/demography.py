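"""Background mortality.

Age-specific all-cause death probabilities enter the model through a
:class:`LifeTable`; the cohort's atrial-fibrillation-related excess
mortality is applied as a multiplier on the hazard (rate) scale, never on
the probability scale, so the result is always a valid probability.

The packaged table ``data/life_table_us_synthetic.csv`` is a synthetic
Gompertz life table (hazard 0.021/year at age 70 rising by a log-slope of
0.095/year) chosen to approximate period US all-cause, all-sex mortality
at ages 70-100; it stands in for the unpublished national table the model
requires, so base-case results are reproduced at tolerance rather than
exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "load_life_table",
    "default_life_table",
    "background_death_prob",
    "synthetic_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    """Ordered (age, annual death probability) entries.

    Ages must be contiguous integers; every probability lies in [0, 1]
    (the final age may be 1 to close the table).  No extrapolation is
    performed: asking for an age outside the table is an error.
    """

    ages: np.ndarray
    q_annual: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if ages.ndim != 1 or ages.shape != q.shape or ages.size == 0:
            raise ValueError("ages and q_annual must be matching 1-d arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life-table ages must be contiguous integers")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def q(self, age: float) -> float:
        """Annual death probability at (the integer part of) ``age``."""
        a = int(math.floor(age))
        if a < self.age_min or a > self.age_max:
            raise ValueError(
                f"age {age} outside life table [{self.age_min}, "
                f"{self.age_max}]; no extrapolation is performed")
        return float(self.q_annual[a - self.age_min])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_annual": self.q_annual})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path: str | Path, provenance: str | None = None
                    ) -> LifeTable:
    """Read a two-column CSV (``age``, ``q_annual``; header required)."""
    df = pd.read_csv(path, comment="#")
    for col in ("age", "q_annual"):
        if col not in df.columns:
            raise ValueError(f"life-table CSV must have a {col!r} column")
    return LifeTable(df["age"].to_numpy(), df["q_annual"].to_numpy(),
                     provenance=provenance or str(path))


def default_life_table() -> LifeTable:
    """The packaged synthetic US-like life table, ages 70-100."""
    path = resources.files("warfce").joinpath(
        "data/life_table_us_synthetic.csv")
    lt = load_life_table(str(path))
    return LifeTable(lt.ages, lt.q_annual,
                     provenance="synthetic Gompertz approximation of period "
                                "US all-cause mortality, ages 70-100")


def background_death_prob(lt: LifeTable, age: float, af_multiplier: float,
                          cycle_length: float) -> float:
    """Per-cycle background death probability at ``age``.

    The annual probability q is converted to a rate r = -ln(1 - q), scaled
    by the atrial-fibrillation hazard multiplier, and converted back:
    1 - exp(-r * m * cycle_length).  A closed-out age (q = 1) yields a
    cycle probability of 1 regardless of the multiplier.
    """
    if af_multiplier <= 0:
        raise ValueError("af_multiplier must be positive")
    q = lt.q(age)
    if q >= 1.0:
        return 1.0
    rate = -math.log1p(-q)
    return -math.expm1(-rate * af_multiplier * cycle_length)


def synthetic_life_table(b: float, c: float, age_min: int, age_max: int
                         ) -> LifeTable:
    """Parametric Gompertz life table: q(age) = 1 - exp(-b * exp(c * age)).

    Deterministic in its inputs; probabilities that overflow are clamped
    at 1 with a warning.  Intended as a test fixture generator.
    """
    if b < 0 or c < 0:
        raise ValueError("Gompertz parameters must be nonnegative")
    ages = np.arange(int(age_min), int(age_max) + 1)
    with np.errstate(over="ignore"):
        hazard = b * np.exp(c * ages.astype(float))
        q = -np.expm1(-hazard)
    q = np.nan_to_num(q, nan=1.0)
    if np.any(q >= 1.0) and b > 0:
        warnings.warn("Gompertz hazard overflows; probabilities clamped at 1",
                      UserWarning, stacklevel=2)
    q = np.clip(q, 0.0, 1.0)
    return LifeTable(ages, q,
                     provenance=f"synthetic Gompertz(b={b}, c={c})")
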