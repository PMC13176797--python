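"""Model parameter registry.

Every input of the decision model — annual clinical event rates, relative
risks, severity splits, utilities, unit costs, visit schedules and
structural constants — is a named :class:`Parameter` carrying a base-case
value, a plausible range and a probabilistic-sensitivity-analysis sampling
distribution.  A :class:`ParameterSet` is the validated collection of all
of them, loaded from a YAML configuration (the packaged default encodes the
model's published input tables in 2024 USD).

Conventions
-----------
* Disutilities are stored as positive decrements from the baseline
  non-valvular-atrial-fibrillation utility.
* Ranges are read as 95% intervals, so the implied standard deviation is
  ``(high - low) / 3.92`` (log scale for log-normal parameters); a
  parameter may instead carry an explicit ``sd``.
* Parameters whose distribution is ``fixed`` are never sampled in the PSA
  but may still carry a range for one-way sensitivity analysis.
* Two rows of the source tables print a base value outside the printed
  range; they are carried verbatim and flagged ``range_inconsistent``
  rather than silently corrected.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "VisitScheduleSpec",
    "load_parameters",
    "default_config_path",
    "derive_hyperparameters",
    "sample_value",
    "sample_parameter_set",
]

DISTRIBUTIONS = ("gamma", "beta", "lognormal", "fixed")
GROUPS = ("event-rate", "relative-risk", "proportion", "utility", "cost",
          "structural")

#: sampling family each group is allowed to use (besides "fixed"),
#: mirroring the model's stated PSA groupings: gamma for event rates and
#: costs, beta for utilities (and the discount rate), log-normal for
#: multiplier parameters.
_FAMILY_FOR_GROUP = {
    "event-rate": {"gamma"},
    "relative-risk": {"lognormal"},
    "proportion": {"beta"},
    "utility": {"beta"},
    "cost": {"gamma"},
    "structural": {"beta"},
}

#: rows printed with a base value outside the printed range; flagged, not
#: rejected.
RANGE_INCONSISTENT_ALLOWLIST = frozenset({"rate_stroke", "disutility_meh"})

#: complete roster of required parameters; loading fails if any is absent
#: and unknown names are rejected.
REQUIRED_PARAMETERS = (
    "rate_stroke", "rate_meh", "rate_recurrent_stroke",
    "is_severity_minor", "is_severity_major", "is_severity_disabled",
    "is_severity_fatal",
    "ich_severity_minor", "ich_severity_major", "ich_severity_disabled",
    "ich_severity_fatal",
    "meh_fatal_fraction", "subtype_split_ischemic",
    "af_mortality_multiplier",
    "rr_stroke_uc", "rr_stroke_ams", "rr_stroke_psm",
    "rr_meh_uc", "rr_meh_ams", "rr_meh_psm",
    "utility_nvaf", "disutility_neuro_minor", "disutility_neuro_major",
    "disutility_neuro_disabled", "disutility_meh",
    "cost_warfarin_day", "cost_inr_lab", "cost_visit_ams", "cost_visit_uc",
    "cost_psm_training", "cost_psm_device", "cost_inr_strip", "cost_lancet",
    "cost_psm_lancing_device",
    "cost_event_is_minor", "cost_event_is_major", "cost_event_is_disabled",
    "cost_event_ich_minor", "cost_event_ich_major", "cost_event_ich_disabled",
    "cost_event_meh",
    "cost_maint_is_minor", "cost_maint_is_major", "cost_maint_is_disabled",
    "cost_maint_ich_minor", "cost_maint_ich_major", "cost_maint_ich_disabled",
    "distance_miles", "mileage_rate",
    "caregiver_hours_minor", "caregiver_hours_major",
    "caregiver_hours_disabled", "caregiver_wage",
    "discount_rate", "cycle_length_years", "start_age", "horizon_years",
    "wtp", "device_life_years", "psm_tests_per_week", "meh_disutility_weeks",
)


class ParameterError(ValueError):
    """A configuration row violates the parameter contract."""


@dataclass(frozen=True)
class Parameter:
    """One model input: base value, plausible range, sampling family."""

    name: str
    base: float
    distribution: str = "fixed"
    low: float | None = None
    high: float | None = None
    sd: float | None = None
    units: str = ""
    group: str = "structural"
    note: str = ""
    range_inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ParameterError(
                f"{self.name}: unknown distribution {self.distribution!r}")
        if self.group not in GROUPS:
            raise ParameterError(f"{self.name}: unknown group {self.group!r}")
        if self.distribution != "fixed":
            allowed = _FAMILY_FOR_GROUP[self.group]
            if self.distribution not in allowed:
                raise ParameterError(
                    f"{self.name}: distribution {self.distribution!r} not "
                    f"allowed for group {self.group!r} (expected one of "
                    f"{sorted(allowed)} or 'fixed')")
        if self.group in ("proportion", "utility") and not (
                0.0 <= self.base <= 1.0):
            raise ParameterError(
                f"{self.name}: {self.group} base {self.base} outside [0, 1]")
        if self.distribution in ("gamma", "lognormal") and self.base < 0:
            raise ParameterError(
                f"{self.name}: {self.distribution} base must be nonnegative")
        if self.low is not None and self.high is not None:
            if self.low > self.high:
                if self.name not in RANGE_INCONSISTENT_ALLOWLIST:
                    raise ParameterError(
                        f"{self.name}: low {self.low} > high {self.high}")
            elif not (self.low <= self.base <= self.high):
                if self.name not in RANGE_INCONSISTENT_ALLOWLIST:
                    raise ParameterError(
                        f"{self.name}: base {self.base} outside "
                        f"[{self.low}, {self.high}]")

    @property
    def has_range(self) -> bool:
        return (self.low is not None and self.high is not None
                and self.high > self.low)

    def implied_sd(self) -> float:
        """Standard deviation implied by the 95%-interval reading (natural
        scale; log-normal parameters use the log scale elsewhere)."""
        if self.sd is not None:
            return float(self.sd)
        if self.low is None or self.high is None:
            return 0.0
        return (self.high - self.low) / 3.92


@dataclass(frozen=True)
class VisitScheduleSpec:
    """Month-level clinic visit intensities: (start_month, end_month,
    visits_per_month) segments, months 1-indexed, end_month ``None`` for
    open-ended."""

    strategy: str
    segments: tuple[tuple[int, int | None, float], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, vpm in self.segments:
            if vpm < 0:
                raise ParameterError(
                    f"{self.strategy} schedule: negative visit rate {vpm}")
            if start != prev_end + 1:
                raise ParameterError(
                    f"{self.strategy} schedule: segments must partition the "
                    f"horizon; segment starting at month {start} does not "
                    f"follow month {prev_end}")
            if end is not None and end < start:
                raise ParameterError(
                    f"{self.strategy} schedule: end month {end} before start "
                    f"{start}")
            prev_end = 10 ** 9 if end is None else end
        if prev_end != 10 ** 9:
            raise ParameterError(
                f"{self.strategy} schedule: final segment must be open-ended")

    def visits_per_month(self, month: int) -> float:
        if month < 1:
            raise ValueError(f"month must be >= 1, got {month}")
        for start, end, vpm in self.segments:
            if month >= start and (end is None or month <= end):
                return vpm
        raise AssertionError("unreachable: schedule covers all months")


class ParameterSet(Mapping):
    """Validated, immutable collection of all model parameters plus the
    clinic visit schedules."""

    def __init__(self, params: Mapping[str, Parameter],
                 schedules: Mapping[str, VisitScheduleSpec],
                 psm_training_cycles: int = 1):
        missing = [n for n in REQUIRED_PARAMETERS if n not in params]
        if missing:
            raise ParameterError(
                "missing required parameter(s): " + ", ".join(missing))
        unknown = [n for n in params if n not in REQUIRED_PARAMETERS]
        if unknown:
            raise ParameterError(
                "unknown parameter(s): " + ", ".join(sorted(unknown)))
        for strat in ("UC", "AMS"):
            if strat not in schedules:
                raise ParameterError(f"missing visit schedule for {strat}")
        self._params = dict(params)
        self.schedules = dict(schedules)
        self.psm_training_cycles = int(psm_training_cycles)
        self._validate_severity_vectors()

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ParameterSet)
                and self._params == other._params
                and self.schedules == other.schedules
                and self.psm_training_cycles == other.psm_training_cycles)

    # -- convenience accessors --------------------------------------------
    def value(self, name: str) -> float:
        return self._params[name].base

    @property
    def n_cycles(self) -> int:
        return int(round(self.value("horizon_years")
                         / self.value("cycle_length_years")))

    def is_severity(self) -> np.ndarray:
        """Severity split (minor, major, disabled, fatal) of a new ischemic
        stroke; sums to 1 as printed."""
        return np.array([self.value("is_severity_minor"),
                         self.value("is_severity_major"),
                         self.value("is_severity_disabled"),
                         self.value("is_severity_fatal")])

    def ich_severity_raw(self) -> np.ndarray:
        return np.array([self.value("ich_severity_minor"),
                         self.value("ich_severity_major"),
                         self.value("ich_severity_disabled"),
                         self.value("ich_severity_fatal")])

    def ich_severity(self) -> np.ndarray:
        """Intracranial-hemorrhage severity split renormalized to sum to 1
        (the printed values sum to 0.98; raw values are preserved in
        :meth:`ich_severity_raw`)."""
        raw = self.ich_severity_raw()
        return raw / raw.sum()

    def _validate_severity_vectors(self) -> None:
        if abs(self.is_severity().sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"ischemic-stroke severity proportions sum to "
                f"{self.is_severity().sum():.6f}, expected 1")
        s = self.ich_severity_raw().sum()
        if abs(s - 1.0) > 1e-9 and abs(s - 0.98) > 1e-9:
            raise ParameterError(
                f"intracranial-hemorrhage severity proportions sum to "
                f"{s:.6f}; expected 1 (or the documented printed sum 0.98)")

    def with_overrides(self, **values: float) -> "ParameterSet":
        """Return a copy with the given parameters' base values replaced."""
        params = dict(self._params)
        for name, v in values.items():
            if name not in params:
                raise KeyError(f"unknown parameter {name!r}")
            p = params[name]
            # an override is an explicit user choice; drop range-consistency
            # enforcement by clearing the flagged comparison when violated
            try:
                params[name] = replace(p, base=float(v))
            except ParameterError:
                params[name] = replace(p, base=float(v),
                                       range_inconsistent=True,
                                       low=None, high=None)
        return ParameterSet(params, self.schedules, self.psm_training_cycles)

    # -- serialization ----------------------------------------------------
    def to_config(self) -> dict:
        """Round-trippable plain-dict form (``load_parameters`` inverse)."""
        out: dict = {"parameters": {}, "visit_schedules": {},
                     "psm_training_cycles": self.psm_training_cycles}
        for name, p in self._params.items():
            row: dict = {"base": p.base, "distribution": p.distribution,
                         "group": p.group}
            if p.low is not None:
                row["low"] = p.low
            if p.high is not None:
                row["high"] = p.high
            if p.sd is not None:
                row["sd"] = p.sd
            if p.units:
                row["units"] = p.units
            if p.note:
                row["note"] = p.note
            out["parameters"][name] = row
        for strat, sched in self.schedules.items():
            out["visit_schedules"][strat] = [
                {"start_month": s, "end_month": e, "visits_per_month": v}
                for s, e, v in sched.segments]
        return out


def default_config_path() -> Path:
    """Path of the packaged default configuration."""
    return Path(resources.files("warfce").joinpath("data/params_us_2024.yaml"))


def load_parameters(config_source: str | Path | Mapping | None = None
                    ) -> ParameterSet:
    """Load and validate a :class:`ParameterSet`.

    Parameters
    ----------
    config_source
        Path to a YAML file, an already-parsed mapping, or ``None`` for the
        packaged default configuration.

    Raises
    ------
    ParameterError
        On missing or unknown parameter names, proportions outside [0, 1],
        or inconsistent ranges not on the documented allowlist.  Allowlisted
        inconsistencies are loaded but flagged with a warning.
    """
    if config_source is None:
        config_source = default_config_path()
    if isinstance(config_source, (str, Path)):
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config_source)
    if not isinstance(cfg, dict) or "parameters" not in cfg:
        raise ParameterError("config must contain a 'parameters' mapping")

    params: dict[str, Parameter] = {}
    for name, row in cfg["parameters"].items():
        if not isinstance(row, Mapping) or "base" not in row:
            raise ParameterError(f"{name}: row must provide a 'base' value")
        known = {"base", "low", "high", "sd", "distribution", "units",
                 "group", "note"}
        extra = set(row) - known
        if extra:
            raise ParameterError(f"{name}: unknown field(s) {sorted(extra)}")
        p = Parameter(
            name=name,
            base=float(row["base"]),
            distribution=row.get("distribution", "fixed"),
            low=None if row.get("low") is None else float(row["low"]),
            high=None if row.get("high") is None else float(row["high"]),
            sd=None if row.get("sd") is None else float(row["sd"]),
            units=row.get("units", ""),
            group=row.get("group", "structural"),
            note=row.get("note", ""),
        )
        if p.low is not None and p.high is not None and not (
                min(p.low, p.high) <= p.base <= max(p.low, p.high)
                and p.low <= p.high):
            warnings.warn(
                f"{name}: base {p.base} inconsistent with printed range "
                f"[{p.low}, {p.high}]; carried as printed and flagged",
                UserWarning, stacklevel=2)
            p = replace(p, range_inconsistent=True)
        params[name] = p

    schedules = {}
    for strat, segs in (cfg.get("visit_schedules") or {}).items():
        schedules[strat] = VisitScheduleSpec(
            strategy=strat,
            segments=tuple((int(s["start_month"]),
                            None if s.get("end_month") is None
                            else int(s["end_month"]),
                            float(s["visits_per_month"])) for s in segs))

    ps = ParameterSet(params, schedules,
                      int(cfg.get("psm_training_cycles", 1)))
    if abs(ps.ich_severity_raw().sum() - 1.0) > 1e-9:
        warnings.warn(
            "intracranial-hemorrhage severity proportions sum to "
            f"{ps.ich_severity_raw().sum():.2f}; renormalized to 1 for "
            "transition construction (raw values preserved)",
            UserWarning, stacklevel=2)
    return ps


# ---------------------------------------------------------------------------
# PSA distribution machinery
# ---------------------------------------------------------------------------

def derive_hyperparameters(p: Parameter) -> dict:
    """Method-of-moments hyperparameters for a parameter's PSA distribution.

    * gamma: mean = base, sd = (high-low)/3.92 (or explicit ``sd``), giving
      shape = (mean/sd)^2 and rate = mean/sd^2; sampling reproduces the mean.
    * beta: same moments on [0, 1]; if the requested variance is infeasible
      (sd^2 >= mean(1-mean)) fall back to the largest feasible variance with
      both shape parameters >= 1, with a warning.
    * log-normal: meanlog = ln(base), sdlog = (ln(high)-ln(low))/3.92;
      sampling reproduces the median.

    A degenerate range (high == low, or no range at all) yields a point mass
    at the base value.
    """
    if p.distribution == "fixed":
        raise ValueError(f"{p.name}: fixed parameters have no distribution")
    if p.distribution == "lognormal":
        if p.low is None or p.high is None or p.high == p.low:
            return {"family": "degenerate", "value": p.base}
        sdlog = (math.log(p.high) - math.log(p.low)) / 3.92
        return {"family": "lognormal", "meanlog": math.log(p.base),
                "sdlog": sdlog}
    sd = p.implied_sd()
    if sd == 0.0:
        return {"family": "degenerate", "value": p.base}
    mean = p.base
    if p.distribution == "gamma":
        shape = (mean / sd) ** 2
        rate = mean / sd ** 2
        return {"family": "gamma", "shape": shape, "rate": rate}
    # beta
    var = sd ** 2
    if var >= mean * (1.0 - mean):
        warnings.warn(
            f"{p.name}: requested beta variance {var:.4g} infeasible for "
            f"mean {mean}; using the widest beta with shape parameters >= 1",
            UserWarning, stacklevel=2)
        nu = 1.0 / min(mean, 1.0 - mean)
    else:
        nu = mean * (1.0 - mean) / var - 1.0
    return {"family": "beta", "alpha": mean * nu, "beta": (1.0 - mean) * nu}


def sample_value(p: Parameter, rng: np.random.Generator) -> float:
    """Draw one value of ``p`` from its derived hyperparameters."""
    h = derive_hyperparameters(p)
    fam = h["family"]
    if fam == "degenerate":
        return h["value"]
    if fam == "gamma":
        return float(rng.gamma(h["shape"], 1.0 / h["rate"]))
    if fam == "beta":
        return float(rng.beta(h["alpha"], h["beta"]))
    if fam == "lognormal":
        return float(rng.lognormal(h["meanlog"], h["sdlog"]))
    raise AssertionError(fam)


def _substream(master_seed: int, name: str, draw_index: int
               ) -> np.random.Generator:
    """Named random substream: one stream per (seed, parameter, draw), so
    adding or removing a parameter never perturbs the others' draws."""
    digest = hashlib.blake2b(name.encode(), digest_size=8).digest()
    name_key = int.from_bytes(digest, "little")
    ss = np.random.SeedSequence([int(master_seed), int(draw_index), name_key])
    return np.random.default_rng(ss)


_MAX_REDRAWS = 100


def sample_parameter_set(ps: ParameterSet, master_seed: int, draw_index: int
                         ) -> tuple[ParameterSet, int]:
    """One PSA realization of ``ps``.

    Fixed-distribution parameters keep their base values.  Draws that are
    invalid for downstream use (proportions or utilities outside [0, 1])
    are re-drawn from the same substream; the total redraw count is
    returned rather than silently clamped.
    """
    overrides: dict[str, float] = {}
    redraws = 0
    for name, p in ps.items():
        if p.distribution == "fixed":
            continue
        rng = _substream(master_seed, name, draw_index)
        v = sample_value(p, rng)
        tries = 0
        while p.group in ("proportion", "utility") and not 0.0 <= v <= 1.0:
            tries += 1
            if tries > _MAX_REDRAWS:
                raise RuntimeError(
                    f"{name}: could not draw a valid value in "
                    f"{_MAX_REDRAWS} attempts")
            v = sample_value(p, rng)
        redraws += tries
        overrides[name] = v
    return ps.with_overrides(**overrides), redraws
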