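"""Nonparametric survival estimation for competing causes of death.

Two routes to the same question, "what is the probability of dying of
cause *j* by time *t*?":

* **Naive cause-specific Kaplan-Meier** — the product-limit estimator run
  with only cause-*j* deaths as events and every competing-cause death
  treated as uninformatively censored.  Its complement ``1 - S_j(t)`` is
  the naive cumulative incidence and is biased upward whenever competing
  causes are dependent (and even without dependence it estimates a
  hypothetical-world quantity, not a real-world probability).
* **Aalen-Johansen cumulative incidence** — the proper competing-risks
  estimator, ``CIF_j(t) = sum over event times t_i <= t of
  S(t_i-) d_ij / n_i``, with ``S`` the all-cause product-limit curve.
  The resulting family satisfies ``S(t) + sum_j CIF_j(t) = 1`` exactly.

Ties between events and censorings at the same time are broken the
standard way: events first, so subjects censored at ``t`` are still at
risk for events at ``t``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ANALYSIS_CAUSES, CauseCategory, Cohort

__all__ = [
    "CurveKind",
    "StepCurve",
    "CifSet",
    "km_cause_specific",
    "km_all_cause",
    "aalen_johansen",
    "naive_cif",
    "sum_curves",
]


class CurveKind(str, enum.Enum):
    SURVIVAL = "survival"
    INCIDENCE = "incidence"


@dataclass(frozen=True)
class StepCurve:
    """A right-continuous piecewise-constant curve over follow-up time.

    ``values[i]`` is the curve's value on ``[times[i], times[i+1])``; before
    the first jump the curve sits at its starting value (1 for survival,
    0 for incidence) and after the last jump it is flat.  ``n_risk`` and
    ``n_event`` record the risk set just before, and the event count at,
    each jump.
    """

    times: np.ndarray
    values: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    kind: CurveKind

    def __post_init__(self) -> None:
        for name in ("times", "values", "n_risk", "n_event"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        t, v = self.times, self.values
        if t.shape != v.shape or t.shape != self.n_risk.shape or t.shape != self.n_event.shape:
            raise ValueError("times/values/n_risk/n_event must have equal length")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("jump times must be strictly increasing")
            if t[0] < 0:
                raise ValueError("jump times must be nonnegative")
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError("curve values must lie in [0, 1]")
            if np.any(np.diff(self.n_risk) > 0):
                raise ValueError("risk set must be nonincreasing across jumps")
            dv = np.diff(np.concatenate(([self.start_value], v)))
            if self.kind is CurveKind.SURVIVAL and np.any(dv > 1e-12):
                raise ValueError("survival curve must be nonincreasing from 1")
            if self.kind is CurveKind.INCIDENCE and np.any(dv < -1e-12):
                raise ValueError("incidence curve must be nondecreasing from 0")

    @property
    def start_value(self) -> float:
        return 1.0 if self.kind is CurveKind.SURVIVAL else 0.0

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the curve (right-continuously) at one or more times."""
        t = np.asarray(t, dtype=float)
        padded = np.concatenate(([self.start_value], self.values))
        idx = np.searchsorted(self.times, t, side="right")
        out = padded[idx]
        return float(out) if out.ndim == 0 else out

    __call__ = value_at

    def to_frame(self, cause: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.values,
                "n_risk": self.n_risk.astype(int),
                "n_event": self.n_event.astype(int),
                "kind": self.kind.value,
                "cause": cause,
            }
        )


@dataclass(frozen=True)
class CifSet:
    """The coherent Aalen-Johansen family: all-cause survival plus one
    cumulative incidence curve per cause, on the pooled event-time grid."""

    overall_survival: StepCurve
    cif_by_cause: Mapping[CauseCategory, StepCurve]

    def conservation_error(self) -> float:
        """max over jump times of |S(t) + sum_j CIF_j(t) - 1| (identically ~0)."""
        grid = self.overall_survival.times
        if grid.size == 0:
            return 0.0
        total = self.overall_survival.value_at(grid).copy()
        for curve in self.cif_by_cause.values():
            total = total + curve.value_at(grid)
        return float(np.max(np.abs(total - 1.0)))


def _event_table(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, dict[CauseCategory, np.ndarray]]:
    """Distinct event times, at-risk counts just before each, and per-cause
    death counts at each.  Risk sets count everyone with time >= t (ties:
    events before censorings)."""
    unknown = sum(1 for r in cohort if r.event and r.cause is CauseCategory.UNKNOWN)
    if unknown:
        raise ValueError(
            f"{unknown} unknown-cause death(s) present: reassign them before estimation"
        )
    times = np.array([r.time_years for r in cohort])
    sorted_times = np.sort(times)
    event_times = np.unique(times[np.array([r.event for r in cohort], dtype=bool)])
    # at risk just before t: all subjects with observed time >= t
    n_risk = (len(times) - np.searchsorted(sorted_times, event_times, side="left")).astype(float)
    d_by_cause: dict[CauseCategory, np.ndarray] = {}
    for cause in ANALYSIS_CAUSES:
        ct = np.sort([r.time_years for r in cohort if r.event and r.cause is cause])
        d_by_cause[cause] = (
            np.searchsorted(ct, event_times, side="right")
            - np.searchsorted(ct, event_times, side="left")
        ).astype(float)
    return event_times, n_risk, d_by_cause


def km_cause_specific(cohort: Cohort, cause: CauseCategory) -> StepCurve:
    """Naive cause-specific Kaplan-Meier survival curve.

    Only deaths of ``cause`` count as events; deaths of any other cause
    are censored at their death time.  Jumps occur only at event times of
    the cause; a cohort with no such deaths yields a flat curve at 1.
    """
    if cause is CauseCategory.UNKNOWN:
        raise ValueError("unknown is not an analysis cause; reassign it first")
    event_times, n_risk, d_by_cause = _event_table(cohort)
    d = d_by_cause[cause]
    mask = d > 0
    t, n, d = event_times[mask], n_risk[mask], d[mask]
    surv = np.cumprod(1.0 - d / n)
    return StepCurve(times=t, values=surv, n_risk=n, n_event=d, kind=CurveKind.SURVIVAL)


def km_all_cause(cohort: Cohort) -> StepCurve:
    """All-cause Kaplan-Meier survival curve (every death is an event)."""
    event_times, n_risk, d_by_cause = _event_table(cohort)
    d_all = sum(d_by_cause.values()) if d_by_cause else np.zeros(0)
    if len(event_times) == 0:
        return StepCurve(
            times=np.zeros(0), values=np.zeros(0), n_risk=np.zeros(0),
            n_event=np.zeros(0), kind=CurveKind.SURVIVAL,
        )
    surv = np.cumprod(1.0 - d_all / n_risk)
    return StepCurve(
        times=event_times, values=surv, n_risk=n_risk, n_event=d_all,
        kind=CurveKind.SURVIVAL,
    )


def aalen_johansen(cohort: Cohort) -> CifSet:
    """Aalen-Johansen cumulative incidence for every analysis cause.

    ``CIF_j(t) = sum over event times t_i <= t of S(t_i-) * d_ij / n_i``
    with ``S`` the all-cause product-limit survival curve.  All curves in
    the returned set share the pooled event-time grid, so the
    conservation identity holds at every point.
    """
    event_times, n_risk, d_by_cause = _event_table(cohort)
    overall = km_all_cause(cohort)
    if len(event_times) == 0:
        empty = {
            c: StepCurve(np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0), CurveKind.INCIDENCE)
            for c in ANALYSIS_CAUSES
        }
        return CifSet(overall_survival=overall, cif_by_cause=empty)
    # survival just before each event time: shift the product by one step
    s_minus = np.concatenate(([1.0], overall.values[:-1]))
    cifs: dict[CauseCategory, StepCurve] = {}
    for cause in ANALYSIS_CAUSES:
        increments = s_minus * d_by_cause[cause] / n_risk
        cifs[cause] = StepCurve(
            times=event_times,
            values=np.cumsum(increments),
            n_risk=n_risk,
            n_event=d_by_cause[cause],
            kind=CurveKind.INCIDENCE,
        )
    return CifSet(overall_survival=overall, cif_by_cause=cifs)


def naive_cif(km_curve: StepCurve) -> StepCurve:
    """Complement of a Kaplan-Meier survival curve: the naive cumulative
    incidence ``1 - S(t)`` on the same jump grid."""
    if km_curve.kind is not CurveKind.SURVIVAL:
        raise ValueError("naive_cif expects a survival curve")
    return StepCurve(
        times=km_curve.times,
        values=1.0 - km_curve.values,
        n_risk=km_curve.n_risk,
        n_event=km_curve.n_event,
        kind=CurveKind.INCIDENCE,
    )


def survival_from_cif(cif: StepCurve) -> StepCurve:
    """Complement of a cumulative incidence curve: the cause-specific
    survival ``1 - CIF_j(t)`` implied by the competing-risks estimate."""
    if cif.kind is not CurveKind.INCIDENCE:
        raise ValueError("survival_from_cif expects an incidence curve")
    return StepCurve(
        times=cif.times,
        values=1.0 - cif.values,
        n_risk=cif.n_risk,
        n_event=cif.n_event,
        kind=CurveKind.SURVIVAL,
    )


def sum_curves(curves: Sequence[StepCurve]) -> "SummedCurve":
    """Pointwise sum of incidence curves on the union of their jump grids.

    The sum is a diagnostic, not a probability: with naive per-cause
    incidence it can exceed 1, which is exactly the pathology that
    signals bias.  Values are therefore NOT clipped to [0, 1].
    """
    for c in curves:
        if c.kind is not CurveKind.INCIDENCE:
            raise ValueError("sum_curves expects incidence curves only")
    if not curves:
        return SummedCurve(times=np.zeros(0), values=np.zeros(0))
    grid = np.unique(np.concatenate([c.times for c in curves]))
    total = np.zeros_like(grid)
    for c in curves:
        total = total + np.asarray(c.value_at(grid))
    return SummedCurve(times=grid, values=total)


@dataclass(frozen=True)
class SummedCurve:
    """Sum of incidence curves; right-continuous, starts at 0, may exceed 1."""

    times: np.ndarray
    values: np.ndarray

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        padded = np.concatenate(([0.0], self.values))
        out = padded[np.searchsorted(self.times, t, side="right")]
        return float(out) if out.ndim == 0 else out

    @property
    def max_value(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0

    @property
    def exceeds_one(self) -> bool:
        return self.max_value > 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "cumulative_incidence_sum": self.values})
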