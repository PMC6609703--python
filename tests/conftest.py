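"""Shared fixtures and exact-rational oracle estimators.

The oracles recompute the product-limit and cumulative-incidence
recursions directly from their definitions in ``fractions.Fraction``
arithmetic, independently of the package's vectorized float
implementations.
"""

from fractions import Fraction

import numpy as np
import pytest

from cifbias import ANALYSIS_CAUSES, CauseCategory, Cohort, SubjectRecord


def km_oracle(cohort, cause=None):
    """Product-limit survival by exact-rational recursion.

    ``cause=None`` treats every death as an event (all-cause curve);
    otherwise only deaths of that cause count and all others censor.
    Ties: events before censorings (at-risk = everyone with time >= t).
    Returns ``{event_time: Fraction}``.
    """
    times = [r.time_years for r in cohort]
    event_times = sorted(
        {r.time_years for r in cohort if r.event and (cause is None or r.cause is cause)}
    )
    surv, out = Fraction(1), {}
    for t in event_times:
        n = sum(1 for x in times if x >= t)
        d = sum(
            1 for r in cohort
            if r.event and r.time_years == t and (cause is None or r.cause is cause)
        )
        surv *= Fraction(n - d, n)
        out[t] = surv
    return out


def aj_oracle(cohort, cause):
    """Aalen-Johansen cumulative incidence by exact-rational recursion:
    CIF_j(t) = sum over event times t_i <= t of S_all(t_i-) d_ij / n_i.
    Returns ``{event_time: Fraction}`` on the pooled event-time grid."""
    times = [r.time_years for r in cohort]
    event_times = sorted({r.time_years for r in cohort if r.event})
    s_all, cif, out = Fraction(1), Fraction(0), {}
    for t in event_times:
        n = sum(1 for x in times if x >= t)
        d_all = sum(1 for r in cohort if r.event and r.time_years == t)
        d_j = sum(1 for r in cohort if r.event and r.time_years == t and r.cause is cause)
        cif += s_all * Fraction(d_j, n)
        s_all *= Fraction(n - d_all, n)
        out[t] = cif
    return out


def random_cohort(rng, n, label="random", p_event=0.6, max_time=50.0, tie_grid=None):
    """A random competing-risks cohort; ``tie_grid`` snaps times to a
    lattice so that tied events and censorings occur."""
    records = []
    for i in range(n):
        t = float(rng.uniform(0.1, max_time))
        if tie_grid:
            t = round(t / tie_grid) * tie_grid + tie_grid
        event = bool(rng.random() < p_event)
        cause = ANALYSIS_CAUSES[rng.integers(len(ANALYSIS_CAUSES))] if event else None
        records.append(SubjectRecord(f"r{i}", label, t, event, cause))
    return Cohort.from_records(records, label=label)


@pytest.fixture
def four_subject_cohort():
    """The hand-worked example: cause-A (cancer) deaths at t=1 and t=3, a
    competing cause-B (CVD) death at t=2, one subject censored at t=4."""
    return Cohort.from_records(
        [
            SubjectRecord("a", "w", 1.0, True, CauseCategory.CANCER),
            SubjectRecord("b", "w", 2.0, True, CauseCategory.CVD),
            SubjectRecord("c", "w", 3.0, True, CauseCategory.CANCER),
            SubjectRecord("d", "w", 4.0, False, None),
        ],
        label="worked",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
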