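"""Small deterministic example cohorts.

These are synthetic stand-ins shaped like the two historical spacefarer
cohorts this kind of analysis is run on: the *counts* (cohort size,
deaths per cause) match published cohort-characteristics tables, while
the individual follow-up times are arbitrary deterministic values chosen
to give a similar mean and maximum follow-up.  They exist so that
summaries, reassignment scenarios and pipeline plumbing can be exercised
without any real roster data, which is never packaged.
"""

from __future__ import annotations

import numpy as np

from .cohort import CauseCategory, Cohort, SubjectRecord

__all__ = ["example_cohort", "EXAMPLE_NAMES"]

EXAMPLE_NAMES = ("astronaut_shaped", "cosmonaut_shaped")

# deaths per cause: (cancer, cvd, other_natural, external, unknown)
_DEATH_MIX = {
    "astronaut_shaped": dict(n=301, mix=(16, 8, 6, 20, 3), max_fu=54.8),
    "cosmonaut_shaped": dict(n=117, mix=(10, 18, 2, 6, 0), max_fu=54.9),
}
_CAUSES = (
    CauseCategory.CANCER,
    CauseCategory.CVD,
    CauseCategory.OTHER_NATURAL,
    CauseCategory.EXTERNAL,
    CauseCategory.UNKNOWN,
)


def example_cohort(name: str) -> Cohort:
    """Build one of the shipped synthetic example cohorts.

    ``astronaut_shaped``: n=301 with 53 deaths split 16/8/6/20/3 across
    cancer / CVD / other natural / external / unknown.
    ``cosmonaut_shaped``: n=117 with 36 deaths split 10/18/2/6/0.
    Deterministic: repeated calls return identical cohorts.
    """
    if name not in _DEATH_MIX:
        raise ValueError(f"unknown example {name!r}; available: {EXAMPLE_NAMES}")
    spec = _DEATH_MIX[name]
    n, mix, max_fu = spec["n"], spec["mix"], spec["max_fu"]
    n_deaths = sum(mix)

    # interleave causes across the death-time ladder so no cause clusters
    causes: list[CauseCategory] = []
    pools = [[c] * k for c, k in zip(_CAUSES, mix)]
    while any(pools):
        for pool in pools:
            if pool:
                causes.append(pool.pop())
    death_times = np.linspace(1.0, max_fu - 1.0, n_deaths)

    # censored follow-up skewed toward shorter times (staggered entry),
    # anchored at the maximum follow-up
    n_cens = n - n_deaths
    cens_times = max_fu * np.linspace(0.0, 1.0, n_cens) ** 1.26
    cens_times[0] = 0.1

    records = [
        SubjectRecord(f"D{i:03d}", name, float(t), True, c)
        for i, (t, c) in enumerate(zip(death_times, causes))
    ] + [
        SubjectRecord(f"C{i:03d}", name, float(t), False, None)
        for i, t in enumerate(cens_times)
    ]
    return Cohort.from_records(records, label=name)
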