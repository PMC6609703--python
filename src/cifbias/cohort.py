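"""Cohort data model, delimited-text I/O, and actuarial summaries.

A cohort is a flat table of subjects followed from study entry (first
spaceflight, first employment, ...) until death or administrative
censoring.  Deaths carry one of five cause-of-death categories; the
``unknown`` category exists only as a bookkeeping label for deaths whose
cause could not be ascertained, and must be reassigned to one of the
natural-cause categories before any cause-specific estimation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "CauseCategory",
    "SubjectRecord",
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "reassign_unknown",
]


class CauseCategory(str, enum.Enum):
    """Cause-of-death taxonomy used throughout the package."""

    CANCER = "cancer"
    CVD = "cvd"
    OTHER_NATURAL = "other_natural"
    EXTERNAL = "external"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Causes that may appear in estimator output (unknown must be reassigned first).
ANALYSIS_CAUSES = (
    CauseCategory.CANCER,
    CauseCategory.CVD,
    CauseCategory.OTHER_NATURAL,
    CauseCategory.EXTERNAL,
)

#: Admissible targets when reassigning unknown-cause deaths.
REASSIGNMENT_TARGETS = (
    CauseCategory.CANCER,
    CauseCategory.CVD,
    CauseCategory.OTHER_NATURAL,
)


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the data contract."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's follow-up: time on study, vital status, cause of death.

    ``time_years`` is measured from study entry; ``cause`` is present iff
    ``event`` is true.
    """

    subject_id: str
    cohort: str
    time_years: float
    event: bool
    cause: CauseCategory | None = None

    def __post_init__(self) -> None:
        t = float(self.time_years)
        if not (t >= 0.0) or t != t or t == float("inf"):
            raise CohortValidationError(
                f"subject {self.subject_id!r}: time_years must be finite and >= 0, got {self.time_years!r}"
            )
        if self.event and self.cause is None:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: event without a cause of death"
            )
        if not self.event and self.cause is not None:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: cause {self.cause} given on a censored record"
            )


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of subject records."""

    records: tuple[SubjectRecord, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.records:
            raise CohortValidationError(f"cohort {self.label!r} is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise CohortValidationError(
                    f"cohort {self.label!r}: duplicate subject_id {rec.subject_id!r}"
                )
            seen.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord], label: str) -> "Cohort":
        return cls(records=tuple(records), label=label)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns subject_id, cohort, time_years, event, cause."""
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "cohort": [r.cohort for r in self.records],
                "time_years": [r.time_years for r in self.records],
                "event": [int(r.event) for r in self.records],
                "cause": [r.cause.value if r.cause else "" for r in self.records],
            }
        )


@dataclass(frozen=True)
class CohortSummary:
    """Actuarial one-cohort summary: person-years and the death mix by cause."""

    n: int
    total_person_years: float
    mean_follow_up: float
    max_follow_up: float
    deaths_by_cause: Mapping[CauseCategory, int] = field(default_factory=dict)
    death_pct_by_cause: Mapping[CauseCategory, float] = field(default_factory=dict)

    @property
    def total_deaths(self) -> int:
        return sum(self.deaths_by_cause.values())

    def to_frame(self) -> pd.DataFrame:
        """Export in the shape of a cohort-characteristics table."""
        rows = [
            ("n", self.n),
            ("total_person_years", round(self.total_person_years, 1)),
            ("mean_follow_up", round(self.mean_follow_up, 1)),
            ("max_follow_up", round(self.max_follow_up, 1)),
            ("deaths_all_causes", self.total_deaths),
        ]
        for cause in CauseCategory:
            n = self.deaths_by_cause.get(cause, 0)
            pct = self.death_pct_by_cause.get(cause)
            label = f"{n} ({pct})" if pct is not None else str(n)
            rows.append((f"deaths_{cause.value}", label))
        return pd.DataFrame(rows, columns=["statistic", "value"])


_REQUIRED_COLUMNS = ("subject_id", "cohort", "time_years", "event", "cause")


def read_cohort(path: str | Path, cohort_label: str | None = None, sep: str = ",") -> Cohort:
    """Read a cohort from delimited text.

    The header must name the columns ``subject_id, cohort, time_years,
    event, cause`` in any order; ``event`` is 0/1 and ``cause`` is one of
    the five category labels, empty on censored rows.

    Raises :class:`CohortValidationError` naming the offending row on any
    contract violation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing column(s) {missing}")

    records: list[SubjectRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            time_years = float(row.time_years)
        except ValueError:
            raise CohortValidationError(
                f"{path} line {idx}: non-numeric time_years {row.time_years!r}"
            ) from None
        if row.event not in ("0", "1"):
            raise CohortValidationError(
                f"{path} line {idx}: event must be 0 or 1, got {row.event!r}"
            )
        event = row.event == "1"
        cause_str = row.cause.strip()
        cause: CauseCategory | None = None
        if cause_str:
            try:
                cause = CauseCategory(cause_str)
            except ValueError:
                raise CohortValidationError(
                    f"{path} line {idx}: unrecognized cause {cause_str!r}"
                ) from None
        try:
            records.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    cohort=row.cohort,
                    time_years=time_years,
                    event=event,
                    cause=cause,
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path} line {idx}: {exc}") from None

    label = cohort_label if cohort_label is not None else (records[0].cohort if records else "")
    return Cohort.from_records(records, label=label)


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort in the delimited-text format that :func:`read_cohort` reads."""
    cohort.to_frame().to_csv(path, sep=sep, index=False)


def _round_half_up(x: float, places: int = 1) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Cohort characteristics: n, person-years, and the death mix by cause.

    Percentages use the all-cause death count as denominator and are
    rounded half-up to one decimal; with zero deaths the percentage map
    is empty.
    """
    times = [r.time_years for r in cohort]
    deaths: dict[CauseCategory, int] = {c: 0 for c in CauseCategory}
    for r in cohort:
        if r.event:
            deaths[r.cause] += 1
    total_deaths = sum(deaths.values())
    pct: dict[CauseCategory, float] = {}
    if total_deaths > 0:
        pct = {
            c: _round_half_up(100.0 * k / total_deaths) for c, k in deaths.items()
        }
    return CohortSummary(
        n=len(cohort),
        total_person_years=sum(times),
        mean_follow_up=sum(times) / len(cohort),
        max_follow_up=max(times),
        deaths_by_cause=deaths,
        death_pct_by_cause=pct,
    )


def reassign_unknown(cohort: Cohort, scenario: CauseCategory) -> Cohort:
    """Return a new cohort with every unknown-cause death relabelled.

    Only the three natural-cause targets (cancer, CVD, other natural) are
    admissible scenarios; external and unknown are rejected.  The input
    cohort is not modified.
    """
    if scenario not in REASSIGNMENT_TARGETS:
        raise ValueError(
            f"invalid reassignment scenario {scenario}: must be one of "
            f"{[c.value for c in REASSIGNMENT_TARGETS]}"
        )
    new_records = tuple(
        replace(r, cause=scenario) if r.cause is CauseCategory.UNKNOWN else r
        for r in cohort
    )
    return Cohort(records=new_records, label=cohort.label)
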