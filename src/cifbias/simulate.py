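"""Synthetic cohorts with competing exponential hazards and shared frailty.

Each subject carries one latent exponential time per cause of death; the
observed record is the minimum of those times and an administrative
censoring horizon (a fixed study-close offset, or per-subject horizons
drawn uniformly to emulate staggered entry).  A mean-1 gamma frailty
``Z ~ Gamma(shape=1/theta, scale=theta)`` multiplies the hazards of a
chosen subset of causes (cancer and CVD by default): ``theta = 0`` gives
independent causes, ``theta > 0`` makes deaths from the dependent causes
positively associated — the "common underlying cause" mechanism whose
signature the bias metrics are designed to pick up.  Because the frailty
has mean 1, marginal death rates stay approximately calibrated as theta
varies.

Closed forms for the independent (``theta = 0``) regime are provided as
oracles: with total hazard ``L = sum_j lambda_j``, the true cumulative
incidence is ``CIF_j(t) = (lambda_j / L) (1 - exp(-L t))`` while the
naive (marginal) counterpart is ``1 - exp(-lambda_j t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .cohort import ANALYSIS_CAUSES, CauseCategory, Cohort, SubjectRecord

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "analytic_cif",
    "naive_analytic_cif",
    "cause_fraction",
    "load_preset",
    "PRESET_NAMES",
]

_PRESET_DIR = Path(__file__).parent / "presets"
PRESET_NAMES = ("astronaut_like", "cosmonaut_like")


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    ``censor_time`` is either a single administrative horizon in years or
    a ``(min, max)`` pair of per-subject uniform horizons (staggered
    entry on the time-since-entry scale).  ``frailty_variance`` is the
    variance theta of the mean-1 gamma frailty shared by
    ``dependent_causes``.
    """

    n: int
    hazards: Mapping[CauseCategory, float]
    censor_time: float | tuple[float, float]
    frailty_variance: float = 0.0
    dependent_causes: frozenset[CauseCategory] = frozenset(
        {CauseCategory.CANCER, CauseCategory.CVD}
    )
    seed: int = 0
    label: str = "simulated"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if self.frailty_variance < 0:
            raise ValueError(f"frailty variance must be >= 0, got {self.frailty_variance}")
        for cause in ANALYSIS_CAUSES:
            lam = self.hazards.get(cause, 0.0)
            if not np.isfinite(lam) or lam < 0:
                raise ValueError(f"hazard for {cause.value} must be finite and >= 0, got {lam}")
        if CauseCategory.UNKNOWN in self.hazards:
            raise ValueError("unknown is not a simulatable cause")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimConfig":
        """Load a config from a YAML file with keys matching the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("calibration_targets", None)  # preset provenance, not a parameter
        raw.update(overrides)
        raw["hazards"] = {CauseCategory(k): float(v) for k, v in raw["hazards"].items()}
        if "dependent_causes" in raw:
            raw["dependent_causes"] = frozenset(CauseCategory(c) for c in raw["dependent_causes"])
        if isinstance(raw.get("censor_time"), list):
            raw["censor_time"] = tuple(raw["censor_time"])
        return cls(**raw)


def load_preset(name: str, **overrides) -> SimConfig:
    """Load one of the shipped cohort presets (``astronaut_like`` or
    ``cosmonaut_like``), optionally overriding fields such as ``seed``."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    return SimConfig.from_yaml(_PRESET_DIR / f"{name}.yaml", **overrides)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort from the latent-failure-time model.

    Reproducible: the same config (including seed) yields a bit-identical
    cohort.  All hazards zero gives an all-censored cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    theta = config.frailty_variance
    if theta > 0:
        frailty = rng.gamma(shape=1.0 / theta, scale=theta, size=n)
    else:
        frailty = np.ones(n)

    latent = np.full((n, len(ANALYSIS_CAUSES)), np.inf)
    for j, cause in enumerate(ANALYSIS_CAUSES):
        lam = config.hazards.get(cause, 0.0)
        rate = lam * (frailty if cause in config.dependent_causes else 1.0)
        draws = rng.exponential(1.0, size=n)  # unit-rate draws scaled below
        with np.errstate(divide="ignore"):
            latent[:, j] = np.where(rate > 0, draws / np.where(rate > 0, rate, 1.0), np.inf)

    if isinstance(config.censor_time, tuple):
        lo, hi = config.censor_time
        horizons = rng.uniform(lo, hi, size=n)
    else:
        horizons = np.full(n, float(config.censor_time))

    t_death = latent.min(axis=1)
    cause_idx = latent.argmin(axis=1)
    died = t_death < horizons
    observed = np.where(died, t_death, horizons)

    width = len(str(n))
    records = [
        SubjectRecord(
            subject_id=f"S{i:0{width}d}",
            cohort=config.label,
            time_years=float(observed[i]),
            event=bool(died[i]),
            cause=ANALYSIS_CAUSES[cause_idx[i]] if died[i] else None,
        )
        for i in range(n)
    ]
    return Cohort.from_records(records, label=config.label)


def analytic_cif(
    hazards: Mapping[CauseCategory, float], cause: CauseCategory, t: float
) -> float:
    """True cumulative incidence of ``cause`` at time t under independent
    exponential competing risks: ``(lambda_j / L)(1 - exp(-L t))``."""
    total = sum(hazards.values())
    if total == 0:
        return 0.0
    lam = hazards.get(cause, 0.0)
    return (lam / total) * -np.expm1(-total * t)


def naive_analytic_cif(
    hazards: Mapping[CauseCategory, float], cause: CauseCategory, t: float
) -> float:
    """Marginal (naive) cumulative incidence ``1 - exp(-lambda_j t)`` — what
    the cause-specific Kaplan-Meier complement converges to when
    competing causes are independent."""
    return float(-np.expm1(-hazards.get(cause, 0.0) * t))


def cause_fraction(
    hazards: Mapping[CauseCategory, float], horizon: float
) -> dict[CauseCategory, float]:
    """Probability of dying of each cause before a fixed horizon
    (independent-hazards regime); the calibration helper behind the
    shipped presets."""
    return {cause: analytic_cif(hazards, cause, horizon) for cause in hazards}
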