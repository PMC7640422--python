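"""Virtual population of singleton pregnant women.

Builds the maternal-age trisomy-21 risk curve and the age-specific
fertility schedule, then draws a stochastic annual cohort: each woman in
the base female population becomes pregnant with her age-specific
probability, and each pregnancy is assigned a fetal Down-syndrome status
by a Bernoulli draw at the maternal-age-specific first-trimester risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import PopulationConfig

__all__ = [
    "AgeRiskCurve",
    "FertilitySchedule",
    "Woman",
    "PregnancyCohort",
    "build_age_risk_curve",
    "build_fertility_schedule",
    "generate_cohort",
    "assign_ds_status",
]

#: Pregnancy states. Transitions into any state other than ``ongoing`` are terminal.
PREGNANCY_STATES = (
    "ongoing",
    "spontaneous_loss",
    "voluntary_termination",
    "procedure_loss",
    "ds_termination",
    "live_birth",
)


@dataclass(frozen=True)
class AgeRiskCurve:
    """First-trimester Down-syndrome risk per pregnancy, by maternal age.

    ``risk`` holds the unscaled curve; :meth:`scaled_risk` applies the
    multiplicative ``prevalence_scale`` calibration factor and clips to
    ``[floor, cap]`` (so a scale of zero leaves every age at the floor).
    """

    age_grid: np.ndarray
    risk: np.ndarray
    prevalence_scale: float = 1.0
    floor: float = 0.0010
    cap: float = 0.066

    def scaled_risk(self) -> np.ndarray:
        return np.clip(self.risk * self.prevalence_scale, self.floor, self.cap)

    def risk_at(self, age: int | np.ndarray) -> np.ndarray:
        ages = np.asarray(age)
        if np.any(ages < self.age_grid[0]) or np.any(ages > self.age_grid[-1]):
            raise ValueError(
                f"age outside the curve domain "
                f"[{self.age_grid[0]}, {self.age_grid[-1]}]"
            )
        return self.scaled_risk()[ages - self.age_grid[0]]

    def with_scale(self, scale: float) -> "AgeRiskCurve":
        return AgeRiskCurve(self.age_grid, self.risk, scale, self.floor, self.cap)

    def _validate(self) -> None:
        scaled = self.scaled_risk()
        if np.any(scaled < self.floor - 1e-12) or np.any(scaled > self.cap + 1e-12):
            raise ValueError("scaled risks escaped the clipping bounds")
        over25 = self.age_grid >= 25
        if np.any(np.diff(scaled[over25]) < -1e-12):
            raise ValueError("risk must be non-decreasing over ages >= 25")


@dataclass(frozen=True)
class FertilitySchedule:
    """Per-age annual pregnancy probability over a base female population."""

    age_grid: np.ndarray
    annual_pregnancy_prob: np.ndarray
    base_population: np.ndarray

    @property
    def expected_pregnancies(self) -> float:
        return float(np.sum(self.base_population * self.annual_pregnancy_prob))

    @property
    def overall_rate(self) -> float:
        total = self.base_population.sum()
        return self.expected_pregnancies / total if total > 0 else 0.0


@dataclass
class Woman:
    """One simulated singleton pregnancy followed on a weekly cycle."""

    id: int
    maternal_age: int
    ds_affected: bool
    entry_week: int = 10
    current_week: int = 10
    pregnancy_state: str = "ongoing"
    pathway_state: str = "start"
    events: list = field(default_factory=list)
    confirmed_week: int | None = None
    accepted_offer: bool | None = None
    screen_positive: bool | None = None
    milestones_done: set = field(default_factory=set)

    def record(self, event) -> None:
        if self.events and event.week < self.events[-1].week:
            raise ValueError("events must be non-decreasing in week")
        self.events.append(event)

    def set_terminal(self, state: str) -> None:
        if state not in PREGNANCY_STATES or state == "ongoing":
            raise ValueError(f"not a terminal pregnancy state: {state!r}")
        if self.pregnancy_state != "ongoing":
            raise ValueError("pregnancy state transitions are irreversible")
        self.pregnancy_state = state

    @property
    def ongoing(self) -> bool:
        return self.pregnancy_state == "ongoing"


@dataclass
class PregnancyCohort:
    """Columnar cohort of pregnancies (one row per woman).

    The arrays are the canonical representation used by the vectorized
    engine; :meth:`to_women` materializes agent objects for the per-woman
    pathway API.
    """

    ages: np.ndarray
    ds_affected: np.ndarray
    entry_week: int
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.ages.shape[0])

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n, dtype=np.int64)

    def to_women(self) -> Iterator[Woman]:
        for i in range(self.n):
            yield Woman(
                id=i,
                maternal_age=int(self.ages[i]),
                ds_affected=bool(self.ds_affected[i]),
                entry_week=self.entry_week,
                current_week=self.entry_week,
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "age": self.ages,
                "ds_affected": self.ds_affected.astype(int),
                "entry_week": self.entry_week,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PregnancyCohort":
        df = pd.read_csv(path)
        if df["id"].duplicated().any():
            raise ValueError("cohort ids must be unique")
        entry = int(df["entry_week"].iloc[0]) if len(df) else 10
        return cls(
            ages=df["age"].to_numpy(np.int64),
            ds_affected=df["ds_affected"].to_numpy(bool),
            entry_week=entry,
        )


def build_age_risk_curve(
    params: PopulationConfig | None = None,
    *,
    table: dict[int, float] | None = None,
    prevalence_scale: float | None = None,
) -> AgeRiskCurve:
    """Construct the maternal-age risk curve.

    With ``table`` given, the explicit age -> risk mapping is validated and
    used as-is (before scaling/clipping). Otherwise the default
    exponential-in-age curve from ``params`` is built: risk doubles every
    ~2.5 years of age and reaches the cap at the oldest age, with young
    ages clipped to the floor.
    """
    params = params or PopulationConfig()
    scale = params.prevalence_scale if prevalence_scale is None else prevalence_scale
    if table is not None:
        ages = np.array(sorted(table), dtype=np.int64)
        risk = np.array([table[int(a)] for a in ages], dtype=float)
        if np.any(risk < 0) or np.any(risk > 1):
            raise ValueError("explicit risks must lie in [0, 1]")
        over25 = ages >= 25
        if np.any(np.diff(risk[over25]) < 0):
            raise ValueError("explicit risk table must be non-decreasing over ages >= 25")
    else:
        ages = np.arange(params.age_min, params.age_max + 1, dtype=np.int64)
        # solve the intercept so the unscaled curve attains the cap at age_max
        b = np.log(params.risk_cap - params.risk_offset) - params.risk_log_slope * params.age_max
        risk = params.risk_offset + np.exp(b + params.risk_log_slope * ages)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk curve parameters produced non-finite risks")
    curve = AgeRiskCurve(
        age_grid=ages,
        risk=risk,
        prevalence_scale=scale,
        floor=params.risk_floor,
        cap=params.risk_cap,
    )
    curve._validate()
    return curve


def build_fertility_schedule(
    overall_rate: float,
    base_population_total: float,
    age_shape: np.ndarray | None = None,
    *,
    params: PopulationConfig | None = None,
) -> FertilitySchedule:
    """Rescale a relative fertility shape to a target overall pregnancy rate.

    The base population is spread uniformly over integer ages; per-age
    probabilities are the shape weights rescaled so that
    ``sum(base * prob) / sum(base) == overall_rate``.
    """
    params = params or PopulationConfig()
    if not (0.0 <= overall_rate < 1.0):
        raise ValueError("overall_rate must lie in [0, 1)")
    ages = np.arange(params.age_min, params.age_max + 1, dtype=np.int64)
    if age_shape is None:
        age_shape = np.exp(-0.5 * ((ages - params.age_mode) / params.age_sd) ** 2)
    age_shape = np.asarray(age_shape, dtype=float)
    if age_shape.shape != ages.shape:
        raise ValueError("age_shape must have one weight per age")
    if np.any(age_shape < 0) or not np.any(age_shape > 0):
        raise ValueError("age_shape weights must be non-negative and not all zero")
    base = np.full(ages.shape, base_population_total / len(ages), dtype=float)
    weighted_mean = np.sum(base * age_shape) / base.sum() if base.sum() > 0 else 1.0
    if overall_rate == 0.0 or base.sum() == 0:
        prob = np.zeros_like(age_shape)
    else:
        prob = overall_rate * age_shape / weighted_mean
    too_high = prob > 1.0
    if np.any(too_high):
        bad_age = int(ages[np.argmax(too_high)])
        raise ValueError(
            f"cannot rescale to overall rate {overall_rate}: per-age pregnancy "
            f"probability at age {bad_age} would exceed 1"
        )
    sched = FertilitySchedule(ages, prob, base)
    if base.sum() > 0 and abs(sched.overall_rate - overall_rate) > 1e-6:
        raise AssertionError("fertility rescale failed to hit the overall rate")
    return sched


def assign_ds_status(age: int, curve: AgeRiskCurve, rng: np.random.Generator) -> bool:
    """Bernoulli fetal Down-syndrome status at the maternal-age-specific risk."""
    risk = float(curve.risk_at(int(age)))
    return bool(rng.random() < risk)


def generate_cohort(
    fertility: FertilitySchedule,
    risk: AgeRiskCurve,
    entry_week: int = 10,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> PregnancyCohort:
    """Draw one annual cohort of pregnancies.

    Per age stratum the number of pregnancies is binomial over the base
    population (the sum of the per-woman Bernoulli draws); fetal DS status
    is an independent per-pregnancy Bernoulli at the scaled curve risk.
    Cohort size is therefore Poisson-binomial with mean
    ``sum(base * prob)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.round(fertility.base_population).astype(np.int64)
    counts = rng.binomial(base, fertility.annual_pregnancy_prob)
    ages = np.repeat(fertility.age_grid, counts)
    risks = risk.risk_at(ages) if ages.size else np.empty(0)
    ds = rng.random(ages.shape) < risks
    return PregnancyCohort(
        ages=ages,
        ds_affected=ds,
        entry_week=entry_week,
        seed=None if isinstance(seed, (np.random.Generator, np.random.SeedSequence)) else seed,
        provenance={
            "overall_rate": fertility.overall_rate,
            "base_population_total": float(fertility.base_population.sum()),
            "prevalence_scale": risk.prevalence_scale,
            "entry_week": entry_week,
        },
    )
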