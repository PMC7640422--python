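"""Structured configuration for the screening budget-impact simulator.

Every tunable quantity of the model lives here: the virtual-population
parameters (size, age structure, maternal-age trisomy-21 risk), the
pregnancy natural-history schedules (spontaneous loss, voluntary induced
abortion), the operating characteristics and unit costs of the screening
tests, the two strategy pathways' uptakes and event calendar, the
non-test unit costs, and the replication controls.

Configs round-trip through plain dictionaries and YAML/JSON files so a
run is fully described by one text file plus a master seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "PopulationConfig",
    "NaturalHistoryConfig",
    "TestProfile",
    "TestsConfig",
    "CalendarConfig",
    "StrategyConfig",
    "CostsConfig",
    "SimulationConfig",
    "default_config",
    "load_config",
    "save_config",
    "set_by_path",
    "get_by_path",
]


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class PopulationConfig:
    """Virtual population of singleton pregnant women aged 15-49.

    The base female population is spread uniformly over integer ages and
    carries a unimodal relative-fertility shape (Gaussian in age, mode
    ``age_mode``); per-age pregnancy probabilities are rescaled so the
    population-weighted mean equals ``overall_pregnancy_rate``.

    The maternal-age trisomy-21 risk curve is exponential in age,
    ``risk_offset + exp(b + risk_log_slope * age)`` with ``b`` solved so the
    unscaled curve reaches ``risk_cap`` at ``age_max``; after multiplication
    by ``prevalence_scale`` the curve is clipped to
    ``[risk_floor, risk_cap]``.
    """

    base_population_total: float = 1_878_000.0
    overall_pregnancy_rate: float = 0.0595
    age_min: int = 15
    age_max: int = 49
    age_mode: float = 29.0
    age_sd: float = 5.5
    entry_week: int = 10
    risk_floor: float = 0.0010
    risk_cap: float = 0.066
    risk_log_slope: float = 0.27726  # ln(2) / 2.5: risk doubles every ~2.5 y of age
    risk_offset: float = 0.0
    prevalence_scale: float = 1.0

    def validate(self) -> None:
        if self.base_population_total < 0:
            raise ValueError("base_population_total must be non-negative")
        _check_prob(self.overall_pregnancy_rate, "overall_pregnancy_rate")
        if not (self.age_min < self.age_max):
            raise ValueError("age_min must be below age_max")
        if not (0.0 < self.risk_floor <= self.risk_cap <= 1.0):
            raise ValueError("risk clipping bounds must satisfy 0 < floor <= cap <= 1")
        if self.prevalence_scale < 0:
            raise ValueError("prevalence_scale must be non-negative")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")


@dataclass
class NaturalHistoryConfig:
    """Weekly competing risks of pregnancy absent any intervention.

    ``ds_loss_anchors`` maps gestational week -> probability of spontaneous
    loss between that week and term, conditional on the pregnancy being
    ongoing at that week (trisomy-21-affected pregnancies).
    ``termination_total`` is the in-model cumulative probability of a
    voluntary induced abortion, split ``termination_t1_share`` /
    ``1 - termination_t1_share`` between the two trimester windows; it is a
    calibration knob because part of the program-wide 23% occurs before the
    model's entry week.
    """

    loss_total_unaffected: float = 0.135
    ds_loss_anchors: dict[int, float] = field(
        default_factory=lambda: {10: 0.36, 12: 0.30, 14: 0.25, 16: 0.21}
    )
    loss_decline_ratio: float = 0.76  # geometric weekly decline of the unaffected hazard
    termination_total: float = 0.23
    termination_t1_share: float = 0.90
    t1_window: tuple[int, int] = (10, 13)
    t2_window: tuple[int, int] = (14, 27)

    def validate(self) -> None:
        if not (0.0 <= self.loss_total_unaffected < 1.0):
            raise ValueError("loss_total_unaffected must lie in [0, 1)")
        if not (0.0 <= self.termination_total < 1.0):
            raise ValueError("termination_total must lie in [0, 1)")
        _check_prob(self.termination_t1_share, "termination_t1_share")
        if not (0.0 < self.loss_decline_ratio <= 1.0):
            raise ValueError("loss_decline_ratio must lie in (0, 1]")
        weeks = sorted(self.ds_loss_anchors)
        vals = [self.ds_loss_anchors[w] for w in weeks]
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("DS loss anchors must be strictly decreasing in week")
        for v in vals:
            _check_prob(v, "ds_loss_anchor")
        if self.t1_window[1] >= self.t2_window[0]:
            raise ValueError("termination windows must be disjoint and ordered")


@dataclass
class TestProfile:
    """Operating characteristics and unit cost of one screening test."""

    __test__ = False  # not a pytest collection target

    name: str
    detection_rate: float
    false_positive_rate: float
    failure_rate: float = 0.0
    unit_cost: float = 0.0

    def validate(self) -> None:
        _check_prob(self.detection_rate, f"{self.name}.detection_rate")
        _check_prob(self.false_positive_rate, f"{self.name}.false_positive_rate")
        _check_prob(self.failure_rate, f"{self.name}.failure_rate")
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}.unit_cost must be non-negative")
        if self.name == "amnio" and (
            self.detection_rate != 1.0 or self.false_positive_rate != 0.0
        ):
            raise ValueError("amniocentesis is modelled as a perfect diagnostic test")


@dataclass
class TestsConfig:
    __test__ = False  # not a pytest collection target

    sips: TestProfile = field(
        default_factory=lambda: TestProfile("sips", 0.85, 0.033, 0.0, 108.60)
    )
    nipt: TestProfile = field(
        default_factory=lambda: TestProfile("nipt", 0.999, 0.001, 0.02, 795.0)
    )
    amnio: TestProfile = field(
        default_factory=lambda: TestProfile("amnio", 1.0, 0.0, 0.0, 864.39)
    )

    def validate(self) -> None:
        for p in (self.sips, self.nipt, self.amnio):
            p.validate()


@dataclass
class CalendarConfig:
    """Gestational weeks of the pathway milestones.

    The confirmatory amniocentesis is performed in the same week the
    triggering positive result is returned (the program schedules it at 16
    weeks alongside the SIPS result); genetic counselling and the
    termination decision follow ``counselling_delay`` weeks after
    confirmation.
    """

    offer_week: int = 12  # screening offer + first serum sample
    sample2_week: int = 15  # quad-marker sample; the SIPS test is billed here
    sips_result_week: int = 16
    nipt_result_week: int = 17
    nipt_retest_week: int = 18
    nipt_retest_result_week: int = 19
    counselling_delay: int = 1

    def validate(self) -> None:
        seq = (
            self.offer_week,
            self.sample2_week,
            self.sips_result_week,
            self.nipt_result_week,
            self.nipt_retest_week,
            self.nipt_retest_result_week,
        )
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError("calendar weeks must be non-decreasing along the pathway")
        if self.counselling_delay < 0:
            raise ValueError("counselling_delay must be non-negative")


@dataclass
class StrategyConfig:
    """Uptakes, invasive-procedure risks and calendar shared by both arms.

    ``p_direct_invasive`` is only nonzero in the direct-choice scenario,
    where screen-positive women split three ways: direct amniocentesis
    (``p_direct_invasive``), NIPT (``uptake_nipt``), or no further testing.
    """

    uptake_screening: float = 0.50
    uptake_nipt: float = 0.90
    uptake_amnio: float = 0.90
    uptake_ds_termination: float = 0.90
    p_direct_invasive: float = 0.0
    amnio_loss_risk: float = 0.0011
    fluid_leak_risk: float = 0.01
    calendar: CalendarConfig = field(default_factory=CalendarConfig)

    def validate(self) -> None:
        for name in (
            "uptake_screening",
            "uptake_nipt",
            "uptake_amnio",
            "uptake_ds_termination",
            "p_direct_invasive",
            "amnio_loss_risk",
            "fluid_leak_risk",
        ):
            _check_prob(getattr(self, name), name)
        if self.p_direct_invasive + self.uptake_nipt > 1.0 + 1e-12:
            raise ValueError(
                "p_direct_invasive + uptake_nipt must not exceed 1 "
                "(the remainder declines further testing)"
            )
        self.calendar.validate()


@dataclass
class CostsConfig:
    """Non-test unit costs, CAD, fiscal year 2015-2016, undiscounted."""

    genetic_counselling: float = 138.636
    program_admin: float = 18.07  # per screening participant
    ds_termination: float = 1632.48
    procedure_loss: float = 2919.00
    fluid_leak_hospitalization: float = 2971.00

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"unit cost {f.name} must be non-negative")


@dataclass
class SimulationConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    natural_history: NaturalHistoryConfig = field(default_factory=NaturalHistoryConfig)
    tests: TestsConfig = field(default_factory=TestsConfig)
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    costs: CostsConfig = field(default_factory=CostsConfig)
    n_replicates: int = 1000
    master_seed: int = 2015
    cohort_sharing: str = "shared_per_replicate"  # or "independent_per_arm"

    def validate(self) -> "SimulationConfig":
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cohort_sharing not in ("shared_per_replicate", "independent_per_arm"):
            raise ValueError(f"unknown cohort_sharing mode {self.cohort_sharing!r}")
        self.population.validate()
        self.natural_history.validate()
        self.tests.validate()
        self.strategy.validate()
        self.costs.validate()
        return self

    def copy(self) -> "SimulationConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        # keys of ds_loss_anchors must survive YAML/JSON round trips as ints
        d["natural_history"]["ds_loss_anchors"] = {
            int(k): float(v)
            for k, v in d["natural_history"]["ds_loss_anchors"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        return _build_dataclass(cls, d).validate()


def _build_dataclass(klass, data):
    if not is_dataclass(klass):
        return data
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {klass.__name__}, got {type(data)}")
    known = {f.name: f for f in fields(klass)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown keys for {klass.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if name == "ds_loss_anchors":
            value = {int(k): float(v) for k, v in value.items()}
        elif name in ("t1_window", "t2_window"):
            value = tuple(int(v) for v in value)
        elif isinstance(value, dict) and isinstance(ftype, str):
            nested = _NESTED_TYPES.get(name)
            if nested is not None:
                value = _build_dataclass(nested, value)
        kwargs[name] = value
    return klass(**kwargs)


_NESTED_TYPES = {
    "population": PopulationConfig,
    "natural_history": NaturalHistoryConfig,
    "tests": TestsConfig,
    "strategy": StrategyConfig,
    "costs": CostsConfig,
    "calendar": CalendarConfig,
    "sips": TestProfile,
    "nipt": TestProfile,
    "amnio": TestProfile,
}


def default_config() -> SimulationConfig:
    """Baseline configuration: the published program parameters."""
    return SimulationConfig().validate()


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def get_by_path(cfg: SimulationConfig, path: str) -> Any:
    obj: Any = cfg
    for part in path.split("."):
        if not hasattr(obj, part):
            raise AttributeError(f"config path {path!r}: no attribute {part!r}")
        obj = getattr(obj, part)
    return obj


def set_by_path(cfg: SimulationConfig, path: str, value: Any) -> SimulationConfig:
    """Return a copy of ``cfg`` with the dotted-path parameter replaced."""
    new = cfg.copy()
    parts = path.split(".")
    obj: Any = new
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise AttributeError(f"config path {path!r}: no attribute {part!r}")
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise AttributeError(f"config path {path!r}: no attribute {parts[-1]!r}")
    setattr(obj, parts[-1], value)
    new.validate()
    return new
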