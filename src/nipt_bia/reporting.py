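"""Budget-impact aggregation, sensitivity scenarios and report serialization.

The budget-impact report mirrors the itemized comparison table: mean event
counts and costs per arm over replicates, per-item cost differences
(contingent minus current; negative = saving), the overall totals, and an
empirical-percentile confidence interval on the per-replicate overall
difference. The Methods-side "current minus contingent" saving is carried
as a labelled convenience field.

Univariate sensitivity scenarios rerun the full experiment with one
parameter replaced, sharing the master seed block (common random numbers)
so scenario deltas are driven by the parameter, not by resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, set_by_path
from .costs import COST_ITEMS
from .engine import ExperimentResult, ReplicateResult, run_experiment

__all__ = [
    "BIAReport",
    "ScenarioSpec",
    "build_bia_report",
    "run_univariate_sensitivity",
    "run_choice_scenario",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class ScenarioSpec:
    """One univariate sensitivity scenario: a dotted config path and value."""

    path: str
    value: float
    label: str


@dataclass
class BIAReport:
    """Itemized budget-impact comparison of the two strategies."""

    item_counts: dict[str, dict[str, float]]  # item -> arm -> mean count
    item_costs: dict[str, dict[str, float]]  # item -> arm -> mean cost
    overall: dict[str, float]  # arm -> mean total
    mean_difference: float  # contingent - current (negative = saving)
    ci: tuple[float, float]
    ci_level: float
    n_replicates: int
    savings_convention: str = (
        "difference = contingent - current; mean_saving = current - contingent"
    )
    mean_saving: float = field(init=False)

    def __post_init__(self):
        self.mean_saving = -self.mean_difference

    def item_difference(self, item: str) -> float:
        return self.item_costs[item]["contingent"] - self.item_costs[item]["current"]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for item in COST_ITEMS:
            rows.append(
                {
                    "item": item,
                    "count_current": self.item_counts[item]["current"],
                    "count_contingent": self.item_counts[item]["contingent"],
                    "cost_current": self.item_costs[item]["current"],
                    "cost_contingent": self.item_costs[item]["contingent"],
                    "difference": self.item_difference(item),
                }
            )
        rows.append(
            {
                "item": "overall",
                "count_current": np.nan,
                "count_contingent": np.nan,
                "cost_current": self.overall["current"],
                "cost_contingent": self.overall["contingent"],
                "difference": self.mean_difference,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "items": {
                item: {
                    "count_current": self.item_counts[item]["current"],
                    "count_contingent": self.item_counts[item]["contingent"],
                    "cost_current": self.item_costs[item]["current"],
                    "cost_contingent": self.item_costs[item]["contingent"],
                    "difference": self.item_difference(item),
                }
                for item in COST_ITEMS
            },
            "overall_current": self.overall["current"],
            "overall_contingent": self.overall["contingent"],
            "mean_difference": self.mean_difference,
            "mean_saving": self.mean_saving,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "ci_level": self.ci_level,
            "n_replicates": self.n_replicates,
            "savings_convention": self.savings_convention,
        }


def build_bia_report(
    pairs: ExperimentResult | list[ReplicateResult], ci_level: float = 0.95
) -> BIAReport:
    """Aggregate paired replicates into the budget-impact report.

    The confidence interval is the empirical percentile interval of the
    per-replicate overall cost difference; at least two replicates are
    required for it to exist.
    """
    reps = list(pairs)
    if len(reps) < 2:
        raise ValueError("a confidence interval requires at least 2 replicate pairs")
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must lie in (0, 1)")
    item_counts = {}
    item_costs = {}
    for item in COST_ITEMS:
        item_counts[item] = {
            arm: float(np.mean([getattr(r, arm).ledger.counts[item] for r in reps]))
            for arm in ("current", "contingent")
        }
        item_costs[item] = {
            arm: float(np.mean([getattr(r, arm).ledger.cost_sums[item] for r in reps]))
            for arm in ("current", "contingent")
        }
    overall = {
        arm: float(np.mean([getattr(r, arm).ledger.total for r in reps]))
        for arm in ("current", "contingent")
    }
    diffs = np.array([r.contingent.ledger.total - r.current.ledger.total for r in reps])
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(diffs, [100 * alpha, 100 * (1 - alpha)])
    return BIAReport(
        item_counts=item_counts,
        item_costs=item_costs,
        overall=overall,
        mean_difference=float(diffs.mean()),
        ci=(float(lo), float(hi)),
        ci_level=ci_level,
        n_replicates=len(reps),
    )


def run_univariate_sensitivity(
    cfg: SimulationConfig,
    scenarios: list[ScenarioSpec],
    reps: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One full experiment per scenario, all on the same master seed block.

    Returns a table with one row per scenario (the baseline first):
    label, parameter path, value, mean total per arm, mean difference.
    """
    rows = []
    specs = [ScenarioSpec("", float("nan"), "baseline")] + list(scenarios)
    for spec in specs:
        scen_cfg = cfg if spec.path == "" else set_by_path(cfg, spec.path, spec.value)
        report = build_bia_report(run_experiment(scen_cfg, reps, seed))
        rows.append(
            {
                "label": spec.label,
                "parameter": spec.path,
                "value": spec.value,
                "total_current": report.overall["current"],
                "total_contingent": report.overall["contingent"],
                "difference": report.mean_difference,
            }
        )
    return pd.DataFrame(rows)


def run_choice_scenario(
    cfg: SimulationConfig,
    p_direct: float,
    p_nipt: float,
    reps: int | None = None,
    seed: int | None = None,
) -> BIAReport:
    """Contingent arm with three-way routing of screen-positives:
    direct amniocentesis (``p_direct``), NIPT (``p_nipt``), or no further
    testing (the remainder)."""
    if not (0.0 <= p_direct <= 1.0 and 0.0 <= p_nipt <= 1.0):
        raise ValueError("routing probabilities must lie in [0, 1]")
    if p_direct + p_nipt > 1.0 + 1e-12:
        raise ValueError("p_direct + p_nipt must not exceed 1")
    scen = cfg.copy()
    scen.strategy.p_direct_invasive = p_direct
    scen.strategy.uptake_nipt = p_nipt
    scen.validate()
    return build_bia_report(run_experiment(scen, reps, seed))


def write_report(report, fmt: str, path: str | Path) -> Path:
    """Serialize a BIAReport or sensitivity table with bit-stable formatting
    (fixed column order, fixed float format) so equal-seed reruns diff clean."""
    path = Path(path)
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown report format {fmt!r}")
    try:
        if isinstance(report, BIAReport):
            if fmt == "csv":
                report.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
            else:
                path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        elif isinstance(report, pd.DataFrame):
            if fmt == "csv":
                report.to_csv(path, index=False, float_format=_FLOAT_FMT)
            else:
                path.write_text(report.to_json(orient="records", indent=2) + "\n")
        else:
            raise TypeError(f"cannot serialize report of type {type(report)}")
    except OSError as exc:
        raise OSError(f"failed writing report to {path}: {exc}") from exc
    return path


def read_report(path: str | Path) -> pd.DataFrame | dict:
    """Read back a serialized report (CSV -> DataFrame, JSON -> dict/list)."""
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    return json.loads(path.read_text())
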