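"""Itemized direct-cost accounting, public-payer perspective, CAD 2015-16.

Maps simulated event tallies (or raw event logs) to an eight-item cost
ledger mirroring the budget-impact table layout: SIPS tests, NIPT attempts
(first draws and retests billed at the same price), amniocenteses
(including karyotype), genetic counselling, procedure-related losses,
amniotic-fluid-leak hospitalizations, trisomy-21 terminations, and
per-participant program administration. No discounting anywhere (single
fiscal-year horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .config import CostsConfig, SimulationConfig
from .natural_history import EventRecord

__all__ = [
    "COST_ITEMS",
    "CostTable",
    "CostLedger",
    "load_cost_table",
    "cost_events",
    "cost_tallies",
    "merge_ledgers",
]

#: Fixed item order of every ledger and report.
COST_ITEMS = (
    "sips_test",
    "nipt_test",
    "amniocentesis",
    "genetic_counselling",
    "procedure_loss",
    "fluid_leak_hospitalization",
    "ds_termination",
    "program_admin",
)

#: Event-log kinds billed to each item (program_admin is billed per participant).
_EVENT_TO_ITEM = {
    "sips_test": "sips_test",
    "nipt_test": "nipt_test",
    "nipt_retest": "nipt_test",  # retests billed at full price
    "amniocentesis": "amniocentesis",
    "genetic_counselling": "genetic_counselling",
    "procedure_loss": "procedure_loss",
    "fluid_leak_hospitalization": "fluid_leak_hospitalization",
    "ds_termination": "ds_termination",
}

#: Event kinds that carry no direct cost.
_FREE_EVENTS = {"spontaneous_loss", "voluntary_termination", "live_birth", "admin"}


@dataclass(frozen=True)
class CostTable:
    """Unit costs (CAD) per billable item."""

    unit_costs: dict[str, float]

    def __post_init__(self):
        unknown = set(self.unit_costs) - set(COST_ITEMS)
        if unknown:
            raise ValueError(f"unknown cost item keys: {sorted(unknown)}")
        missing = set(COST_ITEMS) - set(self.unit_costs)
        if missing:
            raise ValueError(f"missing cost items: {sorted(missing)}")
        for k, v in self.unit_costs.items():
            if v < 0:
                raise ValueError(f"negative unit cost for {k}: {v}")

    def __getitem__(self, item: str) -> float:
        return self.unit_costs[item]


def load_cost_table(config: SimulationConfig | Mapping[str, float] | None = None) -> CostTable:
    """Assemble the cost table from a simulation config (test unit costs come
    from the test profiles; the remaining items from the costs block), or
    from an explicit item -> cost mapping, or the defaults."""
    if config is None:
        config = SimulationConfig()
    if isinstance(config, SimulationConfig):
        c: CostsConfig = config.costs
        units = {
            "sips_test": config.tests.sips.unit_cost,
            "nipt_test": config.tests.nipt.unit_cost,
            "amniocentesis": config.tests.amnio.unit_cost,
            "genetic_counselling": c.genetic_counselling,
            "procedure_loss": c.procedure_loss,
            "fluid_leak_hospitalization": c.fluid_leak_hospitalization,
            "ds_termination": c.ds_termination,
            "program_admin": c.program_admin,
        }
        return CostTable(units)
    return CostTable(dict(config))


@dataclass
class CostLedger:
    """Itemized event counts and cost sums for one simulated arm.

    Counts may be fractional when the ledger is a mean over replicates.
    """

    counts: dict[str, float] = field(default_factory=lambda: {k: 0.0 for k in COST_ITEMS})
    cost_sums: dict[str, float] = field(default_factory=lambda: {k: 0.0 for k in COST_ITEMS})

    @property
    def total(self) -> float:
        return float(sum(self.cost_sums.values()))

    def check(self, table: CostTable | None = None, tol: float = 1e-6) -> None:
        """Internal consistency: total additivity and, with a table,
        per-item count x unit-cost identity."""
        if table is not None:
            for item in COST_ITEMS:
                expected = self.counts[item] * table[item]
                if abs(self.cost_sums[item] - expected) > tol * max(1.0, abs(expected)):
                    raise AssertionError(f"ledger item {item} violates count x unit cost")

    def items(self) -> Iterable[tuple[str, float, float]]:
        for item in COST_ITEMS:
            yield item, self.counts[item], self.cost_sums[item]


def cost_tallies(tallies: Mapping[str, float], table: CostTable) -> CostLedger:
    """Ledger from an arm's summary tallies (the vectorized-engine path).

    Expected tally keys: ``participants`` (bills one SIPS test and one
    program-admin fee each), ``nipt_attempts``, ``amniocenteses``,
    ``counselling``, ``procedure_losses``, ``fluid_leaks``,
    ``ds_terminations``.
    """
    counts = {
        "sips_test": float(tallies.get("participants", 0)),
        "nipt_test": float(tallies.get("nipt_attempts", 0)),
        "amniocentesis": float(tallies.get("amniocenteses", 0)),
        "genetic_counselling": float(tallies.get("counselling", 0)),
        "procedure_loss": float(tallies.get("procedure_losses", 0)),
        "fluid_leak_hospitalization": float(tallies.get("fluid_leaks", 0)),
        "ds_termination": float(tallies.get("ds_terminations", 0)),
        "program_admin": float(tallies.get("participants", 0)),
    }
    sums = {k: counts[k] * table[k] for k in COST_ITEMS}
    return CostLedger(counts=counts, cost_sums=sums)


def cost_events(
    events: Iterable[EventRecord],
    table: CostTable,
    participants: int,
) -> CostLedger:
    """Ledger from a raw event log of one simulated arm.

    Bills each SIPS completion, each NIPT attempt (first draw and retest),
    each amniocentesis, counselling session, trisomy-21 termination,
    procedure loss and leak hospitalization, plus the program administration
    fee once per screening participant.
    """
    if participants < 0:
        raise ValueError("participants must be non-negative")
    counts = {k: 0.0 for k in COST_ITEMS}
    for ev in events:
        if ev.kind in _FREE_EVENTS:
            continue
        item = _EVENT_TO_ITEM.get(ev.kind)
        if item is None:
            raise KeyError(f"event kind {ev.kind!r} missing from the cost table mapping")
        counts[item] += 1.0
    counts["program_admin"] = float(participants)
    sums = {k: counts[k] * table[k] for k in COST_ITEMS}
    return CostLedger(counts=counts, cost_sums=sums)


def merge_ledgers(ledgers: list[CostLedger], mode: str = "mean") -> CostLedger:
    """Itemwise sum or mean of ledgers; mean mode may produce fractional
    counts (replicate averages)."""
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown merge mode {mode!r}")
    if not ledgers:
        raise ValueError("no ledgers to merge")
    keys = set(ledgers[0].counts)
    for led in ledgers[1:]:
        if set(led.counts) != keys:
            raise ValueError("mismatched item sets")
    denom = len(ledgers) if mode == "mean" else 1
    counts = {k: sum(l.counts[k] for l in ledgers) / denom for k in ledgers[0].counts}
    sums = {k: sum(l.cost_sums[k] for l in ledgers) / denom for k in ledgers[0].cost_sums}
    return CostLedger(counts=counts, cost_sums=sums)
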