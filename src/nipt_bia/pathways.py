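"""The two screening strategy state machines, at the level of one woman.

Current practice: serum integrated screening (SIPS) -> amniocentesis for
screen-positives. Contingent strategy: SIPS -> NIPT for screen-positives ->
amniocentesis for NIPT-positives (with one retest after an NIPT no-call; a
second no-call ends testing). A direct-choice variant routes a fraction of
screen-positives straight to amniocentesis.

The biochemical risk computation behind the program's 1-in-300 cutoff is
abstracted into detection-rate / false-positive-rate Bernoulli outcomes by
fetal status. Amniocentesis is a perfect diagnostic carrying independent
procedure-loss and amniotic-fluid-leak risks. Confirmed trisomy-21
pregnancies receive genetic counselling and terminate with the configured
uptake; screen-negatives, decliners and NIPT-negatives revert to the
natural course of pregnancy.

These per-woman operations are the reference semantics; the vectorized
engine in :mod:`nipt_bia.engine` implements the same pathway over whole
cohorts at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Woman
from .config import StrategyConfig, TestProfile, TestsConfig
from .natural_history import EventRecord

__all__ = [
    "ScreenOutcome",
    "offer_screening",
    "run_sips",
    "run_nipt",
    "run_amniocentesis",
    "step_pathway",
    "milestone_weeks",
]


@dataclass(frozen=True)
class ScreenOutcome:
    result: str  # positive | negative | failed_twice | declined
    attempts: int = 1

    def __post_init__(self):
        if self.result not in ("positive", "negative", "failed_twice", "declined"):
            raise ValueError(f"unknown screen result {self.result!r}")
        if self.attempts not in (1, 2):
            raise ValueError("attempts must be 1 or 2")


def offer_screening(woman: Woman, uptake: float, rng: np.random.Generator) -> bool:
    """Bernoulli acceptance of the screening offer; decliners follow the
    natural course of pregnancy."""
    if not woman.ongoing:
        raise ValueError("screening offered to a non-ongoing pregnancy")
    return bool(rng.random() < uptake)


def _bernoulli_result(ds_affected: bool, profile: TestProfile, rng) -> str:
    p = profile.detection_rate if ds_affected else profile.false_positive_rate
    return "positive" if rng.random() < p else "negative"


def run_sips(woman: Woman, profile: TestProfile, rng: np.random.Generator) -> ScreenOutcome:
    """Resolve the SIPS result: positive with probability ``detection_rate``
    for an affected fetus, ``false_positive_rate`` otherwise (the 1/300 risk
    cutoff is folded into these rates)."""
    if not woman.ongoing:
        raise ValueError("run_sips called after a terminal pregnancy state")
    return ScreenOutcome(_bernoulli_result(woman.ds_affected, profile, rng), attempts=1)


def run_nipt(woman: Woman, profile: TestProfile, rng: np.random.Generator) -> ScreenOutcome:
    """Resolve NIPT with up to one retest after a no-call.

    Every attempt is billed; a second no-call returns ``failed_twice``
    (no further testing downstream).
    """
    attempts = 1
    if rng.random() < profile.failure_rate:
        attempts = 2
        if rng.random() < profile.failure_rate:
            return ScreenOutcome("failed_twice", attempts=2)
    return ScreenOutcome(_bernoulli_result(woman.ds_affected, profile, rng), attempts=attempts)


def run_amniocentesis(
    woman: Woman, cfg: StrategyConfig, rng: np.random.Generator
) -> list[EventRecord]:
    """Perform amniocentesis at the woman's current week.

    Emits the procedure event; samples procedure-related fetal loss (which
    ends the pregnancy and pre-empts any diagnosis) and amniotic-fluid-leak
    hospitalization as independent Bernoullis. Absent a procedure loss the
    diagnosis equals the true fetal status (perfect test) and a confirmed
    trisomy-21 pregnancy is flagged for counselling.
    """
    if not woman.ongoing:
        raise ValueError("amniocentesis on a non-ongoing pregnancy")
    week = woman.current_week
    lost = rng.random() < cfg.amnio_loss_risk
    leak = rng.random() < cfg.fluid_leak_risk
    if lost:
        payload = None  # the loss pre-empts the diagnosis
    else:
        payload = "ds_confirmed" if woman.ds_affected else "no_ds"
    records = [EventRecord(week, "amniocentesis", payload=payload)]
    if leak:
        records.append(EventRecord(week, "fluid_leak_hospitalization"))
    if lost:
        woman.set_terminal("procedure_loss")
        records.append(EventRecord(week, "procedure_loss"))
        woman.pathway_state = "closed"
    elif woman.ds_affected:
        woman.pathway_state = "confirmed"
        woman.confirmed_week = week
    else:
        woman.pathway_state = "closed"
    return records


def milestone_weeks(cfg: StrategyConfig, strategy: str) -> set[int]:
    """Weeks at which :func:`step_pathway` may act for a given strategy."""
    cal = cfg.calendar
    weeks = {
        cal.offer_week,
        cal.sample2_week,
        cal.sips_result_week,
        cal.sips_result_week + cfg.calendar.counselling_delay,
    }
    if strategy in ("contingent", "contingent_with_choice"):
        weeks |= {
            cal.nipt_result_week,
            cal.nipt_retest_week,
            cal.nipt_retest_result_week,
            cal.nipt_result_week + cal.counselling_delay,
            cal.nipt_retest_result_week + cal.counselling_delay,
        }
    return weeks


def step_pathway(
    woman: Woman,
    cfg: StrategyConfig,
    tests: TestsConfig,
    week: int,
    rng: np.random.Generator,
    strategy: str = "current",
) -> list[EventRecord]:
    """Execute the pathway milestone scheduled at ``week`` for one woman.

    Dispatches on ``(strategy, woman.pathway_state, week)``; advances the
    pathway state and returns the billed/logged events. Must be called at
    most once per (woman, milestone).
    """
    if strategy not in ("current", "contingent", "contingent_with_choice"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if not woman.ongoing:
        return []
    cal = cfg.calendar
    key = (week, woman.pathway_state)
    if key in woman.milestones_done:
        raise ValueError(f"milestone {key} executed twice for woman {woman.id}")
    records: list[EventRecord] = []

    def done():
        woman.milestones_done.add(key)

    state = woman.pathway_state

    if week == cal.offer_week and state == "start":
        woman.accepted_offer = offer_screening(woman, cfg.uptake_screening, rng)
        woman.pathway_state = "awaiting_sample2" if woman.accepted_offer else "closed"
        done()
    elif week == cal.sample2_week and state == "awaiting_sample2":
        records.append(EventRecord(week, "sips_test"))
        woman.pathway_state = "awaiting_result"
        done()
    elif week == cal.sips_result_week and state == "awaiting_result":
        outcome = run_sips(woman, tests.sips, rng)
        woman.screen_positive = outcome.result == "positive"
        if not woman.screen_positive:
            woman.pathway_state = "closed"
        else:
            records += _route_positive(woman, cfg, tests, rng, strategy)
        done()
    elif (
        strategy != "current"
        and week == cal.nipt_result_week
        and state == "nipt_pending"
    ):
        if rng.random() < tests.nipt.failure_rate:
            woman.pathway_state = "nipt_retest_due"
        else:
            records += _resolve_nipt_result(woman, cfg, tests, rng)
        done()
    elif (
        strategy != "current"
        and week == cal.nipt_retest_week
        and state == "nipt_retest_due"
    ):
        records.append(EventRecord(week, "nipt_retest"))
        woman.pathway_state = "nipt_retest_pending"
        done()
    elif (
        strategy != "current"
        and week == cal.nipt_retest_result_week
        and state == "nipt_retest_pending"
    ):
        if rng.random() < tests.nipt.failure_rate:
            # second no-call: no further testing
            woman.pathway_state = "closed"
        else:
            records += _resolve_nipt_result(woman, cfg, tests, rng)
        done()
    elif state == "confirmed" and woman.confirmed_week is not None and week == (
        woman.confirmed_week + cal.counselling_delay
    ):
        records.append(EventRecord(week, "genetic_counselling"))
        if rng.random() < cfg.uptake_ds_termination:
            woman.set_terminal("ds_termination")
            records.append(EventRecord(week, "ds_termination"))
        woman.pathway_state = "closed"
        done()
    return records


def _route_positive(woman, cfg, tests, rng, strategy) -> list[EventRecord]:
    """Route a screen-positive woman at the SIPS result week."""
    if strategy == "current":
        if rng.random() < cfg.uptake_amnio:
            return run_amniocentesis(woman, cfg, rng)
        woman.pathway_state = "closed"
        return []
    u = rng.random()
    if u < cfg.p_direct_invasive:
        if rng.random() < cfg.uptake_amnio:
            return run_amniocentesis(woman, cfg, rng)
        woman.pathway_state = "closed"
        return []
    if u < cfg.p_direct_invasive + cfg.uptake_nipt:
        woman.pathway_state = "nipt_pending"
        return [EventRecord(woman.current_week, "nipt_test")]
    woman.pathway_state = "closed"
    return []


def _resolve_nipt_result(woman, cfg, tests, rng) -> list[EventRecord]:
    result = _bernoulli_result(woman.ds_affected, tests.nipt, rng)
    if result == "positive":
        if rng.random() < cfg.uptake_amnio:
            return run_amniocentesis(woman, cfg, rng)
    woman.pathway_state = "closed"
    return []
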