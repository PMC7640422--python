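"""Replicated weekly microsimulation of both screening strategies.

One replicate draws a fresh virtual cohort, samples each woman's natural
history (first spontaneous-loss week and first voluntary-termination week,
competing with spontaneous loss taking within-week precedence), then
resolves the strategy pathway on the milestone calendar. Both arms of a
replicate consume the same cohort and the same pre-drawn uniforms (common
random numbers), so cost differences reflect the strategies, not sampling
noise.

The simulation is vectorized: pathway logic is boolean-mask algebra over
the cohort arrays, which makes a ~112k-agent replicate run in tens of
milliseconds. An agent-based reference path built on the per-woman
operations in :mod:`nipt_bia.pathways` is provided for cross-validation.

``calibrate`` pins four under-determined knobs to printed program
aggregates by sequential one-dimensional root finding on simulated means
over a fixed seed block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cohort import PregnancyCohort, build_age_risk_curve, build_fertility_schedule, generate_cohort
from .config import SimulationConfig
from .costs import CostLedger, cost_events, cost_tallies, load_cost_table
from .natural_history import (
    NO_EVENT_WEEK,
    TERM_WEEK,
    advance_week,
    sample_event_week,
    schedules_from_config,
)
from .pathways import milestone_weeks, step_pathway

__all__ = [
    "ArmResult",
    "ReplicateResult",
    "ExperimentResult",
    "CalibrationAnchors",
    "CalibrationRecord",
    "simulate_replicate",
    "simulate_replicate_agents",
    "run_experiment",
    "calibrate",
    "build_population",
]

ARMS = ("current", "contingent")

TALLY_KEYS = (
    "cohort_size",
    "pre_offer_exits",
    "decliners",
    "accepted_offer",
    "participants",
    "screen_positives",
    "nipt_women",
    "nipt_attempts",
    "nipt_failed_twice",
    "amniocenteses",
    "procedure_losses",
    "fluid_leaks",
    "confirmed_ds",
    "counselling",
    "ds_terminations",
    "spontaneous_losses",
    "voluntary_terminations",
    "live_births",
)


@dataclass
class ArmResult:
    """Tallies and itemized cost ledger of one arm of one replicate."""

    arm: str
    tallies: dict[str, int]
    ledger: CostLedger

    def check(self) -> None:
        t = self.tallies
        terminal = (
            t["spontaneous_losses"]
            + t["voluntary_terminations"]
            + t["procedure_losses"]
            + t["ds_terminations"]
            + t["live_births"]
        )
        if terminal != t["cohort_size"]:
            raise AssertionError("terminal states do not partition the cohort")
        if t["pre_offer_exits"] + t["decliners"] + t["accepted_offer"] != t["cohort_size"]:
            raise AssertionError("offer partition does not cover the cohort")
        if t["confirmed_ds"] > t["amniocenteses"]:
            raise AssertionError("confirmed DS exceeds amniocenteses")
        if t["counselling"] > t["confirmed_ds"]:
            raise AssertionError("counselling exceeds confirmed DS")
        if t["ds_terminations"] > t["counselling"]:
            raise AssertionError("terminations exceed counselling")


@dataclass
class ReplicateResult:
    index: int
    cohort_size: int
    current: ArmResult
    contingent: ArmResult


@dataclass
class ExperimentResult:
    replicates: list[ReplicateResult]

    def __iter__(self):
        return iter(self.replicates)

    def __len__(self):
        return len(self.replicates)

    @property
    def cohort_sizes(self) -> np.ndarray:
        return np.array([r.cohort_size for r in self.replicates])


def build_population(cfg: SimulationConfig):
    """Fertility schedule and risk curve implied by the population block."""
    pop = cfg.population
    fertility = build_fertility_schedule(
        pop.overall_pregnancy_rate, pop.base_population_total, params=pop
    )
    risk = build_age_risk_curve(pop)
    return fertility, risk


def _draw_cohort(cfg: SimulationConfig, seed) -> PregnancyCohort:
    fertility, risk = build_population(cfg)
    return generate_cohort(fertility, risk, cfg.population.entry_week, seed)


# ---------------------------------------------------------------------------
# vectorized replicate
# ---------------------------------------------------------------------------

def _child(ss: np.random.SeedSequence, key: int) -> np.random.SeedSequence:
    """Stateless child seed: same (parent, key) always maps to the same
    stream, so arms and repeated evaluations sharing a parent share draws."""
    return np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (key,))


_UNIFORM_BLOCKS = (
    "offer",
    "sips",
    "route",
    "fail1",
    "fail2",
    "nres1",
    "nres2",
    "amnio",
    "ploss",
    "leak",
    "term",
)


def _natural_history_weeks(cfg, cohort, rng):
    """First-event weeks of the two natural-history processes, per woman."""
    losses, terminations = schedules_from_config(
        cfg.natural_history, cfg.population.entry_week
    )
    n = cohort.n
    u_loss = rng.random(n)
    u_via = rng.random(n)
    t_loss_u = sample_event_week(losses.hazard_unaffected, losses.weeks, u_loss)
    t_loss_d = sample_event_week(losses.hazard_ds, losses.weeks, u_loss)
    t_loss = np.where(cohort.ds_affected, t_loss_d, t_loss_u)
    t_via = sample_event_week(terminations.hazard, terminations.weeks, u_via)
    return t_loss, t_via


def simulate_replicate(
    cfg: SimulationConfig,
    arm: str,
    cohort: PregnancyCohort,
    seed: int | np.random.SeedSequence,
) -> ArmResult:
    """Simulate one arm over one cohort; deterministic given (cfg, cohort, seed).

    Running both arms with the same seed shares every natural-history and
    decision uniform, so quantities upstream of the pathway divergence
    (SIPS participation, screen results) are bit-identical across arms.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    cfg.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    nat_ss, path_ss = _child(ss, 0), _child(ss, 1)
    t_loss, t_via = _natural_history_weeks(cfg, cohort, np.random.default_rng(nat_ss))
    n = cohort.n
    ds = cohort.ds_affected
    rng = np.random.default_rng(path_ss)
    u = {name: rng.random(n) for name in _UNIFORM_BLOCKS}

    st = cfg.strategy
    cal = st.calendar
    sips = cfg.tests.sips
    nipt = cfg.tests.nipt

    t_nat = np.minimum(t_loss, t_via)

    def alive(week):
        # True if no natural event occurred in weeks entry..week
        return t_nat > week

    offered = alive(cal.offer_week)
    accepted = offered & (u["offer"] < st.uptake_screening)
    participant = accepted & alive(cal.sample2_week)
    pos_draw = np.where(
        ds, u["sips"] < sips.detection_rate, u["sips"] < sips.false_positive_rate
    )
    positive = participant & pos_draw
    rw = cal.sips_result_week
    actionable = positive & alive(rw)

    amnio_week = np.full(n, NO_EVENT_WEEK, dtype=np.int64)
    nipt_attempt1 = np.zeros(n, dtype=bool)
    nipt_retest = np.zeros(n, dtype=bool)
    failed_twice = np.zeros(n, dtype=bool)

    if arm == "current":
        amnio = actionable & (u["amnio"] < st.uptake_amnio)
        amnio_week[amnio] = rw
    else:
        p_direct = st.p_direct_invasive
        direct = actionable & (u["route"] < p_direct)
        nipt_routed = actionable & ~direct & (u["route"] < p_direct + st.uptake_nipt)

        amnio_direct = direct & (u["amnio"] < st.uptake_amnio)
        amnio_week[amnio_direct] = rw

        nipt_attempt1 = nipt_routed
        fail1 = nipt_attempt1 & (u["fail1"] < nipt.failure_rate)
        res1 = nipt_attempt1 & ~fail1
        pos1 = res1 & np.where(
            ds, u["nres1"] < nipt.detection_rate, u["nres1"] < nipt.false_positive_rate
        )
        amnio1 = pos1 & alive(cal.nipt_result_week) & (u["amnio"] < st.uptake_amnio)
        amnio_week[amnio1] = cal.nipt_result_week

        nipt_retest = fail1 & alive(cal.nipt_retest_week)
        failed_twice = nipt_retest & (u["fail2"] < nipt.failure_rate)
        res2 = nipt_retest & ~failed_twice
        pos2 = res2 & np.where(
            ds, u["nres2"] < nipt.detection_rate, u["nres2"] < nipt.false_positive_rate
        )
        amnio2 = (
            pos2 & alive(cal.nipt_retest_result_week) & (u["amnio"] < st.uptake_amnio)
        )
        amnio_week[amnio2] = cal.nipt_retest_result_week

        amnio = amnio_direct | amnio1 | amnio2

    ploss = amnio & (u["ploss"] < st.amnio_loss_risk)
    leak = amnio & (u["leak"] < st.fluid_leak_risk)
    confirmed = amnio & ds & ~ploss
    couns_week = amnio_week + cal.counselling_delay
    counselled = confirmed & (t_nat > couns_week)
    terminated = counselled & (u["term"] < st.uptake_ds_termination)

    natural = ~(ploss | terminated)
    nat_event = natural & (t_nat < NO_EVENT_WEEK)
    spont = nat_event & (t_loss <= t_via)
    via = nat_event & ~(t_loss <= t_via)
    births = natural & (t_nat == NO_EVENT_WEEK)

    tallies = {
        "cohort_size": n,
        "pre_offer_exits": int(np.sum(~offered)),
        "decliners": int(np.sum(offered & ~accepted)),
        "accepted_offer": int(np.sum(accepted)),
        "participants": int(np.sum(participant)),
        "screen_positives": int(np.sum(actionable)),
        "nipt_women": int(np.sum(nipt_attempt1)),
        "nipt_attempts": int(np.sum(nipt_attempt1) + np.sum(nipt_retest)),
        "nipt_failed_twice": int(np.sum(failed_twice)),
        "amniocenteses": int(np.sum(amnio)),
        "procedure_losses": int(np.sum(ploss)),
        "fluid_leaks": int(np.sum(leak)),
        "confirmed_ds": int(np.sum(confirmed)),
        "counselling": int(np.sum(counselled)),
        "ds_terminations": int(np.sum(terminated)),
        "spontaneous_losses": int(np.sum(spont)),
        "voluntary_terminations": int(np.sum(via)),
        "live_births": int(np.sum(births)),
    }
    ledger = cost_tallies(tallies, load_cost_table(cfg))
    result = ArmResult(arm=arm, tallies=tallies, ledger=ledger)
    result.check()
    return result


# ---------------------------------------------------------------------------
# agent-based reference replicate (per-woman operations)
# ---------------------------------------------------------------------------


def simulate_replicate_agents(
    cfg: SimulationConfig,
    arm: str,
    cohort: PregnancyCohort,
    seed: int | np.random.SeedSequence,
) -> ArmResult:
    """Reference implementation: loop each woman through weekly cycles using
    the per-woman natural-history and pathway operations.

    Statistically equivalent to :func:`simulate_replicate` (same weekly
    semantics, different random-number consumption order); used for
    cross-validation and for small illustrative runs with full event logs.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    cfg.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    losses, terminations = schedules_from_config(
        cfg.natural_history, cfg.population.entry_week
    )
    strategy = "current" if arm == "current" else (
        "contingent_with_choice" if cfg.strategy.p_direct_invasive > 0 else "contingent"
    )
    mw = milestone_weeks(cfg.strategy, strategy)
    all_events = []
    tallies = {k: 0 for k in TALLY_KEYS}
    tallies["cohort_size"] = cohort.n
    delay = cfg.strategy.calendar.counselling_delay

    for woman in cohort.to_women():
        events = []
        while woman.ongoing:
            week = woman.current_week
            rec = advance_week(woman, losses, terminations, rng)
            if rec is not None:
                events.append(rec)
                break
            # survived this week's natural-history draws; the week's
            # milestones run now (losses precede appointments within a week)
            woman.current_week = week
            if week in mw or (
                woman.pathway_state == "confirmed"
                and woman.confirmed_week is not None
                and week == woman.confirmed_week + delay
            ):
                events.extend(
                    step_pathway(woman, cfg.strategy, cfg.tests, week, rng, strategy)
                )
            if not woman.ongoing:
                break
            woman.current_week = week + 1
        all_events.extend(events)
        _tally_agent(tallies, woman, events)

    ledger = cost_events(all_events, load_cost_table(cfg), tallies["participants"])
    result = ArmResult(arm=arm, tallies=tallies, ledger=ledger)
    result.check()
    return result


def _tally_agent(t, woman, events):
    kinds = [e.kind for e in events]
    state = woman.pregnancy_state
    t["spontaneous_losses"] += state == "spontaneous_loss"
    t["voluntary_terminations"] += state == "voluntary_termination"
    t["procedure_losses"] += state == "procedure_loss"
    t["ds_terminations"] += state == "ds_termination"
    t["live_births"] += state == "live_birth"
    if woman.accepted_offer is None:
        t["pre_offer_exits"] += 1
    elif woman.accepted_offer:
        t["accepted_offer"] += 1
    else:
        t["decliners"] += 1
    t["participants"] += "sips_test" in kinds
    t["screen_positives"] += bool(woman.screen_positive)
    t["nipt_women"] += "nipt_test" in kinds
    t["nipt_attempts"] += kinds.count("nipt_test") + kinds.count("nipt_retest")
    t["amniocenteses"] += "amniocentesis" in kinds
    t["confirmed_ds"] += any(
        e.kind == "amniocentesis" and e.payload == "ds_confirmed" for e in events
    )
    t["counselling"] += "genetic_counselling" in kinds
    t["fluid_leaks"] += "fluid_leak_hospitalization" in kinds


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def run_experiment(
    cfg: SimulationConfig,
    n_replicates: int | None = None,
    master_seed: int | None = None,
) -> ExperimentResult:
    """Run paired current/contingent replicates.

    Each replicate draws a fresh cohort from its own seed sub-stream. Under
    the default ``shared_per_replicate`` mode both arms consume the same
    cohort and the same decision uniforms; ``independent_per_arm`` gives
    each arm its own cohort and draws (higher-variance differences).
    """
    cfg.validate()
    n_reps = cfg.n_replicates if n_replicates is None else int(n_replicates)
    seed = cfg.master_seed if master_seed is None else int(master_seed)
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_reps)
    replicates = []
    shared = cfg.cohort_sharing == "shared_per_replicate"
    for i, rep_ss in enumerate(rep_seeds):
        if shared:
            cohort_ss, sim_ss = _child(rep_ss, 0), _child(rep_ss, 1)
            cohort = _draw_cohort(cfg, cohort_ss)
            cur = simulate_replicate(cfg, "current", cohort, sim_ss)
            con = simulate_replicate(cfg, "contingent", cohort, sim_ss)
            size = cohort.n
        else:
            ss_a, ss_b = _child(rep_ss, 0), _child(rep_ss, 1)
            cohort_a = _draw_cohort(cfg, _child(ss_a, 0))
            cur = simulate_replicate(cfg, "current", cohort_a, _child(ss_a, 1))
            cohort_b = _draw_cohort(cfg, _child(ss_b, 0))
            con = simulate_replicate(cfg, "contingent", cohort_b, _child(ss_b, 1))
            size = cohort_a.n
        replicates.append(
            ReplicateResult(index=i, cohort_size=size, current=cur, contingent=con)
        )
    return ExperimentResult(replicates=replicates)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationAnchors:
    """Printed program aggregates the free knobs are pinned to."""

    pregnancies: float = 111_752.0
    participants: float = 41_904.0
    amnios_current: float = 1_773.0
    confirmed_ds_current: float = 114.0
    rel_tolerance: float = 0.02
    n_replicates: int = 48

    def validate(self):
        for name in ("pregnancies", "participants", "amnios_current", "confirmed_ds_current"):
            if getattr(self, name) <= 0:
                raise ValueError(f"anchor {name} must be positive")
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be positive")


@dataclass
class CalibrationRecord:
    knobs: dict[str, float] = field(default_factory=dict)
    achieved: dict[str, float] = field(default_factory=dict)


def _mean_current_tallies(cfg: SimulationConfig, seeds, keys):
    sums = {k: 0.0 for k in keys}
    for rep_ss in seeds:
        cohort_ss, sim_ss = _child(rep_ss, 0), _child(rep_ss, 1)
        cohort = _draw_cohort(cfg, cohort_ss)
        res = simulate_replicate(cfg, "current", cohort, sim_ss)
        for k in keys:
            sums[k] += res.tallies[k]
    return {k: v / len(seeds) for k, v in sums.items()}


def calibrate(
    cfg: SimulationConfig, anchors: CalibrationAnchors | None = None
) -> tuple[SimulationConfig, CalibrationRecord]:
    """Pin the four free knobs to the printed anchors, in order:

    1. base-population scale -> mean pregnancies (closed form: the expected
       cohort size is exactly rate x base population);
    2. effective in-model voluntary-termination total (pre-screening
       attrition) -> mean SIPS participants;
    3. maternal-age risk prevalence scale -> mean confirmed-DS counselling
       in the current arm;
    4. effective SIPS false-positive rate -> mean current-arm amniocenteses.

    Knobs 2-4 use monotone one-dimensional root finding (brentq) on the
    simulated current-arm mean over a fixed block of replicate seeds
    (common random numbers across evaluations). Raises if no root lies
    within the knob's bounds, naming the anchor.
    """
    anchors = anchors or CalibrationAnchors()
    anchors.validate()
    cfg = cfg.copy()
    cfg.validate()
    record = CalibrationRecord()

    # (1) base population: E[cohort size] = overall_rate x base_total exactly
    cfg.population.base_population_total = (
        anchors.pregnancies / cfg.population.overall_pregnancy_rate
    )
    record.knobs["population.base_population_total"] = cfg.population.base_population_total
    record.achieved["pregnancies"] = (
        cfg.population.base_population_total * cfg.population.overall_pregnancy_rate
    )

    # fixed seed block shared by every evaluation of every knob
    cal_ss = np.random.SeedSequence([int(cfg.master_seed) % (2**31), 909])
    seeds = cal_ss.spawn(anchors.n_replicates)

    def solve(path, target, tally_key, lo, hi, anchor_name):
        def f(x):
            trial = cfg.copy()
            _set(trial, path, x)
            trial.validate()
            mean = _mean_current_tallies(trial, seeds, (tally_key,))[tally_key]
            return mean - target

        f_lo, f_hi = f(lo), f(hi)
        if f_lo == 0:
            root = lo
        elif f_hi == 0:
            root = hi
        elif np.sign(f_lo) == np.sign(f_hi):
            raise ValueError(
                f"calibration: no root within bounds [{lo}, {hi}] for anchor "
                f"{anchor_name!r} (f(lo)={f_lo:.1f}, f(hi)={f_hi:.1f})"
            )
        else:
            root = brentq(f, lo, hi, xtol=1e-6, rtol=1e-4)
        _set(cfg, path, float(root))
        record.knobs[path] = float(root)
        achieved = _mean_current_tallies(cfg, seeds, (tally_key,))[tally_key]
        record.achieved[anchor_name] = achieved
        rel = abs(achieved - target) / target
        if rel > anchors.rel_tolerance:
            raise ValueError(
                f"calibration for anchor {anchor_name!r} converged to a point "
                f"{rel:.1%} away from the target"
            )

    solve(
        "natural_history.termination_total",
        anchors.participants,
        "participants",
        0.0,
        0.45,
        "participants",
    )
    solve(
        "population.prevalence_scale",
        anchors.confirmed_ds_current,
        "counselling",
        0.02,
        80.0,
        "confirmed_ds_current",
    )
    solve(
        "tests.sips.false_positive_rate",
        anchors.amnios_current,
        "amniocenteses",
        0.0,
        0.15,
        "amnios_current",
    )
    cfg.validate()
    return cfg, record


def _set(cfg, path, value):
    obj = cfg
    parts = path.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    setattr(obj, parts[-1], value)
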