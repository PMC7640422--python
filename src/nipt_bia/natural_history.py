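"""Weekly natural history of pregnancy: spontaneous loss and voluntary termination.

Two competing weekly hazards act on every ongoing pregnancy, independent of
any screening activity:

* spontaneous fetal loss, with a status-specific schedule. Unaffected
  pregnancies carry a front-loaded (geometrically declining) hazard scaled
  to a configured cumulative loss from model entry to term. Trisomy-21
  pregnancies instead follow published conditional anchors — the
  probability of losing the pregnancy between week ``w`` and term, given it
  is ongoing at ``w`` — interpolated log-linearly in survival between
  anchor weeks and flattened to a constant hazard thereafter;
* voluntary induced abortion, with a uniform weekly hazard within each
  trimester window solving the window's share of the cumulative total.

Within a week the spontaneous-loss draw precedes the voluntary-termination
draw, and both precede any scheduled screening milestone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Woman
from .config import NaturalHistoryConfig

__all__ = [
    "EventRecord",
    "LossSchedule",
    "TerminationSchedule",
    "build_loss_schedule",
    "build_termination_schedule",
    "advance_week",
    "sample_event_week",
    "NO_EVENT_WEEK",
    "EVENT_KINDS",
    "TERM_WEEK",
]

#: Gestational week of delivery; pregnancies ongoing at the end of week 39 give birth.
TERM_WEEK = 40

#: Sentinel week meaning "the hazard process never fires" (live birth).
NO_EVENT_WEEK = 10_000

EVENT_KINDS = frozenset(
    {
        "sips_test",
        "nipt_test",
        "nipt_retest",
        "amniocentesis",
        "procedure_loss",
        "fluid_leak_hospitalization",
        "genetic_counselling",
        "ds_termination",
        "voluntary_termination",
        "spontaneous_loss",
        "admin",
        "live_birth",
    }
)


@dataclass(frozen=True)
class EventRecord:
    week: int
    kind: str
    payload: Optional[str] = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (10 <= self.week <= TERM_WEEK):
            raise ValueError(f"event week {self.week} outside [10, {TERM_WEEK}]")


@dataclass(frozen=True)
class LossSchedule:
    """Per-week spontaneous-loss hazards by fetal status, entry week to term."""

    weeks: np.ndarray
    hazard_unaffected: np.ndarray
    hazard_ds: np.ndarray

    def hazard(self, week: int, ds_affected: bool) -> float:
        if week >= TERM_WEEK:
            return 0.0
        idx = week - int(self.weeks[0])
        if idx < 0:
            return 0.0
        h = self.hazard_ds if ds_affected else self.hazard_unaffected
        return float(h[idx])

    def survival_to_term(self, ds_affected: bool) -> float:
        h = self.hazard_ds if ds_affected else self.hazard_unaffected
        return float(np.prod(1.0 - h))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": self.weeks,
                "hazard_unaffected": self.hazard_unaffected,
                "hazard_ds": self.hazard_ds,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class TerminationSchedule:
    """Per-week voluntary induced-abortion hazard among ongoing pregnancies."""

    weeks: np.ndarray
    hazard: np.ndarray

    def hazard_at(self, week: int) -> float:
        idx = week - int(self.weeks[0])
        if idx < 0 or idx >= len(self.weeks) or week >= TERM_WEEK:
            return 0.0
        return float(self.hazard[idx])

    def cumulative(self) -> float:
        return 1.0 - float(np.prod(1.0 - self.hazard))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"week": self.weeks, "hazard": self.hazard})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_loss_schedule(
    total_unaffected: float = 0.135,
    ds_anchors: dict[int, float] | None = None,
    shape: float = 0.76,
    entry_week: int = 10,
) -> LossSchedule:
    """Build the status-specific weekly spontaneous-loss hazards.

    Parameters
    ----------
    total_unaffected:
        Cumulative loss probability from ``entry_week`` to term for
        unaffected pregnancies.
    ds_anchors:
        week -> conditional probability of loss between that week and term
        for trisomy-21 pregnancies; must be strictly decreasing in week.
    shape:
        Weekly geometric decline ratio of the unaffected hazard (1 = flat);
        smaller values front-load losses into the earliest weeks.
    """
    if ds_anchors is None:
        ds_anchors = {10: 0.36, 12: 0.30, 14: 0.25, 16: 0.21}
    if not (0.0 <= total_unaffected < 1.0):
        raise ValueError("total_unaffected must lie in [0, 1)")
    if not (0.0 < shape <= 1.0):
        raise ValueError("shape (geometric decline ratio) must lie in (0, 1]")
    anchor_weeks = sorted(ds_anchors)
    anchor_vals = np.array([ds_anchors[w] for w in anchor_weeks], dtype=float)
    if np.any(np.diff(anchor_vals) >= 0):
        raise ValueError("DS anchors must be strictly decreasing in week")
    if np.any(anchor_vals < 0) or np.any(anchor_vals >= 1):
        raise ValueError("DS anchors must lie in [0, 1)")
    if anchor_weeks[0] != entry_week:
        raise ValueError("the first DS anchor must sit at the entry week")

    weeks = np.arange(entry_week, TERM_WEEK, dtype=np.int64)

    # --- DS-affected hazards ------------------------------------------------
    # Survival from entry up to (not including) week w:  L(w) = S_term(entry) / S_term(w)
    # where S_term(w) = 1 - anchor(w) is the conditional survival to term.
    s_entry = 1.0 - anchor_vals[0]
    log_l = np.log(s_entry / (1.0 - anchor_vals))  # log survival at anchor weeks
    last_anchor = anchor_weeks[-1]
    interp_weeks = np.arange(entry_week, last_anchor + 1)
    log_l_interp = np.interp(interp_weeks, anchor_weeks, log_l)
    hazard_ds = np.zeros(weeks.shape, dtype=float)
    # weekly hazards inside the anchored range (weeks entry .. last_anchor-1)
    h_inner = 1.0 - np.exp(np.diff(log_l_interp))
    hazard_ds[: last_anchor - entry_week] = h_inner
    # constant hazard from the last anchor to week 39, consuming the remaining
    # conditional loss (e.g. 21% from week 16 on)
    n_tail = TERM_WEEK - last_anchor
    tail_surv = 1.0 - anchor_vals[-1]
    hazard_ds[last_anchor - entry_week:] = 1.0 - tail_surv ** (1.0 / n_tail)
    if np.any(hazard_ds < -1e-12) or np.any(hazard_ds > 1.0):
        raise ValueError("infeasible DS anchor set: weekly hazard escaped [0, 1]")
    hazard_ds = np.clip(hazard_ds, 0.0, 1.0)

    # --- unaffected hazards: geometric decline scaled to the total ----------
    decline = shape ** (weeks - entry_week).astype(float)
    if total_unaffected == 0.0:
        hazard_u = np.zeros(weeks.shape, dtype=float)
    else:
        target_log_surv = np.log(1.0 - total_unaffected)

        def gap(h0: float) -> float:
            return float(np.sum(np.log1p(-h0 * decline))) - target_log_surv

        hi = 1.0 / float(decline.max())  # largest h0 keeping every hazard <= 1
        if gap(hi * (1 - 1e-12)) > 0:
            raise ValueError(
                "infeasible shape: cannot reach the requested cumulative loss "
                "with every weekly hazard <= 1"
            )
        h0 = brentq(gap, 0.0, hi * (1 - 1e-12), xtol=1e-15, rtol=1e-14)
        hazard_u = h0 * decline

    return LossSchedule(weeks=weeks, hazard_unaffected=hazard_u, hazard_ds=hazard_ds)


def build_termination_schedule(
    total: float = 0.23,
    t1_share: float = 0.90,
    t1_window: tuple[int, int] = (10, 13),
    t2_window: tuple[int, int] = (14, 27),
    entry_week: int = 10,
) -> TerminationSchedule:
    """Uniform weekly VIA hazard per trimester window.

    The unconditional probability mass in the first window is
    ``t1_share * total`` and in the second ``(1 - t1_share) * total``; the
    weekly hazard within each window is constant and solves the window's
    cumulative target exactly.
    """
    if not (0.0 <= total < 1.0):
        raise ValueError("total must lie in [0, 1)")
    if not (0.0 <= t1_share <= 1.0):
        raise ValueError("t1_share must lie in [0, 1]")
    if t1_window[1] >= t2_window[0]:
        raise ValueError("windows must be disjoint and ordered")
    weeks = np.arange(entry_week, TERM_WEEK, dtype=np.int64)
    hazard = np.zeros(weeks.shape, dtype=float)

    n1 = t1_window[1] - t1_window[0] + 1
    n2 = t2_window[1] - t2_window[0] + 1
    mass1 = t1_share * total
    mass2 = (1.0 - t1_share) * total
    for (lo, hi), n, mass, surv_before in (
        (t1_window, n1, mass1, 1.0),
        (t2_window, n2, mass2, 1.0 - mass1),
    ):
        if mass == 0.0:
            continue
        if n <= 0:
            raise ValueError("window of zero length with nonzero share")
        # P(event in window) = surv_before * (1 - (1 - h)^n) = mass
        frac = mass / surv_before
        if frac >= 1.0:
            raise ValueError("infeasible window mass")
        h = 1.0 - (1.0 - frac) ** (1.0 / n)
        sel = (weeks >= lo) & (weeks <= hi)
        if sel.sum() != n:
            raise ValueError("window extends outside the modelled weeks")
        hazard[sel] = h
    return TerminationSchedule(weeks=weeks, hazard=hazard)


def advance_week(
    woman: Woman,
    losses: LossSchedule,
    terminations: TerminationSchedule,
    rng: np.random.Generator,
) -> Optional[EventRecord]:
    """Advance one woman by one weekly cycle of the natural history.

    Evaluates, in fixed order, spontaneous loss then voluntary termination
    at the current week; on an event the terminal state is set and the
    record returned. Otherwise the week counter advances, and reaching the
    term week yields a live birth.
    """
    if not woman.ongoing:
        raise ValueError("advance_week called on a non-ongoing pregnancy")
    week = woman.current_week
    if rng.random() < losses.hazard(week, woman.ds_affected):
        woman.set_terminal("spontaneous_loss")
        rec = EventRecord(week, "spontaneous_loss")
        woman.record(rec)
        return rec
    if rng.random() < terminations.hazard_at(week):
        woman.set_terminal("voluntary_termination")
        rec = EventRecord(week, "voluntary_termination")
        woman.record(rec)
        return rec
    woman.current_week = week + 1
    if woman.current_week >= TERM_WEEK:
        woman.set_terminal("live_birth")
        rec = EventRecord(TERM_WEEK, "live_birth")
        woman.record(rec)
        return rec
    return None


def _event_week_cdf(hazards: np.ndarray) -> np.ndarray:
    """Cumulative pmf of the first-event week for a weekly-hazard process."""
    surv = np.cumprod(1.0 - hazards)
    prev = np.concatenate(([1.0], surv[:-1]))
    return np.cumsum(hazards * prev)


def sample_event_week(
    hazards: np.ndarray,
    weeks: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Inverse-CDF sample of the first-event week; NO_EVENT_WEEK if none fires.

    ``u`` are uniforms, one per subject; the mapping is monotone in ``u`` so
    shared uniforms give common-random-number coupling across schedules.
    """
    cdf = _event_week_cdf(np.asarray(hazards, dtype=float))
    idx = np.searchsorted(cdf, u, side="right")
    out = np.full(np.shape(u), NO_EVENT_WEEK, dtype=np.int64)
    hit = idx < len(weeks)
    out[hit] = np.asarray(weeks)[idx[hit]]
    return out


def schedules_from_config(cfg: NaturalHistoryConfig, entry_week: int = 10):
    """Build both schedules from a config block."""
    losses = build_loss_schedule(
        total_unaffected=cfg.loss_total_unaffected,
        ds_anchors=cfg.ds_loss_anchors,
        shape=cfg.loss_decline_ratio,
        entry_week=entry_week,
    )
    terminations = build_termination_schedule(
        total=cfg.termination_total,
        t1_share=cfg.termination_t1_share,
        t1_window=cfg.t1_window,
        t2_window=cfg.t2_window,
        entry_week=entry_week,
    )
    return losses, terminations
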