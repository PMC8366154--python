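"""Discrete-event simulation of the tiered recruitment protocol.

Treated patients are enrolled first (pull by pull); each enrollment opens a
recruitment window for that patient's candidate pool.  Contacts start in
the closest priority tier, escalate to the next tier every
``escalation_interval`` weeks while no match has enrolled, and the window
closes unconditionally after ``match_window`` weeks.  Every contacted
candidate enrolls with probability ``confirm_eligible_prob *
p_enroll_control``; the first enrollment forms the dyad.  A control
enrolled anywhere is removed from every other pool (each patient belongs
to at most one dyad).  The simulation stops once ``target_dyads`` dyads
are formed or all pools are exhausted, and emits a full event log from
which the dyad list can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import RecruitmentParams
from .exceptions import ConfigError
from .matching import MatchPool

EVENT_KINDS = ("pull_opened", "letter_sent", "contact_attempt", "enrolled_treated",
               "enrolled_control", "dyad_formed", "escalation", "window_closed")


@dataclass(frozen=True)
class RecruitmentEvent:
    week: int
    kind: str
    treated_id: str | None = None
    control_id: str | None = None
    tier: int | None = None
    distance: float | None = None


@dataclass(frozen=True)
class Dyad:
    treated_id: str
    control_id: str
    tier_of_enrollment: int
    days_between_enrollments: int
    distance: float


class _ActiveTreated:
    __slots__ = ("pool", "enroll_week", "attempted", "matched")

    def __init__(self, pool: MatchPool, enroll_week: int):
        self.pool = pool
        self.enroll_week = enroll_week
        self.attempted: set[str] = set()
        self.matched = False


def _normalize_pools(pools) -> list[tuple[int, list[MatchPool]]]:
    if isinstance(pools, Mapping):
        return [(int(k), list(v)) for k, v in sorted(pools.items())]
    if pools and isinstance(pools[0], MatchPool):
        return [(0, list(pools))]
    return [(i, list(p)) for i, p in enumerate(pools)]


def simulate_recruitment(pools, params: RecruitmentParams,
                         rng: np.random.Generator | None = None
                         ) -> tuple[list[Dyad], list[str], list[RecruitmentEvent]]:
    """Run the recruitment protocol over match pools.

    Parameters
    ----------
    pools
        Either a flat list of :class:`MatchPool` (a single pull), a list of
        per-pull lists, or a mapping pull index -> pools.  Pull k opens at
        week ``k * pull_interval_weeks``.
    params
        Validated :class:`RecruitmentParams`; ``params.seed`` drives the
        simulation unless an explicit generator is supplied.

    Returns ``(dyads, unmatched_treated_ids, event_log)``.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pulls = _normalize_pools(pools)
    log: list[RecruitmentEvent] = []
    dyads: list[Dyad] = []
    unmatched: list[str] = []
    enrolled_controls: set[str] = set()
    used_treated: set[str] = set()
    active: list[_ActiveTreated] = []
    p_enroll = params.confirm_eligible_prob * params.p_enroll_control

    pull_weeks = {k: k * params.pull_interval_weeks for k, _ in pulls}
    last_week = max(pull_weeks.values(), default=0) + params.match_window + 1
    pull_iter = iter(pulls)
    next_pull = next(pull_iter, None)
    week = 0
    done = False
    while week <= last_week and not done:
        # open any pull scheduled for this week: enroll its treated patients
        while next_pull is not None and pull_weeks[next_pull[0]] == week:
            k, pool_list = next_pull
            log.append(RecruitmentEvent(week, "pull_opened"))
            for pool in pool_list:
                if pool.treated_id in used_treated or not pool.eligible_for_recruitment:
                    continue
                used_treated.add(pool.treated_id)
                if rng.random() < params.p_enroll_treated:
                    log.append(RecruitmentEvent(week, "enrolled_treated",
                                                treated_id=pool.treated_id))
                    for cand in pool.candidates[:params.max_letters]:
                        log.append(RecruitmentEvent(week, "letter_sent",
                                                    treated_id=pool.treated_id,
                                                    control_id=cand.control_id,
                                                    tier=cand.tier))
                    active.append(_ActiveTreated(pool, week))
            next_pull = next(pull_iter, None)

        # weekly contact round for every open window, in enrollment order
        for state in active:
            if state.matched or done:
                continue
            elapsed = week - state.enroll_week
            if elapsed >= params.match_window:
                state.matched = True  # closes bookkeeping below as unmatched
                unmatched.append(state.pool.treated_id)
                log.append(RecruitmentEvent(week, "window_closed",
                                            treated_id=state.pool.treated_id))
                continue
            max_tier = 1 + elapsed // params.escalation_interval
            if elapsed > 0 and elapsed % params.escalation_interval == 0:
                log.append(RecruitmentEvent(week, "escalation",
                                            treated_id=state.pool.treated_id,
                                            tier=max_tier))
            contacts = 0
            for cand in state.pool.candidates:
                if contacts >= params.contacts_per_week or state.matched:
                    break
                if cand.tier > max_tier:
                    break  # candidates are sorted by tier; nothing further is open
                if (cand.control_id in state.attempted
                        or cand.control_id in enrolled_controls):
                    continue
                state.attempted.add(cand.control_id)
                contacts += 1
                log.append(RecruitmentEvent(week, "contact_attempt",
                                            treated_id=state.pool.treated_id,
                                            control_id=cand.control_id,
                                            tier=cand.tier))
                if rng.random() < p_enroll:
                    enrolled_controls.add(cand.control_id)
                    state.matched = True
                    days = 7 * (week - state.enroll_week)
                    if params.day_jitter:
                        days += int(rng.integers(0, 7))
                    log.append(RecruitmentEvent(week, "enrolled_control",
                                                treated_id=state.pool.treated_id,
                                                control_id=cand.control_id,
                                                tier=cand.tier,
                                                distance=cand.distance))
                    log.append(RecruitmentEvent(week, "dyad_formed",
                                                treated_id=state.pool.treated_id,
                                                control_id=cand.control_id,
                                                tier=cand.tier,
                                                distance=cand.distance))
                    dyads.append(Dyad(state.pool.treated_id, cand.control_id,
                                      cand.tier, days, cand.distance))
                    if len(dyads) >= params.target_dyads:
                        done = True
        if done:
            break
        if next_pull is None and all(s.matched for s in active):
            break
        week += 1

    # windows still open when the target was reached (or time ran out)
    for state in active:
        if not state.matched:
            unmatched.append(state.pool.treated_id)
            log.append(RecruitmentEvent(week, "window_closed",
                                        treated_id=state.pool.treated_id))
    return dyads, unmatched, log


def dyads_from_log(log: Sequence[RecruitmentEvent]) -> list[Dyad]:
    """Replay the event log, reconstructing the dyad list deterministically."""
    enroll_week: dict[str, int] = {}
    dyads: list[Dyad] = []
    for ev in log:
        if ev.kind == "enrolled_treated":
            enroll_week[ev.treated_id] = ev.week
        elif ev.kind == "dyad_formed":
            days = 7 * (ev.week - enroll_week[ev.treated_id])
            dyads.append(Dyad(ev.treated_id, ev.control_id, ev.tier, days,
                              ev.distance))
    return dyads


def recruitment_summary(dyads: Sequence[Dyad],
                        log: Sequence[RecruitmentEvent]) -> dict:
    """Summaries over realized dyads: matched fraction, tier-of-enrollment
    distribution (percent of enrolled dyads), median days between the two
    enrollments, and cumulative dyad counts by week and tier."""
    n_treated = sum(1 for ev in log if ev.kind == "enrolled_treated")
    tiers = [d.tier_of_enrollment for d in dyads]
    tier_dist = {}
    if tiers:
        vals, counts = np.unique(tiers, return_counts=True)
        tier_dist = {int(t): 100.0 * c / len(tiers) for t, c in zip(vals, counts)}
    weekly: dict[int, dict[int, int]] = {}
    for ev in log:
        if ev.kind == "dyad_formed":
            weekly.setdefault(ev.week, {})
            weekly[ev.week][ev.tier] = weekly[ev.week].get(ev.tier, 0) + 1
    cumulative = []
    running: dict[int, int] = {}
    for wk in sorted(weekly):
        for t, c in weekly[wk].items():
            running[t] = running.get(t, 0) + c
        cumulative.append({"week": wk, "by_tier": dict(sorted(running.items()))})
    return {
        "n_dyads": len(dyads),
        "n_treated_enrolled": n_treated,
        "fraction_matched": len(dyads) / n_treated if n_treated else float("nan"),
        "tier_distribution_pct": tier_dist,
        "median_days_between_enrollments": (float(np.median(
            [d.days_between_enrollments for d in dyads])) if dyads else float("nan")),
        "cumulative_by_week": cumulative,
    }
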