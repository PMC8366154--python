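"""Recruitment discrete-event simulation: limits, laws, replay, summaries."""

import dataclasses

import numpy as np
import pytest

from prospmatch import (Dyad, RecruitmentParams, dyads_from_log,
                        recruitment_summary, simulate_recruitment)
from prospmatch.matching import MatchCandidate, MatchPool


def pool_with_tiers(tid, tiers, prefix="C"):
    """A pool whose candidates have the given tiers (distances consistent
    with the default ladder), sorted as build_pool would emit them."""
    ladder = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0)
    cands, counts = [], {}
    for i, t in enumerate(sorted(tiers)):
        counts[t] = counts.get(t, 0) + 1
        d = ladder[t - 1] + 0.01 * counts[t]
        cands.append(MatchCandidate(f"{tid}{prefix}{i}", d, t, counts[t]))
    return MatchPool(tid, cands, True)


def params(**overrides):
    base = dict(target_dyads=275, seed=0, pull_interval_weeks=13)
    base.update(overrides)
    return RecruitmentParams(**base)


def test_certain_enrollment_forms_tier1_dyad_immediately():
    pools = [pool_with_tiers("T0", [1, 1, 2])]
    dyads, unmatched, log = simulate_recruitment(
        pools, params(p_enroll_control=1.0, contacts_per_week=1))
    assert len(dyads) == 1 and not unmatched
    assert dyads[0].tier_of_enrollment == 1
    assert dyads[0].days_between_enrollments <= 7


def test_impossible_enrollment_leaves_all_unmatched():
    pools = [pool_with_tiers(f"T{i}", [1, 1, 2, 3, 3]) for i in range(4)]
    dyads, unmatched, log = simulate_recruitment(
        pools, params(p_enroll_control=0.0))
    assert dyads == []
    assert sorted(unmatched) == [f"T{i}" for i in range(4)]
    closed = {ev.treated_id for ev in log if ev.kind == "window_closed"}
    assert closed == set(unmatched)


def test_matched_fraction_matches_geometric_closed_form():
    # 5 tier-1 candidates, one sequential contact per week, 5-week window:
    # success probability 1 - 0.8^5
    p_success = 1.0 - 0.8 ** 5
    n_rep = 2000
    rng = np.random.default_rng(123)
    par = params(p_enroll_control=0.2, contacts_per_week=1, target_dyads=1)
    hits = 0
    for _ in range(n_rep):
        dyads, _, _ = simulate_recruitment([pool_with_tiers("T0", [1] * 5)],
                                           par, rng=rng)
        hits += bool(dyads)
    se = np.sqrt(p_success * (1 - p_success) / n_rep)
    assert abs(hits / n_rep - p_success) < 3 * se


def test_treated_enrollment_probability_gates_pools():
    pools = [pool_with_tiers(f"T{i}", [1] * 5) for i in range(300)]
    par = params(p_enroll_treated=0.0, p_enroll_control=1.0)
    dyads, unmatched, log = simulate_recruitment(pools, par)
    assert dyads == [] and unmatched == []
    assert not any(ev.kind == "enrolled_treated" for ev in log)


def test_ineligible_pools_are_never_recruited():
    small = MatchPool("T0", [MatchCandidate("C0", 0.05, 1, 1)], False)
    dyads, unmatched, log = simulate_recruitment(
        [small], params(p_enroll_control=1.0))
    assert dyads == [] and unmatched == []


def _big_run(p_control=0.3, seed=5, target=80):
    rng = np.random.default_rng(99)
    pools = []
    shared = [f"S{i}" for i in range(40)]  # controls shared across pools
    for i in range(120):
        tiers = sorted(rng.choice([1, 1, 2, 2, 3, 4, 5], size=8))
        cands, counts = [], {}
        ladder = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0)
        for j, t in enumerate(tiers):
            counts[t] = counts.get(t, 0) + 1
            cid = shared[int(rng.integers(40))] if rng.random() < 0.5 \
                else f"T{i}C{j}"
            if any(c.control_id == cid for c in cands):
                continue
            cands.append(MatchCandidate(cid, ladder[t - 1] + 0.01 * counts[t],
                                        t, counts[t]))
        pools.append(MatchPool(f"T{i}", cands, True))
    par = params(p_enroll_control=p_control, seed=seed, target_dyads=target)
    return simulate_recruitment({0: pools[:60], 1: pools[60:]}, par), par


def test_conservation_window_escalation_and_stopping_laws():
    (dyads, unmatched, log), par = _big_run()
    # conservation: each id in at most one dyad
    treated_ids = [d.treated_id for d in dyads]
    control_ids = [d.control_id for d in dyads]
    assert len(set(treated_ids)) == len(treated_ids)
    assert len(set(control_ids)) == len(control_ids)
    assert not set(treated_ids) & set(control_ids)
    # enrolled controls are never contacted again
    enrolled_at = {}
    for ev in log:
        if ev.kind == "contact_attempt":
            assert ev.control_id not in enrolled_at
        elif ev.kind == "enrolled_control":
            enrolled_at[ev.control_id] = ev.week
    # window and escalation laws, per treated enrollment week
    enroll_week = {ev.treated_id: ev.week for ev in log
                   if ev.kind == "enrolled_treated"}
    for ev in log:
        if ev.kind == "enrolled_control":
            assert ev.week - enroll_week[ev.treated_id] < par.match_window
        if ev.kind == "contact_attempt":
            lag = ev.week - enroll_week[ev.treated_id]
            assert lag >= (ev.tier - 1) * par.escalation_interval
    # stopping law
    assert len(dyads) <= par.target_dyads


def test_event_log_replays_to_the_dyad_list():
    (dyads, _, log), _ = _big_run()
    assert dyads_from_log(log) == dyads


def test_matched_fraction_monotone_in_enrollment_probability():
    fractions = []
    for p in (0.05, 0.3, 0.9):
        (dyads, unmatched, log), _ = _big_run(p_control=p, seed=11, target=500)
        s = recruitment_summary(dyads, log)
        fractions.append(s["fraction_matched"])
    assert fractions[0] < fractions[1] < fractions[2]


def test_certain_enrollment_with_deep_pools_matches_everyone():
    pools = [pool_with_tiers(f"T{i}", [1] * 6) for i in range(50)]
    dyads, unmatched, _ = simulate_recruitment(
        pools, params(p_enroll_control=1.0, target_dyads=50))
    assert len(dyads) == 50 and not unmatched


def test_summary_tier_distribution_hand_count():
    dyads = [Dyad("T0", "C0", 1, 0, 0.05), Dyad("T1", "C1", 1, 7, 0.05),
             Dyad("T2", "C2", 2, 7, 0.2), Dyad("T3", "C3", 3, 30, 0.4)]
    s = recruitment_summary(dyads, [])
    assert s["tier_distribution_pct"] == {1: 50.0, 2: 25.0, 3: 25.0}
    assert s["median_days_between_enrollments"] == 7.0


def test_summary_all_tier_one():
    dyads = [Dyad(f"T{i}", f"C{i}", 1, 0, 0.01) for i in range(3)]
    assert recruitment_summary(dyads, [])["tier_distribution_pct"] == {1: 100.0}


def test_summary_with_zero_dyads_is_empty_not_error():
    s = recruitment_summary([], [])
    assert s["n_dyads"] == 0 and s["tier_distribution_pct"] == {}


def test_empty_pools_return_zero_dyads_with_log():
    dyads, unmatched, log = simulate_recruitment([], params())
    assert dyads == [] and unmatched == []


def test_identical_seed_identical_outcome():
    pools = [pool_with_tiers(f"T{i}", [1, 2, 2, 3, 4]) for i in range(30)]
    a = simulate_recruitment(pools, params(seed=42))
    b = simulate_recruitment(pools, params(seed=42))
    assert a == b
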