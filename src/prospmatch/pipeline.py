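"""End-to-end study driver: generate → classify → match → recruit → balance.

One global seed is split hierarchically (numpy ``SeedSequence``) into
per-stage substreams, so each stage is independently reproducible and the
whole run is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .balance import balance_table, render_balance_table
from .cohort import MATCHING_COVARIATES, generate_cohort, patients_to_frame
from .config import StudyConfig
from .eligibility import (CONTROL_ELIGIBLE, TREATED_ELIGIBLE, filter_facilities,
                          rolling_pull)
from .matching import build_pools, pool_statistics
from .recruitment import recruitment_summary, simulate_recruitment


def default_pull_schedule(config: StudyConfig) -> list[int]:
    """Quarterly pulls (default every 91 days) across the exposure window,
    ending with one pull that sees the complete exposure year."""
    start, end = config.windows.exposure
    step = 91
    schedule = list(range(start + step, end, step))
    schedule.append(end)
    return schedule


def _stage_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def run_full_study(config: StudyConfig, seed: int | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline on a synthetic cohort and return a report.

    When ``seed`` is given it overrides the per-stage seeds in the config
    through hierarchical substreams.  With ``out_dir`` set, all artifacts
    (patients.csv, visits.csv, eligibility.csv, pools.csv, dyads.csv,
    events.jsonl, balance.csv, report.json) are written there.
    """
    config.validate()
    cohort_cfg = config.cohort
    recr = config.recruitment
    if seed is not None:
        s_cohort, s_recruit = _stage_seeds(seed, 2)
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=s_cohort)
        recr = dataclasses.replace(recr, seed=s_recruit)

    patients, visits = generate_cohort(cohort_cfg, config.windows)

    kept_facilities = filter_facilities(patients, visits, config.windows,
                                        config.min_facility_treatment_visits)
    patients_kept = [p for p in patients if p.facility_id in kept_facilities]

    schedule = default_pull_schedule(config)
    pulls = rolling_pull(patients_kept, visits, config.windows, schedule)
    assignments = [a for pull in pulls for a in pull]
    by_id = {p.patient_id: p for p in patients_kept}

    pools_by_pull: dict[int, list] = {}
    cum_controls: list = []
    all_pools = []
    for k, pull in enumerate(pulls):
        cum_controls.extend(by_id[a.patient_id] for a in pull
                            if a.arm == CONTROL_ELIGIBLE)
        treated_k = [by_id[a.patient_id] for a in pull if a.arm == TREATED_ELIGIBLE]
        if treated_k and len(cum_controls) >= 2:
            pools = build_pools(treated_k, cum_controls, config.matching,
                                pull_index=k)
            pools_by_pull[k] = pools
            all_pools.extend(pools)

    report: dict = {
        "n_patients": len(patients),
        "n_facilities_kept": len(kept_facilities),
        "n_treated_eligible": sum(a.arm == TREATED_ELIGIBLE for a in assignments),
        "n_control_eligible": sum(a.arm == CONTROL_ELIGIBLE for a in assignments),
        "pull_schedule": schedule,
    }
    if all_pools:
        report["pool_statistics"] = pool_statistics(all_pools,
                                                    config.matching.min_pool_size)

    dyads, unmatched, log = simulate_recruitment(pools_by_pull, recr)
    report["recruitment"] = recruitment_summary(dyads, log)
    report["n_unmatched_treated"] = len(unmatched)

    # pre-matching balance: all treated-eligible vs all control-eligible
    frame = patients_to_frame(patients_kept).set_index("patient_id", drop=False)
    treated_ids = [a.patient_id for a in assignments if a.arm == TREATED_ELIGIBLE]
    control_ids = [a.patient_id for a in assignments if a.arm == CONTROL_ELIGIBLE]
    balance_pre = balance_post = None
    if treated_ids and control_ids:
        balance_pre = balance_table(frame.loc[treated_ids], frame.loc[control_ids],
                                    MATCHING_COVARIATES)
        report["balance_pre"] = balance_pre.to_dict("records")
    if dyads:
        g1 = frame.loc[[d.treated_id for d in dyads]]
        g2 = frame.loc[[d.control_id for d in dyads]]
        balance_post = balance_table(g1, g2, MATCHING_COVARIATES)
        report["balance_post"] = balance_post.to_dict("records")
    else:
        report["balance_post"] = None
        report["notice"] = "no dyads formed; post-matching balance skipped"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_patients(patients, out / "patients.csv")
        io.write_visits(visits, out / "visits.csv")
        io.write_eligibility(assignments, out / "eligibility.csv")
        io.write_pools(all_pools, out / "pools.csv")
        io.write_dyads(dyads, out / "dyads.csv")
        io.write_events(log, out / "events.jsonl")
        if balance_post is not None:
            balance_post.to_csv(out / "balance.csv", index=False)
            (out / "balance.txt").write_text(render_balance_table(balance_post))
        io.write_json(report, out / "report.json")
    return report
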