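"""Readers/writers for the package's tabular artifacts.

All artifacts are UTF-8 text: CSV with explicit headers for tables, JSON
Lines for event streams, JSON for reports.  Missing values are empty
fields.  Schemas are documented in docs/formats.md; every writer
round-trips through the corresponding reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import (PatientRecord, VisitEvent, frame_to_patients,
                     frame_to_visits, patients_to_frame, visits_to_frame)
from .eligibility import ArmAssignment
from .matching import MatchCandidate, MatchPool
from .recruitment import Dyad, RecruitmentEvent


def write_patients(patients: Sequence[PatientRecord], path) -> None:
    patients_to_frame(patients).to_csv(path, index=False)


def read_patients(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "facility_id": str})
    for col in ("female", "advance_directive", "dementia", "any_hospitalization",
                "excluded", "transferred"):
        df[col] = df[col].astype(bool)
    return frame_to_patients(df)


def write_visits(visits: Sequence[VisitEvent], path) -> None:
    visits_to_frame(visits).to_csv(path, index=False)


def read_visits(path) -> list[VisitEvent]:
    return frame_to_visits(pd.read_csv(path, dtype={"patient_id": str}))


def write_eligibility(assignments: Sequence[ArmAssignment], path) -> None:
    pd.DataFrame([dataclasses.asdict(a) for a in assignments]).to_csv(path,
                                                                      index=False)


def read_eligibility(path) -> list[ArmAssignment]:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    out = []
    for r in df.to_dict("records"):
        pull = r.get("pull_index")
        pull = None if pull in ("", None) or pd.isna(pull) else int(float(pull))
        out.append(ArmAssignment(r["patient_id"], r["arm"], r.get("reason", ""),
                                 pull))
    return out


def write_pools(pools: Sequence[MatchPool], path) -> None:
    rows = []
    for p in pools:
        for c in p.candidates:
            rows.append({"treated_id": p.treated_id, "control_id": c.control_id,
                         "distance": c.distance, "tier": c.tier,
                         "rank_within_tier": c.rank_within_tier,
                         "eligible_for_recruitment": p.eligible_for_recruitment,
                         "pull_index": p.pull_index})
        if not p.candidates:  # keep empty pools visible
            rows.append({"treated_id": p.treated_id, "control_id": "",
                         "distance": "", "tier": "", "rank_within_tier": "",
                         "eligible_for_recruitment": p.eligible_for_recruitment,
                         "pull_index": p.pull_index})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pools(path) -> list[MatchPool]:
    df = pd.read_csv(path, dtype={"treated_id": str, "control_id": str},
                     keep_default_na=False)
    pools: dict[str, MatchPool] = {}
    for r in df.to_dict("records"):
        tid = r["treated_id"]
        pull = r.get("pull_index")
        pull = None if pull in ("", None) else int(float(pull))
        if tid not in pools:
            pools[tid] = MatchPool(tid, [],
                                   str(r["eligible_for_recruitment"]) == "True",
                                   pull)
        if r["control_id"]:
            pools[tid].candidates.append(MatchCandidate(
                r["control_id"], float(r["distance"]), int(r["tier"]),
                int(r["rank_within_tier"])))
    return list(pools.values())


def write_dyads(dyads: Sequence[Dyad], path) -> None:
    pd.DataFrame([dataclasses.asdict(d) for d in dyads]).to_csv(path, index=False)


def read_dyads(path) -> list[Dyad]:
    df = pd.read_csv(path, dtype={"treated_id": str, "control_id": str})
    return [Dyad(r.treated_id, r.control_id, int(r.tier_of_enrollment),
                 int(r.days_between_enrollments), float(r.distance))
            for r in df.itertuples(index=False)]


def write_events(log: Sequence[RecruitmentEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in log:
            fh.write(json.dumps(dataclasses.asdict(ev)) + "\n")


def read_events(path) -> list[RecruitmentEvent]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(RecruitmentEvent(**json.loads(line)))
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
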