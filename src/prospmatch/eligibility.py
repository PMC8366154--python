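"""Eligibility classification from visit histories.

A patient is *treated-eligible* when the pre-exposure year shows at least
two usual-care visits and no treatment-clinic visits, and the exposure
year shows at least two treatment-clinic visits and no usual-care visits
(a clean transfer).  A patient is *control-eligible* when both years show
at least two usual-care visits and no treatment-clinic visits.  Exclusion
flags (hospice/palliative/institutionalized) are applied at classification
time.  Windows are half-open [start, end) on integer days; visits outside
both windows are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cohort import TREATMENT_CLINIC, USUAL_CLINIC, PatientRecord, VisitEvent
from .config import StudyWindows
from .exceptions import InputError

TREATED_ELIGIBLE = "treated_eligible"
CONTROL_ELIGIBLE = "control_eligible"
INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class ArmAssignment:
    patient_id: str
    arm: str
    reason: str = ""
    pull_index: int | None = None


def _window_counts(visits: Iterable[VisitEvent], windows: StudyWindows):
    pre_usual = pre_treat = exp_usual = exp_treat = 0
    for v in visits:
        if windows.in_pre(v.day):
            if v.clinic == TREATMENT_CLINIC:
                pre_treat += 1
            else:
                pre_usual += 1
        elif windows.in_exposure(v.day):
            if v.clinic == TREATMENT_CLINIC:
                exp_treat += 1
            else:
                exp_usual += 1
    return pre_usual, pre_treat, exp_usual, exp_treat


def classify_patient(visits: Sequence[VisitEvent], windows: StudyWindows,
                     record: PatientRecord) -> ArmAssignment:
    """Classify one patient from their visit history."""
    ids = {v.patient_id for v in visits}
    if ids and ids != {record.patient_id}:
        raise InputError(f"visits contain patient ids {sorted(ids)} but record "
                         f"is for {record.patient_id}")
    pid = record.patient_id
    if record.excluded:
        return ArmAssignment(pid, INELIGIBLE, "excluded_flag")
    pre_u, pre_t, exp_u, exp_t = _window_counts(visits, windows)
    clean_pre = pre_u >= 2 and pre_t == 0
    if clean_pre and exp_t >= 2 and exp_u == 0:
        return ArmAssignment(pid, TREATED_ELIGIBLE)
    if clean_pre and exp_u >= 2 and exp_t == 0:
        return ArmAssignment(pid, CONTROL_ELIGIBLE)
    if not clean_pre:
        reason = ("treatment_visit_in_pre_exposure" if pre_t > 0
                  else "insufficient_pre_exposure_visits")
    elif exp_t > 0 and exp_u > 0:
        reason = "mixed_clinics_in_exposure"
    elif exp_t == 1:
        reason = "insufficient_exposure_visits"
    else:
        reason = "insufficient_exposure_visits"
    return ArmAssignment(pid, INELIGIBLE, reason)


def classify_cohort(patients: Sequence[PatientRecord],
                    visits: Sequence[VisitEvent],
                    windows: StudyWindows) -> list[ArmAssignment]:
    by_patient: dict[str, list[VisitEvent]] = {p.patient_id: [] for p in patients}
    for v in visits:
        if v.patient_id in by_patient:
            by_patient[v.patient_id].append(v)
    return [classify_patient(by_patient[p.patient_id], windows, p)
            for p in patients]


def filter_facilities(patients: Sequence[PatientRecord],
                      visits: Sequence[VisitEvent],
                      windows: StudyWindows,
                      min_treatment_visits: int) -> set[str]:
    """Facilities whose treatment-clinic visit volume in the exposure window
    meets the threshold; downstream stages drop patients elsewhere."""
    if min_treatment_visits < 0:
        raise InputError("min_treatment_visits must be >= 0")
    facility_of = {p.patient_id: p.facility_id for p in patients}
    counts: dict[str, int] = {p.facility_id: 0 for p in patients}
    for v in visits:
        if (v.clinic == TREATMENT_CLINIC and windows.in_exposure(v.day)
                and v.patient_id in facility_of):
            counts[facility_of[v.patient_id]] += 1
    return {fac for fac, c in counts.items() if c >= min_treatment_visits}


def rolling_pull(patients: Sequence[PatientRecord],
                 visits: Sequence[VisitEvent],
                 windows: StudyWindows,
                 pull_schedule: Sequence[int]) -> list[list[ArmAssignment]]:
    """Quarterly-style rolling identification of eligible patients.

    At each pull day only visits strictly before that day are visible.  A
    patient is emitted at the first pull where they satisfy an arm's
    criteria and never re-emitted; the pulls partition the eventually
    eligible set.
    """
    if list(pull_schedule) != sorted(set(pull_schedule)):
        raise InputError("pull_schedule must be strictly increasing")
    by_patient: dict[str, list[VisitEvent]] = {p.patient_id: [] for p in patients}
    for v in visits:
        if v.patient_id in by_patient:
            by_patient[v.patient_id].append(v)
    emitted: set[str] = set()
    result: list[list[ArmAssignment]] = []
    for k, pull_day in enumerate(pull_schedule):
        newly: list[ArmAssignment] = []
        for p in patients:
            if p.patient_id in emitted:
                continue
            seen = [v for v in by_patient[p.patient_id] if v.day < pull_day]
            a = classify_patient(seen, windows, p)
            if a.arm != INELIGIBLE:
                newly.append(ArmAssignment(a.patient_id, a.arm, a.reason, k))
                emitted.add(p.patient_id)
        result.append(newly)
    return result
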