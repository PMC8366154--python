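"""Synthetic multi-facility cohort generator.

Emulates an administrative cohort of community-dwelling older adults in
which transfer from usual primary care to a geriatric team-care model is
driven by *observed* covariates (age, frailty scores, dementia, prior
hospitalization).  Selection into the treatment arm follows a logistic
model on standardized covariates, so unmatched arms are imbalanced by
construction and matching has something real to remove.  An optional
unobserved-confounder term (default weight 0) is available for residual
confounding studies.

Conventions: day 0 is the start of the exposure period; visits are drawn
uniformly within the pre-exposure window [-365, 0) and exposure window
[0, 365).  Patients designated for an arm are guaranteed at least two
qualifying visits per required window; a small ``crossover_prob`` fraction
receive one disqualifying opposite-clinic visit so the eligibility filter
has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CohortConfig
from .exceptions import DegenerateInputError

TREATMENT_CLINIC = "treatment_clinic"
USUAL_CLINIC = "usual_clinic"


@dataclass(frozen=True)
class PatientRecord:
    """One patient's fixed pre-exposure covariates and flags."""

    patient_id: str
    facility_id: str
    age: float
    race: str
    female: bool
    advance_directive: bool
    dementia: bool
    n_hospitalizations: int
    any_hospitalization: bool
    can_score: float
    jfi_score: float
    excluded: bool
    transferred: bool
    latent_transfer_propensity: float  # generator-internal; never used in matching


@dataclass(frozen=True)
class VisitEvent:
    """One dated clinic contact. ``day`` is an offset from the study origin."""

    patient_id: str
    day: int
    clinic: str


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(PatientRecord)]
    return pd.DataFrame([[getattr(p, c) for c in cols] for p in patients],
                        columns=cols)


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    cols = [f.name for f in fields(PatientRecord)]
    return [PatientRecord(**{c: row[c] for c in cols})
            for row in df.to_dict("records")]


def visits_to_frame(visits: Iterable[VisitEvent]) -> pd.DataFrame:
    return pd.DataFrame([(v.patient_id, v.day, v.clinic) for v in visits],
                        columns=["patient_id", "day", "clinic"])


def frame_to_visits(df: pd.DataFrame) -> list[VisitEvent]:
    return [VisitEvent(r.patient_id, int(r.day), r.clinic)
            for r in df.itertuples(index=False)]


def _selection_propensity(cfg: CohortConfig, age, can, jfi, dementia, n_hosp,
                          unobserved) -> np.ndarray:
    """Logistic transfer propensity on standardized covariates.

    Continuous covariates are standardized by their configured marginal
    mean/SD so the coefficients are on a common per-SD log-odds scale;
    dementia enters as 0/1, hospitalizations as a sqrt-rate-scaled count,
    and ``unobserved`` is a standard-normal latent confounder.
    """
    coef = dict(cfg.selection_coefficients)
    hosp_scale = np.sqrt(cfg.hospitalization_rate) if cfg.hospitalization_rate > 0 else 1.0
    lp = (coef.get("intercept", 0.0)
          + coef.get("age", 0.0) * (age - cfg.age_mean) / cfg.age_sd
          + coef.get("can_score", 0.0) * (can - cfg.can_mean) / cfg.can_sd
          + coef.get("jfi_score", 0.0) * (jfi - cfg.jfi_mean) / cfg.jfi_sd
          + coef.get("dementia", 0.0) * dementia
          + coef.get("n_hospitalizations", 0.0)
          * (n_hosp - cfg.hospitalization_rate) / hosp_scale
          + coef.get("unobserved", 0.0) * unobserved)
    return 1.0 / (1.0 + np.exp(-lp))


def _visit_days(rng: np.random.Generator, window: tuple[int, int], n: int) -> np.ndarray:
    return rng.integers(window[0], window[1], size=n)


def generate_cohort(config: CohortConfig,
                    windows=None) -> tuple[list[PatientRecord], list[VisitEvent]]:
    """Generate a reproducible synthetic cohort.

    Returns patient records and their visit histories.  Deterministic for a
    fixed ``config`` (the seed lives in the config).
    """
    config.validate()
    if windows is None:
        from .config import StudyWindows
        windows = StudyWindows()
    rng = np.random.default_rng(config.seed)
    n = config.n_facilities * config.patients_per_facility

    facility = np.repeat([f"F{i:03d}" for i in range(config.n_facilities)],
                         config.patients_per_facility)
    age = np.maximum(18.0, rng.normal(config.age_mean, config.age_sd, n))
    race = rng.choice(CohortConfig.RACE_CATEGORIES, size=n,
                      p=[config.race_probs[c] for c in CohortConfig.RACE_CATEGORIES])
    female = rng.random(n) < config.female_prob
    advance_directive = rng.random(n) < config.advance_directive_prob
    dementia = rng.random(n) < config.dementia_prob
    n_hosp = rng.poisson(config.hospitalization_rate, n)

    # CAN and JFI: correlated truncated normals, clamped to their scales.
    rho = config.can_jfi_corr
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    can = np.clip(config.can_mean + config.can_sd * z[:, 0], 0.0, 99.0)
    jfi = np.clip(config.jfi_mean + config.jfi_sd * z[:, 1], 0.0, 13.0)

    unobserved = rng.standard_normal(n)
    propensity = _selection_propensity(config, age, can, jfi,
                                       dementia.astype(float), n_hosp, unobserved)
    transferred = rng.random(n) < propensity

    excl = np.zeros(n, dtype=bool)
    for p in config.exclusion_probs.values():
        excl |= rng.random(n) < p

    patients = [
        PatientRecord(
            patient_id=f"P{i:06d}", facility_id=facility[i],
            age=float(age[i]), race=str(race[i]), female=bool(female[i]),
            advance_directive=bool(advance_directive[i]), dementia=bool(dementia[i]),
            n_hospitalizations=int(n_hosp[i]),
            any_hospitalization=bool(n_hosp[i] > 0),
            can_score=float(can[i]), jfi_score=float(jfi[i]),
            excluded=bool(excl[i]), transferred=bool(transferred[i]),
            latent_transfer_propensity=float(propensity[i]))
        for i in range(n)
    ]

    visits: list[VisitEvent] = []
    lam = config.visit_intensity
    crossover = rng.random(n) < config.crossover_prob
    for i, rec in enumerate(patients):
        n_pre = max(2, rng.poisson(lam))
        n_exp = max(2, rng.poisson(lam))
        pre_days = _visit_days(rng, windows.pre_exposure, n_pre)
        exp_days = _visit_days(rng, windows.exposure, n_exp)
        exp_clinic = TREATMENT_CLINIC if rec.transferred else USUAL_CLINIC
        for d in pre_days:
            visits.append(VisitEvent(rec.patient_id, int(d), USUAL_CLINIC))
        for d in exp_days:
            visits.append(VisitEvent(rec.patient_id, int(d), exp_clinic))
        if crossover[i]:
            # one disqualifying opposite-clinic visit in the exposure window
            bad_clinic = USUAL_CLINIC if rec.transferred else TREATMENT_CLINIC
            visits.append(VisitEvent(rec.patient_id,
                                     int(_visit_days(rng, windows.exposure, 1)[0]),
                                     bad_clinic))
    return patients, visits


# covariates summarized in balance reports: the four distance variables
# plus every coarsened-exact characteristic (race as per-category indicators)
MATCHING_COVARIATES: Sequence[tuple[str, str]] = (
    ("age", "continuous"),
    ("n_hospitalizations", "continuous"),
    ("can_score", "continuous"),
    ("jfi_score", "continuous"),
    ("race_black", "binary"),
    ("race_white", "binary"),
    ("race_other_or_missing", "binary"),
    ("female", "binary"),
    ("advance_directive", "binary"),
    ("dementia", "binary"),
    ("any_hospitalization", "binary"),
)


def confounding_report(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Unmatched standardized mean differences, transferred vs not.

    Sanity surface for the generator: under the default confounded
    configuration at least one covariate should show |SMD| >= 0.2 before
    matching; under a null selection model all should be near 0.
    """
    from .balance import balance_table
    df = patients_to_frame(patients)
    treated = df[df.transferred]
    control = df[~df.transferred]
    if len(treated) == 0 or len(control) == 0:
        raise DegenerateInputError("confounding report requires at least one "
                                   "patient in each arm")
    return balance_table(treated, control, MATCHING_COVARIATES)
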