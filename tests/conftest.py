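import dataclasses

import numpy as np
import pytest

from prospmatch import (CohortConfig, MatchingParams, PatientRecord, StudyConfig,
                        run_full_study)


def make_patient(**overrides) -> PatientRecord:
    """A valid baseline patient; override any field."""
    base = dict(
        patient_id="P0", facility_id="F0", age=80.0, race="white", female=False,
        advance_directive=False, dementia=False, n_hospitalizations=0,
        any_hospitalization=False, can_score=50.0, jfi_score=4.0,
        excluded=False, transferred=False, latent_transfer_propensity=0.1)
    base.update(overrides)
    if "n_hospitalizations" in overrides and "any_hospitalization" not in overrides:
        base["any_hospitalization"] = base["n_hospitalizations"] > 0
    return PatientRecord(**base)


def random_patients(rng: np.random.Generator, n: int, n_facilities: int = 2,
                    prefix: str = "P") -> list[PatientRecord]:
    """Random but invariant-respecting patients for oracle tests."""
    out = []
    for i in range(n):
        hosp = int(rng.poisson(0.5))
        out.append(make_patient(
            patient_id=f"{prefix}{i:05d}",
            facility_id=f"F{rng.integers(n_facilities)}",
            age=float(rng.normal(80, 7)),
            race=str(rng.choice(["black", "white", "other_or_missing"])),
            female=bool(rng.random() < 0.3),
            advance_directive=bool(rng.random() < 0.3),
            dementia=bool(rng.random() < 0.2),
            n_hospitalizations=hosp,
            can_score=float(rng.uniform(0, 99)),
            jfi_score=float(rng.uniform(0, 13)),
        ))
    return out


@pytest.fixture(scope="session")
def default_study_report():
    """One full default-configuration study run shared across tests."""
    return run_full_study(StudyConfig().validate(), seed=7)


@pytest.fixture(scope="session")
def small_cohort_config():
    return dataclasses.replace(CohortConfig(), n_facilities=2,
                               patients_per_facility=300, seed=3)


@pytest.fixture()
def matching_params():
    return MatchingParams()
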