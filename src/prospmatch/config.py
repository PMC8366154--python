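"""Study configuration: typed parameter blocks for every pipeline stage.

A :class:`StudyConfig` bundles the cohort generator, eligibility windows,
matching, recruitment and power-simulation parameters, and can be loaded
from / serialized to YAML or JSON.  Validation is strict: unknown keys are
rejected and every constraint violation names the offending field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .exceptions import ConfigError

SCHEMA_VERSION = "1.0"

#: continuous variables entering the Mahalanobis distance
DISTANCE_VARIABLES = ("age", "n_hospitalizations", "can_score", "jfi_score")


def _require(cond: bool, field_name: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {constraint}")


def _prob(value: float, name: str) -> None:
    _require(0.0 <= value <= 1.0, name, f"must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class StudyWindows:
    """Half-open day intervals for the pre-exposure and exposure periods.

    Day 0 is the start of the exposure period; the two windows must be
    adjacent (pre-exposure ends where exposure begins).  A visit on a
    boundary day belongs to the later window.
    """

    pre_exposure: tuple[int, int] = (-365, 0)
    exposure: tuple[int, int] = (0, 365)

    def validate(self) -> "StudyWindows":
        _require(self.pre_exposure[0] < self.pre_exposure[1], "windows.pre_exposure",
                 "must have positive length")
        _require(self.exposure[0] < self.exposure[1], "windows.exposure",
                 "must have positive length")
        _require(self.pre_exposure[1] == self.exposure[0], "windows",
                 "pre_exposure must end where exposure begins")
        return self

    def in_pre(self, day: int) -> bool:
        return self.pre_exposure[0] <= day < self.pre_exposure[1]

    def in_exposure(self, day: int) -> bool:
        return self.exposure[0] <= day < self.exposure[1]


def _default_selection_coefficients() -> dict[str, float]:
    # log-odds weights on standardized covariates; intercept ~ logit(0.10).
    # Positive weights on frailty/risk scores reproduce the empirical pattern
    # that sicker, older patients are the ones referred into the geriatric
    # care model, which is what makes the unmatched arms imbalanced.
    return {
        "intercept": -2.2,
        "age": 0.4,
        "can_score": 0.6,
        "jfi_score": 0.6,
        "dementia": 0.8,
        "n_hospitalizations": 0.3,
        "unobserved": 0.0,
    }


_SELECTION_KEYS = frozenset(_default_selection_coefficients())


@dataclass
class CohortConfig:
    """Parameters of the synthetic multi-facility cohort generator.

    Marginal defaults target the enrolled study population: mean age ~80,
    CAN ~50 (0-99 scale), JFI ~4 (0-13 scale), ~2% female, ~83% white,
    ~28% advance directive, ~3% dementia, ~0.1 hospitalizations/year.
    """

    n_facilities: int = 6
    patients_per_facility: int = 1500
    seed: int = 0
    age_mean: float = 80.0
    age_sd: float = 7.0
    race_probs: dict[str, float] = field(default_factory=lambda: {
        "black": 0.124, "white": 0.833, "other_or_missing": 0.043})
    female_prob: float = 0.02
    advance_directive_prob: float = 0.28
    dementia_prob: float = 0.033
    hospitalization_rate: float = 0.11
    can_mean: float = 50.0
    can_sd: float = 30.0
    jfi_mean: float = 4.0
    jfi_sd: float = 2.0
    can_jfi_corr: float = 0.3
    selection_coefficients: dict[str, float] = field(
        default_factory=_default_selection_coefficients)
    exclusion_probs: dict[str, float] = field(default_factory=lambda: {
        "hospice": 0.01, "palliative": 0.01, "institutionalized": 0.02})
    visit_intensity: float = 6.0
    crossover_prob: float = 0.05

    RACE_CATEGORIES = ("black", "white", "other_or_missing")

    def validate(self) -> "CohortConfig":
        _require(self.n_facilities >= 1, "cohort.n_facilities", "must be >= 1")
        _require(self.patients_per_facility >= 1, "cohort.patients_per_facility",
                 "must be >= 1")
        _require(set(self.race_probs) == set(self.RACE_CATEGORIES), "cohort.race_probs",
                 f"must have exactly the keys {self.RACE_CATEGORIES}")
        for k, v in self.race_probs.items():
            _prob(v, f"cohort.race_probs[{k}]")
        _require(abs(sum(self.race_probs.values()) - 1.0) < 1e-9, "cohort.race_probs",
                 "must sum to 1 within 1e-9")
        for name in ("female_prob", "advance_directive_prob", "dementia_prob",
                     "crossover_prob"):
            _prob(getattr(self, name), f"cohort.{name}")
        for k, v in self.exclusion_probs.items():
            _prob(v, f"cohort.exclusion_probs[{k}]")
        _require(self.age_sd > 0, "cohort.age_sd", "must be > 0")
        _require(self.can_sd > 0, "cohort.can_sd", "must be > 0")
        _require(self.jfi_sd > 0, "cohort.jfi_sd", "must be > 0")
        _require(self.hospitalization_rate >= 0, "cohort.hospitalization_rate",
                 "must be >= 0")
        _require(self.visit_intensity > 0, "cohort.visit_intensity", "must be > 0")
        _require(-1.0 < self.can_jfi_corr < 1.0, "cohort.can_jfi_corr",
                 "must be in (-1, 1)")
        unknown = set(self.selection_coefficients) - _SELECTION_KEYS
        _require(not unknown, "cohort.selection_coefficients",
                 f"unknown covariate name(s): {sorted(unknown)}")
        return self


@dataclass
class MatchingParams:
    """Coarsened-exact + distance matching parameters."""

    age_caliper: float = 5.0
    age_bin_width: float | None = None  # if set, bins replace the caliper
    min_pool_size: int = 5
    tier_ladder: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0)
    distance_mode: str = "diagonal"  # "diagonal" or "full"

    def validate(self) -> "MatchingParams":
        _require(self.age_caliper >= 0, "matching.age_caliper", "must be >= 0")
        _require(self.min_pool_size >= 1, "matching.min_pool_size", "must be >= 1")
        _require(len(self.tier_ladder) >= 1, "matching.tier_ladder",
                 "must have at least one threshold")
        ladder = tuple(float(t) for t in self.tier_ladder)
        _require(all(b > a for a, b in zip(ladder, ladder[1:])) and ladder[0] > 0,
                 "matching.tier_ladder", "ladder must be increasing and positive")
        _require(all(math.isfinite(t) for t in ladder), "matching.tier_ladder",
                 "thresholds must be finite (the last tier is implicitly unbounded)")
        _require(self.distance_mode in ("diagonal", "full"), "matching.distance_mode",
                 "must be 'diagonal' or 'full'")
        if self.age_bin_width is not None:
            _require(self.age_bin_width > 0, "matching.age_bin_width", "must be > 0")
        return self


@dataclass
class RecruitmentParams:
    """Discrete-event recruitment protocol parameters (time unit: weeks)."""

    p_enroll_treated: float = 1.0
    p_enroll_control: float = 0.20
    escalation_interval: int = 2
    match_window: int = 5
    contacts_per_week: int = 3
    target_dyads: int = 275
    seed: int = 0
    confirm_eligible_prob: float = 1.0
    pull_interval_weeks: int = 13
    max_letters: int = 20
    day_jitter: bool = False

    def validate(self) -> "RecruitmentParams":
        for name in ("p_enroll_treated", "p_enroll_control", "confirm_eligible_prob"):
            _prob(getattr(self, name), f"recruitment.{name}")
        _require(self.escalation_interval >= 1, "recruitment.escalation_interval",
                 "must be >= 1 week")
        _require(self.match_window >= 1, "recruitment.match_window",
                 "must be >= 1 week")
        _require(self.contacts_per_week >= 1, "recruitment.contacts_per_week",
                 "must be >= 1")
        _require(self.target_dyads >= 1, "recruitment.target_dyads", "must be >= 1")
        _require(self.pull_interval_weeks >= 0, "recruitment.pull_interval_weeks",
                 "must be >= 0")
        _require(self.max_letters >= 1, "recruitment.max_letters", "must be >= 1")
        return self


@dataclass
class PowerSpec:
    """Monte-Carlo sample-size simulation for zero-inflated count outcomes.

    Marginal arm means are in days not at home over the follow-up interval;
    the non-zero component rate is solved so the marginal mean hits its
    target.  ``zero_inflation``, ``icc`` and the analysis model are
    reconstruction defaults, each a config knob.
    """

    n_dyads: int = 275
    n_replicates: int = 1000
    mean_control: float = 5.5
    mean_treated: float = 4.0
    family: str = "zip"  # "zip" or "zinb"
    zero_inflation: float = 0.3
    nb_dispersion: float = 1.0
    variance_multiplier_target: float | None = None  # if set, calibrates nb_dispersion
    n_clusters: int = 57
    icc: float = 0.05
    alpha: float = 0.05
    analysis: str = "zi_regression"
    seed: int = 0
    max_failure_fraction: float = 0.10

    def validate(self) -> "PowerSpec":
        _require(self.n_dyads >= 2, "power.n_dyads", "must be >= 2")
        _require(self.n_replicates >= 1, "power.n_replicates", "must be >= 1")
        _require(self.mean_control >= 0 and self.mean_treated >= 0, "power.means",
                 "arm means must be >= 0")
        _require(self.family in ("zip", "zinb"), "power.family",
                 "must be 'zip' or 'zinb'")
        _prob(self.zero_inflation, "power.zero_inflation")
        if self.zero_inflation == 1.0 and max(self.mean_control, self.mean_treated) > 0:
            raise ConfigError("power.zero_inflation: cannot be 1 with a positive "
                              "target mean (infeasible marginal mean)")
        _require(self.nb_dispersion > 0, "power.nb_dispersion", "must be > 0")
        if self.variance_multiplier_target is not None:
            _require(self.variance_multiplier_target > 1, "power.variance_multiplier_target",
                     "must be > 1 (ratio of ZINB to ZIP marginal variance)")
        _require(self.n_clusters >= 1, "power.n_clusters", "must be >= 1")
        _require(0.0 <= self.icc < 1.0, "power.icc", "must be in [0, 1)")
        _require(0.0 < self.alpha < 1.0, "power.alpha", "must be in (0, 1)")
        _require(self.analysis in ("zi_regression", "cluster_robust",
                                   "paired_nonparametric"), "power.analysis",
                 "must be one of zi_regression, cluster_robust, paired_nonparametric")
        _prob(self.max_failure_fraction, "power.max_failure_fraction")
        return self


@dataclass
class StudyConfig:
    """Top-level study configuration; sections mirror the pipeline stages."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    windows: StudyWindows = field(default_factory=StudyWindows)
    matching: MatchingParams = field(default_factory=MatchingParams)
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    power: PowerSpec = field(default_factory=PowerSpec)
    min_facility_treatment_visits: int = 0
    version: str = SCHEMA_VERSION

    def validate(self) -> "StudyConfig":
        self.cohort.validate()
        self.windows.validate()
        self.matching.validate()
        self.recruitment.validate()
        self.power.validate()
        _require(self.min_facility_treatment_visits >= 0,
                 "min_facility_treatment_visits", "must be >= 0")
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["matching"]["tier_ladder"] = list(self.matching.tier_ladder)
        d["windows"] = {"pre_exposure": list(self.windows.pre_exposure),
                        "exposure": list(self.windows.exposure)}
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)


def _build_section(cls, data: Mapping[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    kwargs = dict(data)
    if cls is MatchingParams and "tier_ladder" in kwargs:
        kwargs["tier_ladder"] = tuple(kwargs["tier_ladder"])
    return cls(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> StudyConfig:
    """Build a validated :class:`StudyConfig` from a plain mapping."""
    known = {"cohort", "windows", "matching", "recruitment", "power",
             "min_facility_treatment_visits", "version"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    windows_data = data.get("windows", {})
    if windows_data:
        extra = set(windows_data) - {"pre_exposure", "exposure"}
        if extra:
            raise ConfigError(f"windows: unknown key(s) {sorted(extra)}")
        windows = StudyWindows(
            pre_exposure=tuple(windows_data.get("pre_exposure", (-365, 0))),
            exposure=tuple(windows_data.get("exposure", (0, 365))))
    else:
        windows = StudyWindows()
    cfg = StudyConfig(
        cohort=_build_section(CohortConfig, data.get("cohort", {}), "cohort"),
        windows=windows,
        matching=_build_section(MatchingParams, data.get("matching", {}), "matching"),
        recruitment=_build_section(RecruitmentParams, data.get("recruitment", {}),
                                   "recruitment"),
        power=_build_section(PowerSpec, data.get("power", {}), "power"),
        min_facility_treatment_visits=data.get("min_facility_treatment_visits", 0),
        version=str(data.get("version", SCHEMA_VERSION)),
    )
    return cfg.validate()


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a study configuration from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)
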