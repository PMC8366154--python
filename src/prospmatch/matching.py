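"""Coarsened-exact plus minimum-distance match-pool construction.

For each treated patient, candidate controls must agree exactly on the
coarsened key (facility, race, sex, advance directive, dementia, any prior
hospitalization) and lie within an age caliper (default |Δage| ≤ 5 years;
an age-bin option exists for sensitivity).  Candidates are then ranked by
a Mahalanobis distance over four standardized continuous variables — age,
hospitalization count, CAN score, JFI score — and banded into priority
tiers (default thresholds 0.1, 0.25, 0.5, 1.0, 2.0; last tier unbounded).
A treated patient is recruitable only with at least ``min_pool_size``
(default 5) candidates, reflecting an expected one-in-five telephone
enrollment rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .cohort import PatientRecord
from .config import DISTANCE_VARIABLES, MatchingParams
from .exceptions import ConfigError, DegenerateInputError


class ExactKey(NamedTuple):
    """Coarsened characteristics that must agree exactly (age handled
    separately as a caliper, or as a bin when configured)."""

    facility_id: str
    race: str
    female: bool
    advance_directive: bool
    dementia: bool
    any_hospitalization: bool


def exact_key(record: PatientRecord) -> ExactKey:
    return ExactKey(record.facility_id, record.race, record.female,
                    record.advance_directive, record.dementia,
                    record.any_hospitalization)


def exact_compatible(a: PatientRecord, b: PatientRecord,
                     params: MatchingParams) -> bool:
    """Exact-key equality plus the age rule (caliper, or shared bin)."""
    if exact_key(a) != exact_key(b):
        return False
    if params.age_bin_width is not None:
        w = params.age_bin_width
        return int(a.age // w) == int(b.age // w)
    return abs(a.age - b.age) <= params.age_caliper


@dataclass(frozen=True)
class Standardizer:
    """Per-variable location/scale transform (x - mean) / SD, fitted on a
    reference population (the control-eligible patients at the current pull)."""

    variables: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def transform(self, record: PatientRecord) -> np.ndarray:
        x = np.array([getattr(record, v) for v in self.variables], dtype=float)
        return (x - np.asarray(self.means)) / np.asarray(self.sds)

    def transform_matrix(self, records: Sequence[PatientRecord]) -> np.ndarray:
        x = np.array([[getattr(r, v) for v in self.variables] for r in records],
                     dtype=float)
        return (x - np.asarray(self.means)) / np.asarray(self.sds)


def fit_standardizer(controls: Sequence[PatientRecord],
                     variables: Sequence[str] = DISTANCE_VARIABLES) -> Standardizer:
    """Estimate means and sample SDs (ddof=1) on the reference population."""
    if len(controls) < 2:
        raise DegenerateInputError("need at least 2 records to fit a standardizer")
    x = np.array([[getattr(r, v) for v in variables] for r in controls], dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    for v, s in zip(variables, sds):
        if s <= 0.0:
            raise DegenerateInputError(
                f"variable {v!r} has zero variance in the reference population")
    return Standardizer(tuple(variables), tuple(means), tuple(sds))


def fit_covariance_inverse(controls: Sequence[PatientRecord],
                           standardizer: Standardizer) -> np.ndarray:
    """Inverse covariance of the standardized variables, for the full
    Mahalanobis mode."""
    z = standardizer.transform_matrix(controls)
    cov = np.cov(z, rowvar=False, ddof=1)
    try:
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "singular covariance among standardized matching variables") from exc


def distance(treated: PatientRecord, control: PatientRecord,
             standardizer: Standardizer, covariance_mode: str = "diagonal",
             cov_inv: np.ndarray | None = None) -> float:
    """Distance between two patients on the standardized variables.

    ``diagonal`` (default) is Euclidean distance on standardized variables,
    i.e. Mahalanobis with a diagonal covariance; ``full`` uses the inverse
    covariance of the standardized reference population.
    """
    d = standardizer.transform(treated) - standardizer.transform(control)
    if covariance_mode == "diagonal":
        return float(np.sqrt(d @ d))
    if covariance_mode == "full":
        if cov_inv is None:
            raise ValueError("full covariance mode requires cov_inv")
        return float(np.sqrt(d @ cov_inv @ d))
    raise ConfigError(f"matching.distance_mode: unknown mode {covariance_mode!r}")


def assign_tiers(distances: np.ndarray,
                 ladder: Sequence[float]) -> np.ndarray:
    """Band distances into 1-based priority tiers.

    Tier k covers [ladder[k-2], ladder[k-1]) with an implicit 0 lower bound
    for tier 1; distances at or beyond the last threshold fall in the
    unbounded final tier (len(ladder) + 1).
    """
    ladder = np.asarray(ladder, dtype=float)
    if len(ladder) == 0 or np.any(np.diff(ladder) <= 0) or ladder[0] <= 0:
        raise ConfigError("matching.tier_ladder: ladder must be increasing "
                          "and positive")
    return np.searchsorted(ladder, np.asarray(distances, dtype=float),
                           side="right") + 1


@dataclass(frozen=True)
class MatchCandidate:
    control_id: str
    distance: float
    tier: int
    rank_within_tier: int


@dataclass
class MatchPool:
    treated_id: str
    candidates: list[MatchCandidate] = field(default_factory=list)
    eligible_for_recruitment: bool = False
    pull_index: int | None = None

    def __len__(self) -> int:
        return len(self.candidates)


def build_pool(treated: PatientRecord, controls: Sequence[PatientRecord],
               params: MatchingParams, standardizer: Standardizer,
               cov_inv: np.ndarray | None = None,
               pull_index: int | None = None) -> MatchPool:
    """Construct the candidate pool for one treated patient.

    Candidates are the exact-compatible controls, each with a distance and
    tier, sorted by (tier, distance, control_id) — the id breaks ties for
    reproducibility.  An empty pool is allowed and flagged not recruitable.
    """
    params.validate()
    compatible = [c for c in controls if exact_compatible(treated, c, params)]
    if not compatible:
        return MatchPool(treated.patient_id, [], False, pull_index)
    zt = standardizer.transform(treated)
    zc = standardizer.transform_matrix(compatible)
    diff = zc - zt
    if params.distance_mode == "diagonal":
        dists = np.sqrt((diff ** 2).sum(axis=1))
    else:
        if cov_inv is None:
            cov_inv = np.eye(diff.shape[1])
        dists = np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_inv, diff))
    tiers = assign_tiers(dists, params.tier_ladder)
    order = sorted(range(len(compatible)),
                   key=lambda i: (tiers[i], dists[i], compatible[i].patient_id))
    candidates: list[MatchCandidate] = []
    tier_counts: dict[int, int] = {}
    for i in order:
        t = int(tiers[i])
        tier_counts[t] = tier_counts.get(t, 0) + 1
        candidates.append(MatchCandidate(compatible[i].patient_id,
                                         float(dists[i]), t, tier_counts[t]))
    return MatchPool(treated.patient_id, candidates,
                     len(candidates) >= params.min_pool_size, pull_index)


def build_pools(treated: Sequence[PatientRecord],
                controls: Sequence[PatientRecord],
                params: MatchingParams,
                pull_index: int | None = None) -> list[MatchPool]:
    """Fit the standardizer on the controls and build every treated pool."""
    standardizer = fit_standardizer(controls)
    cov_inv = (fit_covariance_inverse(controls, standardizer)
               if params.distance_mode == "full" else None)
    return [build_pool(t, controls, params, standardizer, cov_inv, pull_index)
            for t in treated]


def pool_statistics(pools: Sequence[MatchPool], min_pool_size: int = 5) -> dict:
    """Summary over pools: how many lack the minimum, pool-size median and
    range (over all pools, plus a median conditional on recruitability)."""
    if len(pools) == 0:
        raise DegenerateInputError("pool_statistics requires at least one pool")
    sizes = np.array([len(p) for p in pools])
    lacking = int((sizes < min_pool_size).sum())
    eligible_sizes = sizes[sizes >= min_pool_size]
    return {
        "n_pools": len(pools),
        "n_lacking_min_matches": lacking,
        "fraction_lacking": lacking / len(pools),
        "median_pool_size": float(np.median(sizes)),
        "min_pool_size_observed": int(sizes.min()),
        "max_pool_size_observed": int(sizes.max()),
        "median_pool_size_recruitable": (float(np.median(eligible_sizes))
                                         if len(eligible_sizes) else float("nan")),
    }
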