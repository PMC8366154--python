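"""Match-pool construction: exact keys, standardization, distances, tiers."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

from prospmatch import (ConfigError, DegenerateInputError, MatchingParams,
                        assign_tiers, build_pool, distance, exact_compatible,
                        exact_key, fit_covariance_inverse, fit_standardizer,
                        pool_statistics)
from prospmatch.config import DISTANCE_VARIABLES
from prospmatch.matching import MatchPool

from conftest import make_patient, random_patients


def test_exact_key_ignores_distance_variables():
    a = make_patient(can_score=10.0)
    b = make_patient(can_score=90.0)
    assert exact_key(a) == exact_key(b)


def test_exact_key_separates_facilities():
    assert exact_key(make_patient(facility_id="FA")) != \
        exact_key(make_patient(facility_id="FB"))


def test_age_caliper_is_five_years():
    params = MatchingParams()
    assert exact_compatible(make_patient(age=80), make_patient(age=85), params)
    assert not exact_compatible(make_patient(age=80), make_patient(age=86), params)


def test_age_bins_option():
    params = MatchingParams(age_bin_width=5.0)
    # 80 and 84 share the [80, 85) bin; 79 does not
    assert exact_compatible(make_patient(age=80), make_patient(age=84), params)
    assert not exact_compatible(make_patient(age=80), make_patient(age=79.5), params)


def test_caliper_symmetry():
    rng = np.random.default_rng(0)
    params = MatchingParams()
    pts = random_patients(rng, 30)
    for a, b in zip(pts[::2], pts[1::2]):
        assert exact_compatible(a, b, params) == exact_compatible(b, a, params)


def test_standardizer_hand_arithmetic():
    controls = [make_patient(patient_id="C0", age=70.0),
                make_patient(patient_id="C1", age=90.0)]
    s = fit_standardizer(controls, variables=("age",))
    i = s.variables.index("age")
    assert s.means[i] == pytest.approx(80.0)
    assert s.sds[i] == pytest.approx(math.sqrt(200.0))  # sample SD 14.142...


def test_standardizer_zero_variance_error_names_variable():
    controls = [make_patient(patient_id="C0"), make_patient(patient_id="C1")]
    with pytest.raises(DegenerateInputError, match="age"):
        fit_standardizer(controls)


def test_standardized_fitting_population_has_mean_zero_sd_one():
    rng = np.random.default_rng(1)
    controls = random_patients(rng, 200)
    s = fit_standardizer(controls)
    z = s.transform_matrix(controls)
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_distance_zero_iff_equal_on_distance_variables():
    rng = np.random.default_rng(2)
    controls = random_patients(rng, 50)
    s = fit_standardizer(controls)
    a = make_patient(age=77.0, can_score=33.0, jfi_score=5.0, n_hospitalizations=1)
    b = dataclasses.replace(a, patient_id="PB", facility_id="F9")
    assert distance(a, b, s) == 0.0
    c = dataclasses.replace(b, can_score=34.0)
    assert distance(a, c, s) > 0.0


def test_distance_symmetry_and_brute_force_agreement():
    rng = np.random.default_rng(3)
    controls = random_patients(rng, 100)
    s = fit_standardizer(controls)
    pairs = list(zip(random_patients(rng, 20, prefix="A"),
                     random_patients(rng, 20, prefix="B")))
    for a, b in pairs:
        d = distance(a, b, s)
        assert d == pytest.approx(distance(b, a, s), abs=0)
        # independent element-by-element recomputation
        acc = 0.0
        for v, m, sd in zip(s.variables, s.means, s.sds):
            za = (getattr(a, v) - m) / sd
            zb = (getattr(b, v) - m) / sd
            acc += (za - zb) ** 2
        assert d == pytest.approx(math.sqrt(acc), abs=1e-12)


def test_full_mahalanobis_agrees_with_scipy():
    rng = np.random.default_rng(4)
    controls = random_patients(rng, 300)
    s = fit_standardizer(controls)
    vi = fit_covariance_inverse(controls, s)
    for a, b in zip(random_patients(rng, 10, prefix="A"),
                    random_patients(rng, 10, prefix="B")):
        expected = scipy_mahalanobis(s.transform(a), s.transform(b), vi)
        assert distance(a, b, s, "full", vi) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("d, tier", [
    (0.05, 1),   # < 0.1: highest priority
    (0.10, 2),   # half-open boundary: exactly 0.1 falls in the second band
    (0.30, 3),   # < 0.5
    (0.0, 1),
    (1.999, 5),
    (2.0, 6),    # beyond the last threshold: unbounded final tier
    (50.0, 6),
])
def test_tier_ladder(d, tier):
    assert assign_tiers(np.array([d]), (0.1, 0.25, 0.5, 1.0, 2.0))[0] == tier


def test_non_increasing_ladder_rejected():
    with pytest.raises(ConfigError, match="increasing"):
        assign_tiers(np.array([0.1]), (0.5, 0.1))
    with pytest.raises(ConfigError):
        MatchingParams(tier_ladder=(0.5, 0.1)).validate()


def test_pool_without_compatible_controls_is_ineligible():
    treated = make_patient(facility_id="FA")
    controls = [make_patient(patient_id=f"C{i}", facility_id="FB")
                for i in range(10)]
    s = fit_standardizer(random_patients(np.random.default_rng(5), 50))
    pool = build_pool(treated, controls, MatchingParams(), s)
    assert len(pool) == 0 and not pool.eligible_for_recruitment


def test_min_pool_size_rule():
    rng = np.random.default_rng(6)
    treated = make_patient()
    controls = [dataclasses.replace(make_patient(patient_id=f"C{i}"),
                                    can_score=float(10 + i)) for i in range(4)]
    s = fit_standardizer(random_patients(rng, 50))
    pool = build_pool(treated, controls, MatchingParams(min_pool_size=5), s)
    assert len(pool) == 4 and not pool.eligible_for_recruitment
    pool2 = build_pool(treated, controls, MatchingParams(min_pool_size=4), s)
    assert pool2.eligible_for_recruitment


def _oracle_pool(treated, controls, params, s):
    """Exhaustive all-pairs reference implementation."""
    rows = []
    for c in controls:
        if not exact_compatible(treated, c, params):
            continue
        d = distance(c, treated, s)  # symmetric; order swapped on purpose
        t = int(assign_tiers(np.array([d]), params.tier_ladder)[0])
        rows.append((t, d, c.patient_id))
    rows.sort()
    return rows


def test_build_pool_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    params = MatchingParams()
    controls = random_patients(rng, 200, n_facilities=2, prefix="C")
    s = fit_standardizer(controls)
    for treated in random_patients(rng, 10, n_facilities=2, prefix="T"):
        pool = build_pool(treated, controls, params, s)
        oracle = _oracle_pool(treated, controls, params, s)
        assert [(c.tier, c.control_id) for c in pool.candidates] == \
            [(t, cid) for t, _, cid in oracle]
        for cand, (_, d, _) in zip(pool.candidates, oracle):
            assert cand.distance == pytest.approx(d, abs=1e-12)


def test_tier_monotone_in_distance_within_pool():
    rng = np.random.default_rng(8)
    controls = random_patients(rng, 300, n_facilities=1, prefix="C")
    s = fit_standardizer(controls)
    pool = build_pool(make_patient(), controls, MatchingParams(), s)
    tiers = [c.tier for c in sorted(pool.candidates, key=lambda c: c.distance)]
    assert tiers == sorted(tiers)


def test_ties_broken_by_control_id():
    treated = make_patient()
    twin = dict(age=75.0, can_score=40.0, jfi_score=3.0)
    controls = [make_patient(patient_id="C_B", **twin),
                make_patient(patient_id="C_A", **twin),
                make_patient(patient_id="C_C", age=75.0, can_score=41.0,
                             jfi_score=3.0)]
    s = fit_standardizer(random_patients(np.random.default_rng(9), 50))
    pool = build_pool(treated, controls, MatchingParams(), s)
    ids = [c.control_id for c in pool.candidates]
    assert ids.index("C_A") < ids.index("C_B")


def test_pool_statistics_hand_count():
    def fake_pool(tid, n):
        from prospmatch.matching import MatchCandidate
        cands = [MatchCandidate(f"{tid}c{i}", 0.1 * i, 1, i + 1) for i in range(n)]
        return MatchPool(tid, cands, n >= 5)
    stats = pool_statistics([fake_pool("a", 3), fake_pool("b", 5),
                             fake_pool("c", 129)], 5)
    assert stats["n_lacking_min_matches"] == 1
    assert stats["fraction_lacking"] == pytest.approx(1 / 3)
    assert stats["median_pool_size"] == 5
    assert (stats["min_pool_size_observed"], stats["max_pool_size_observed"]) \
        == (3, 129)
    single = pool_statistics([fake_pool("a", 7)], 5)
    assert single["median_pool_size"] == 7
    assert pool_statistics([fake_pool("a", 6), fake_pool("b", 9)],
                           5)["fraction_lacking"] == 0.0


def test_pool_statistics_empty_input_rejected():
    with pytest.raises(DegenerateInputError):
        pool_statistics([], 5)
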