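"""Preprocessing: RR trend, rSO2 fusion, ventilation, stratification,
cohort filter, and stratum normalization statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalwatch import (
    InsufficientDataError,
    ValidationError,
    cohort_inclusion_filter,
    fit_stratum_statistics,
    fuse_rso2,
    normalize,
    rr_trend,
    stratify,
    ventilation_status,
)
from vitalwatch.preprocess import Stratum

from conftest import make_record

NAN = float("nan")


# ----------------------------------------------------------------- fusion
@pytest.mark.parametrize(
    "left,right,expected",
    [(50.0, 60.0, 55.0), (50.0, NAN, 50.0), (NAN, 60.0, 60.0), (NAN, NAN, NAN)],
)
def test_fuse_rso2_cases(left, right, expected):
    got = fuse_rso2(left, right)
    assert got == expected or (np.isnan(got) and np.isnan(expected))


_probe = st.one_of(st.just(float("nan")), st.floats(0, 100))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_probe, _probe)
def test_fuse_rso2_symmetric(a, b):
    x, y = fuse_rso2(a, b), fuse_rso2(b, a)
    assert (np.isnan(x) and np.isnan(y)) or x == y


# ------------------------------------------------------------ ventilation
@pytest.mark.parametrize("etco2,expected", [(5.2, True), (0.0, False), (NAN, False)])
def test_ventilation_status(etco2, expected):
    assert ventilation_status(etco2) is expected


# --------------------------------------------------------------- RR trend
def test_rr_trend_constant_series():
    record = make_record({"rr": np.full(400, 34.0)})
    trend = rr_trend(record)
    assert trend[350] == pytest.approx(34.0)


def test_rr_trend_matches_direct_summation_on_ramp():
    # rr ramps 30..59 over 300 s; trailing window [t-300, t-1]
    rr = np.concatenate([np.linspace(30, 59, 300), np.full(10, 59.0)])
    record = make_record({"rr": rr})
    trend = rr_trend(record)
    assert trend[300] == pytest.approx(np.sum(rr[:300]) / 300.0)
    assert trend[305] == pytest.approx(np.sum(rr[5:305]) / 300.0)


def test_rr_trend_missing_below_min_obs():
    rr = np.full(400, np.nan)
    rr[:100] = 34.0  # only 100 observations in any window
    record = make_record({"rr": rr})
    assert np.isnan(rr_trend(record)[350])
    rr[:150] = 34.0
    assert rr_trend(make_record({"rr": rr}))[150] == pytest.approx(34.0)


def test_rr_trend_shift_equivariant(rng):
    segment = rng.uniform(20, 60, size=600)
    a = make_record({"rr": np.concatenate([segment, np.full(100, np.nan)])})
    b = make_record({"rr": np.concatenate([np.full(37, np.nan), segment])})
    ta, tb = rr_trend(a), rr_trend(b)
    np.testing.assert_allclose(ta[300:600], tb[337:637], equal_nan=True)


# ---------------------------------------------------------- stratification
@pytest.mark.parametrize(
    "spo2,expected",
    [(77.0, Stratum.LOW_SAT), (97.0, Stratum.HIGH_SAT), (90.0, Stratum.HIGH_SAT)],
)
def test_stratify_boundaries(spo2, expected):
    record = make_record({"spo2": np.full(100, spo2)})
    assert stratify(record) is expected


def test_stratify_depends_only_on_value_multiset(rng):
    values = rng.uniform(70, 100, size=500)
    a = make_record({"spo2": values})
    b = make_record({"spo2": rng.permutation(values)})
    assert stratify(a) is stratify(b)


def test_stratify_all_missing_rejected():
    with pytest.raises(ValidationError):
        stratify(make_record({"spo2": np.full(10, np.nan)}))


# ------------------------------------------------------------ cohort filter
def _complete_record(n, **meta):
    cols = {
        "hr": np.full(n, 150.0),
        "rr": np.full(n, 34.0),
        "spo2": np.full(n, 77.0),
        "rso2_left": np.full(n, 55.0),
        "rso2_right": np.full(n, 56.0),
        "ibp_mean": np.full(n, 51.0),
        "etco2": np.zeros(n),
    }
    return make_record(cols, **meta)


def test_cohort_filter_requires_twelve_hours_complete():
    # RR trend (hence vector completeness) starts after 150 observed seconds
    assert cohort_inclusion_filter(_complete_record(12 * 3600 + 150)) is True
    assert cohort_inclusion_filter(_complete_record(12 * 3600 + 149)) is False


@pytest.mark.parametrize(
    "weight,age,expected", [(1900.0, 7.0, False), (3400.0, 7.0, True), (3400.0, 400.0, False)]
)
def test_cohort_filter_weight_and_age(weight, age, expected):
    record = _complete_record(13 * 3600, birth_weight_g=weight, age_days=age)
    assert cohort_inclusion_filter(record) is expected


# -------------------------------------------------------------- statistics
def test_two_point_statistics_match_hand_calculation():
    a = np.array([150.0, 30.0, 70.0, 50.0, 45.0])
    b = np.array([160.0, 40.0, 80.0, 60.0, 55.0])
    stats = fit_stratum_statistics(np.vstack([a, b]), min_vectors=2)
    np.testing.assert_allclose(stats.mean, (a + b) / 2)
    np.testing.assert_allclose(stats.sd, np.abs(a - b) / np.sqrt(2))


def test_iid_standard_normal_recovers_moments(rng):
    n = 10000
    X = rng.standard_normal((n, 5))
    stats = fit_stratum_statistics(X)
    bound = 4 / np.sqrt(n)
    assert np.all(np.abs(stats.mean) < bound)
    assert np.all(np.abs(stats.sd - 1) < bound)
    assert np.all(np.abs(stats.covariance - np.eye(5)) < bound)


def test_identical_vectors_rejected():
    X = np.tile([150.0, 34.0, 77.0, 55.0, 51.0], (150, 1))
    with pytest.raises(ValidationError):
        fit_stratum_statistics(X)


def test_too_few_vectors_rejected(rng):
    with pytest.raises(InsufficientDataError):
        fit_stratum_statistics(rng.standard_normal((50, 5)))


def test_normalize_mean_is_zero_and_unit_offsets(rng):
    X = rng.normal([150, 34, 77, 55, 51], [10, 4, 6, 7, 5], size=(500, 5))
    stats = fit_stratum_statistics(X)
    np.testing.assert_allclose(normalize(stats.mean, stats), np.zeros(5), atol=1e-12)
    np.testing.assert_allclose(
        normalize(stats.mean + stats.sd, stats), np.ones(5), atol=1e-12
    )
    v = X[17]
    np.testing.assert_allclose(normalize(v, stats), (v - stats.mean) / stats.sd)


def test_normalize_rejects_incomplete():
    stats = fit_stratum_statistics(
        np.random.default_rng(0).standard_normal((200, 5))
    )
    with pytest.raises(ValidationError):
        normalize(np.array([1.0, np.nan, 0.0, 0.0, 0.0]), stats)
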