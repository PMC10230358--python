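"""Parameter-combination model (submodel 2): Mahalanobis reduction,
percentile prefilter, one-class SVM, static cutoffs, persistence."""

import numpy as np
import pytest
from sklearn.svm import OneClassSVM

from vitalwatch import (
    CombinationModel,
    InsufficientDataError,
    StaticCutoffs,
    ValidationError,
    mahalanobis_distance,
    percentile_prefilter,
)
from vitalwatch.preprocess import normalize
from vitalwatch.simulate import LOW_SAT_PROFILE

from conftest import profile_mvn


# ------------------------------------------------------------- Mahalanobis
def test_mahalanobis_trivial_cases():
    assert mahalanobis_distance(np.zeros(5), np.eye(5)) == 0.0
    assert mahalanobis_distance(np.array([3.0, 4.0, 0, 0, 0]), np.eye(5)) == pytest.approx(5.0)


def test_mahalanobis_against_explicit_block_inverse():
    # 2x2 block [[2,1],[1,2]] in an otherwise-identity covariance;
    # inverse block is [[2,-1],[-1,2]]/3, so z=(1,1,0,0,0) gives d^2 = 2/3
    cov = np.eye(5)
    cov[:2, :2] = [[2.0, 1.0], [1.0, 2.0]]
    z = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
    assert mahalanobis_distance(z, cov) == pytest.approx(np.sqrt(2.0 / 3.0))


def test_mahalanobis_invariant_under_linear_maps(rng):
    for _ in range(5):
        cov = rng.standard_normal((5, 5))
        cov = cov @ cov.T + 5 * np.eye(5)
        z = rng.standard_normal(5)
        A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        d1 = mahalanobis_distance(z, cov)
        d2 = mahalanobis_distance(A @ z, A @ cov @ A.T)
        assert d1 == pytest.approx(d2, rel=1e-8)


# ---------------------------------------------------------------- prefilter
def test_prefilter_retains_exactly_eighty_of_hundred(rng):
    d = rng.permutation(np.linspace(0.1, 10, 100))
    assert percentile_prefilter(d).size == 80


def test_prefilter_keeps_all_ties():
    assert percentile_prefilter(np.full(50, 3.0)).size == 50


def test_prefilter_matches_sort_oracle():
    d = np.arange(1.0, 11.0)
    kept = percentile_prefilter(d)
    threshold = np.percentile(d, 80)
    oracle = {i for i, v in enumerate(d) if v <= threshold}
    assert set(kept) == oracle


def test_prefilter_retained_fraction_bounds(rng):
    for n in (25, 100, 1000):
        d = rng.standard_normal(n) ** 2
        frac = percentile_prefilter(d).size / n
        assert 0.8 <= frac <= 0.8 + 1.0 / n + 1e-12


# -------------------------------------------------------------- SVM model
@pytest.fixture(scope="module")
def small_model():
    X = profile_mvn(LOW_SAT_PROFILE, 3000, seed=7)
    return CombinationModel(random_state=0).fit(X), X


def test_nu_property_on_training_partition(small_model):
    model, X = small_model
    labels = model.predict(X[model.train_indices_])
    assert np.mean(labels == -1) <= model.nu + 0.02


def test_population_mean_is_stable_and_far_vector_unstable(small_model):
    model, _ = small_model
    mean = model.stats_.mean
    assert model.classify(mean)[0] == "STABLE"
    far = mean + 10 * model.stats_.sd
    assert model.classify(far)[0] == "UNSTABLE"


def test_fit_is_reproducible(small_model):
    model, X = small_model
    again = CombinationModel(random_state=0).fit(X)
    probe = profile_mvn(LOW_SAT_PROFILE, 200, seed=9)
    np.testing.assert_array_equal(
        model.decision_function(probe), again.decision_function(probe)
    )


def test_decision_function_matches_sklearn(small_model):
    model, X = small_model
    z_train = normalize(X[model.train_indices_], model.stats_)
    svm = OneClassSVM(kernel="rbf", nu=model.nu, gamma=model.gamma_).fit(z_train)
    probe = profile_mvn(LOW_SAT_PROFILE, 300, seed=11)
    z = normalize(probe, model.stats_)
    np.testing.assert_allclose(
        model.decision_function(probe), svm.decision_function(z), rtol=1e-9, atol=1e-9
    )


def test_persistence_round_trip_is_bit_identical(small_model, tmp_path):
    model, _ = small_model
    model.save(tmp_path / "bundle")
    loaded = CombinationModel.load(tmp_path / "bundle")
    probe = profile_mvn(LOW_SAT_PROFILE, 500, seed=13)
    a = model.decision_function(probe)
    b = loaded.decision_function(probe)
    np.testing.assert_array_equal(a, b)  # exact, not approximate
    assert loaded.threshold_ == model.threshold_


def test_insufficient_vectors_rejected(rng):
    X = profile_mvn(LOW_SAT_PROFILE, 400, seed=3)
    with pytest.raises(InsufficientDataError):
        CombinationModel(min_train=500).fit(X)


# ----------------------------------------------------------- static cutoffs
def test_cutoff_truth_table():
    cutoffs = StaticCutoffs({"hr": (60.0, 230.0), "ibp_mean": (20.0, 90.0)})
    inside = np.array([150.0, 34.0, 77.0, 55.0, 51.0])
    assert not cutoffs.violation(inside)[0]
    high_hr = inside.copy(); high_hr[0] = 240.0
    assert cutoffs.violation(high_hr)[0]
    low_ibp = inside.copy(); low_ibp[4] = 15.0
    assert cutoffs.violation(low_ibp)[0]
    assert not StaticCutoffs({}).violation(high_hr)[0]


def test_cutoff_bounds_validated():
    with pytest.raises(ValidationError):
        StaticCutoffs({"hr": (100.0, 50.0)})


def test_svm_inlier_with_cutoff_violation_is_unstable():
    X = profile_mvn(LOW_SAT_PROFILE, 1500, seed=21)
    tight = StaticCutoffs({"hr": (None, 100.0)})  # below the population center
    model = CombinationModel(cutoffs=tight, random_state=0).fit(X)
    mean = model.stats_.mean
    assert model.predict(mean.reshape(1, -1))[0] == 1  # SVM accepts the centroid
    assert model.classify(mean)[0] == "UNSTABLE"  # but the cutoff fires
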