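"""Shared fixtures.

The expensive objects (a trained detector and its training cohort, a
classified stable record) are session-scoped so that the end-to-end
properties share one fit.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vitalwatch as vw
from vitalwatch.preprocess import Stratum
from vitalwatch.simulate import SIM_PARAMETERS

#: study-condition constants shared by the end-to-end tests
TRAIN_SEEDS = tuple(range(100, 110))
TRAIN_HOURS = 3
STABLE_SEED = 1
STABLE_HOURS = 6


def profile_mvn(profile, n: int, seed: int) -> np.ndarray:
    """Sample complete 5-parameter vectors from a stratum profile's
    multivariate-normal (mean = centers, cov = D R D), in model parameter
    order (hr, rr_trend, spo2, rso2_fused, ibp_mean)."""
    rng = np.random.default_rng(seed)
    mean = np.array([profile.centers[p] for p in SIM_PARAMETERS])
    sd = profile.sd_vector()
    cov = np.outer(sd, sd) * np.asarray(profile.correlation, dtype=float)
    return rng.multivariate_normal(mean, cov, size=n)


def make_record(
    columns: dict[str, np.ndarray], start: int = 0, **meta
) -> vw.PatientRecord:
    """Build a record from per-column arrays (missing columns all-NaN)."""
    n = len(next(iter(columns.values())))
    data = {
        c: np.asarray(columns.get(c, np.full(n, np.nan)), dtype=float)
        for c in ("hr", "rr", "spo2", "rso2_left", "rso2_right", "ibp_mean", "etco2")
    }
    frame = pd.DataFrame(data, index=pd.RangeIndex(start, start + n, name="t"))
    meta.setdefault("birth_weight_g", 3400.0)
    meta.setdefault("age_days", 7.0)
    return vw.PatientRecord(data=frame, **meta)


@pytest.fixture(scope="session")
def training_cohort() -> list[vw.PatientRecord]:
    return [
        vw.simulate(Stratum.LOW_SAT, TRAIN_HOURS * 3600, s)[0] for s in TRAIN_SEEDS
    ]


@pytest.fixture(scope="session")
def detector(training_cohort) -> vw.DeteriorationDetector:
    det = vw.DeteriorationDetector(random_state=0)
    det.fit(training_cohort)
    return det


@pytest.fixture(scope="session")
def combo_model(detector) -> vw.CombinationModel:
    return detector.models_[Stratum.LOW_SAT]


@pytest.fixture(scope="session")
def stable_record():
    record, truth = vw.simulate(Stratum.LOW_SAT, STABLE_HOURS * 3600, STABLE_SEED)
    return record, truth


@pytest.fixture(scope="session")
def stable_result(detector, stable_record) -> vw.ClassificationResult:
    return detector.predict_record(stable_record[0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
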