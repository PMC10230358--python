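"""Preprocessing: RR trend, rSO2 fusion, ventilation status, stratification,
cohort filtering, and per-stratum normalization statistics.

The classifier operates on 5-vectors of (HR, smoothed RR, SpO2, fused rSO2,
mean IBP).  Respiratory rate enters as a 300-second trailing moving average
because neonatal RR fluctuates strongly within minutes; the two cerebral
oximetry probes are fused into one value; EtCO2 > 0 is the proxy for active
mechanical ventilation.  Patients are stratified by admission-mean SpO2
(< 90% cyanotic vs >= 90% acyanotic) and each stratum gets its own mean,
scale and correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .records import PatientRecord

#: Order of the five model parameters in every matrix/vector.
PARAMETERS = ("hr", "rr_trend", "spo2", "rso2_fused", "ibp_mean")

RR_TREND_WINDOW = 300
RR_TREND_MIN_OBS = 150


class Stratum(str, Enum):
    """Admission-mean SpO2 stratum: cyanotic (<90%) vs acyanotic (>=90%)."""

    LOW_SAT = "LOW_SAT"
    HIGH_SAT = "HIGH_SAT"


def fuse_rso2(left, right):
    """Fuse the two cerebral oximetry probes.

    Mean when both probes read, the single available probe otherwise,
    missing when neither reads.  Accepts scalars or arrays.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    both = ~np.isnan(left) & ~np.isnan(right)
    out = np.where(both, (left + right) / 2.0, np.where(np.isnan(left), right, left))
    return float(out) if out.ndim == 0 else out


def ventilation_status(etco2) -> np.ndarray | bool:
    """True iff EtCO2 is non-missing and strictly positive."""
    etco2 = np.asarray(etco2, dtype=float)
    out = np.greater(etco2, 0.0, where=~np.isnan(etco2), out=np.zeros(etco2.shape, bool))
    return bool(out) if out.ndim == 0 else out


def rr_trend(
    record: PatientRecord,
    window: int = RR_TREND_WINDOW,
    min_obs: int = RR_TREND_MIN_OBS,
) -> np.ndarray:
    """Trailing moving average of RR over ``[t-window, t-1]`` at each second.

    NaN wherever fewer than ``min_obs`` non-missing RR values fall in the
    window.  Returned array is aligned with ``record.t``.
    """
    rr = record.data["rr"]
    return rr.shift(1).rolling(window=window, min_periods=min_obs).mean().to_numpy()


def parameter_matrix(
    record: PatientRecord,
    window: int = RR_TREND_WINDOW,
    min_obs: int = RR_TREND_MIN_OBS,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the per-second ``(n, 5)`` parameter matrix and completeness mask.

    Columns follow :data:`PARAMETERS`; ``complete[t]`` is True iff all five
    parameters are non-missing at that second.
    """
    d = record.data
    X = np.column_stack(
        [
            d["hr"].to_numpy(dtype=float),
            rr_trend(record, window=window, min_obs=min_obs),
            d["spo2"].to_numpy(dtype=float),
            fuse_rso2(d["rso2_left"].to_numpy(), d["rso2_right"].to_numpy()),
            d["ibp_mean"].to_numpy(dtype=float),
        ]
    )
    complete = ~np.isnan(X).any(axis=1)
    return X, complete


def stratify(record: PatientRecord) -> Stratum:
    """Assign the record to a stratum from its mean SpO2 over the admission.

    Exactly 90.0 maps to HIGH_SAT (the split is <90 vs >=90).
    """
    spo2 = record.data["spo2"].to_numpy(dtype=float)
    spo2 = spo2[~np.isnan(spo2)]
    if spo2.size == 0:
        raise ValidationError("cannot stratify: all SpO2 values are missing")
    return Stratum.LOW_SAT if spo2.mean() < 90.0 else Stratum.HIGH_SAT


def cohort_inclusion_filter(
    record: PatientRecord,
    min_hours: float = 12.0,
    min_weight: float = 2000.0,
    max_age: float = 365.0,
) -> bool:
    """Cohort inclusion: enough complete data, adequate weight, infant age.

    ``True`` iff at least ``min_hours`` hours of seconds carry a complete
    5-parameter vector, birth weight >= ``min_weight`` grams, and age at
    admission < ``max_age`` days.
    """
    _, complete = parameter_matrix(record)
    if int(complete.sum()) < int(round(min_hours * 3600)):
        return False
    if not (record.birth_weight_g >= min_weight):
        return False
    return bool(record.age_days < max_age)


@dataclass
class StratumStatistics:
    """Per-stratum normalization statistics.

    ``mean``/``sd`` are per-parameter moments on the original scales;
    ``covariance`` is the covariance of the z-scored vectors (i.e. the
    correlation structure), ridge-regularized to positive definiteness.
    """

    stratum: Stratum
    mean: np.ndarray
    sd: np.ndarray
    covariance: np.ndarray
    schema_version: int = 1

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = len(PARAMETERS)
        if self.mean.shape != (k,) or self.sd.shape != (k,):
            raise ValidationError("mean and sd must be 5-vectors")
        if self.covariance.shape != (k, k):
            raise ValidationError("covariance must be 5x5")
        if not np.all(self.sd > 0):
            raise ValidationError("sd must be strictly positive")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance)[0] <= 0:
            raise ValidationError("covariance must be positive definite")


def fit_stratum_statistics(
    vectors: np.ndarray,
    stratum: Stratum = Stratum.LOW_SAT,
    ridge: float = 1e-6,
    min_vectors: int = 100,
) -> StratumStatistics:
    """Fit per-parameter moments and the z-score covariance for one stratum.

    Sample moments (ddof=1) over complete 5-vectors; if the z-score
    covariance is not positive definite, ``ridge * trace/5`` is added to the
    diagonal (escalating tenfold while needed).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(PARAMETERS):
        raise ValidationError("vectors must be an (n, 5) array")
    if np.isnan(X).any():
        raise ValidationError("vectors must be complete (no missing values)")
    if X.shape[0] < min_vectors:
        raise InsufficientDataError(
            f"need at least {min_vectors} complete vectors, got {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = [PARAMETERS[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance parameter(s): {zero}")
    z = (X - mean) / sd
    cov = np.cov(z, rowvar=False, ddof=1)
    lam = ridge * np.trace(cov) / cov.shape[0]
    for _ in range(8):
        try:
            np.linalg.cholesky(cov)
            break
        except np.linalg.LinAlgError:
            cov = cov + lam * np.eye(cov.shape[0])
            lam *= 10.0
    return StratumStatistics(stratum=stratum, mean=mean, sd=sd, covariance=cov)


def normalize(vectors: np.ndarray, stats: StratumStatistics) -> np.ndarray:
    """Elementwise z-scores ``(value - mean) / sd`` against stratum moments."""
    X = np.asarray(vectors, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("cannot normalize incomplete vectors")
    return (X - stats.mean) / stats.sd


# ---------------------------------------------------------------------------
# Text persistence of StratumStatistics (key/value + matrix rows)

def save_statistics(stats: StratumStatistics, path: str | Path) -> None:
    lines = [
        f"schema_version: {stats.schema_version}",
        f"stratum: {stats.stratum.value}",
        "mean: " + " ".join(repr(float(v)) for v in stats.mean),
        "sd: " + " ".join(repr(float(v)) for v in stats.sd),
        "covariance:",
    ]
    lines += ["  " + " ".join(repr(float(v)) for v in row) for row in stats.covariance]
    Path(path).write_text("\n".join(lines) + "\n")


def load_statistics(path: str | Path) -> StratumStatistics:
    lines = Path(path).read_text().splitlines()
    fields: dict[str, str] = {}
    rows: list[list[float]] = []
    in_matrix = False
    for line in lines:
        if in_matrix:
            rows.append([float(v) for v in line.split()])
        elif line.startswith("covariance:"):
            in_matrix = True
        else:
            key, _, value = line.partition(":")
            fields[key.strip()] = value.strip()
    return StratumStatistics(
        stratum=Stratum(fields["stratum"]),
        mean=np.array([float(v) for v in fields["mean"].split()]),
        sd=np.array([float(v) for v in fields["sd"].split()]),
        covariance=np.array(rows),
        schema_version=int(fields.get("schema_version", "1")),
    )
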