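"""Canonical data model and I/O for per-second vital-sign records.

A patient record is a contiguous 1 Hz grid of observations of five vital
parameters (heart rate, respiratory rate, SpO2, bilateral cerebral rSO2,
invasive mean blood pressure) plus end-tidal CO2, with explicit missingness
(NaN).  Time is integer seconds since admission start; the on-disk format is
a plain CSV with one row per observed second and empty cells for missing
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Column order of the stream CSV (after the leading ``t`` column).
VITAL_COLUMNS = ("hr", "rr", "spo2", "rso2_left", "rso2_right", "ibp_mean", "etco2")

#: Columns bounded to the 0-100 saturation scale.
_SATURATION_COLUMNS = ("spo2", "rso2_left", "rso2_right")


@dataclass
class PatientRecord:
    """A 1 Hz-aligned vital-sign series with patient metadata.

    Parameters
    ----------
    data
        DataFrame indexed by integer second ``t`` (contiguous, step 1) with
        float columns :data:`VITAL_COLUMNS`; NaN encodes a missing value.
    patient_id
        Opaque identifier.
    birth_weight_g
        Birth weight in grams (used by the cohort inclusion filter).
    age_days
        Age at admission in days.
    """

    data: pd.DataFrame
    patient_id: str = "anon"
    birth_weight_g: float = math.nan
    age_days: float = math.nan

    def __post_init__(self) -> None:
        missing = [c for c in VITAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"record is missing columns {missing}")
        t = self.data.index.to_numpy()
        if len(t) and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise ValidationError("record index must be a contiguous 1 Hz grid")
        for col in _SATURATION_COLUMNS:
            vals = self.data[col].to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 100)
            if np.any(bad[~np.isnan(vals)]):
                raise ValidationError(f"{col} values must lie in [0, 100]")

    @property
    def t(self) -> np.ndarray:
        """Integer second axis (seconds since admission start)."""
        return self.data.index.to_numpy()

    @property
    def duration(self) -> int:
        """Record length in seconds (grid length, including gap seconds)."""
        return len(self.data)

    def copy(self) -> "PatientRecord":
        return replace(self, data=self.data.copy())


def read_record(
    path: str | Path,
    *,
    patient_id: str | None = None,
    birth_weight_g: float = math.nan,
    age_days: float = math.nan,
) -> PatientRecord:
    """Read a stream CSV into a :class:`PatientRecord`.

    Rows are aligned to a 1 Hz grid starting at the first timestamp; gaps are
    filled with all-missing seconds and duplicate timestamps resolve
    last-wins.  Timestamps must be non-decreasing.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=float)
    expected = ("t",) + VITAL_COLUMNS
    if tuple(frame.columns) != expected:
        raise FormatError(
            f"{path}: header must be {','.join(expected)}, got {','.join(frame.columns)}"
        )
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    t = frame["t"].to_numpy()
    if np.any(np.isnan(t)) or np.any(t != np.round(t)):
        raise FormatError(f"{path}: t must be integer seconds")
    if np.any(np.diff(t) < 0):
        raise ValidationError(f"{path}: timestamps must be non-decreasing")
    frame["t"] = t.astype(np.int64)
    frame = frame.drop_duplicates(subset="t", keep="last").set_index("t")
    grid = np.arange(frame.index[0], frame.index[-1] + 1)
    frame = frame.reindex(grid)
    frame.index.name = "t"
    return PatientRecord(
        data=frame,
        patient_id=patient_id if patient_id is not None else path.stem,
        birth_weight_g=birth_weight_g,
        age_days=age_days,
    )


def write_record(record: PatientRecord, path: str | Path) -> None:
    """Write a record to the stream CSV format (empty cells for missing)."""
    # Default pandas float formatting is shortest-round-trip, so a written
    # record reads back value-identical (required for reproducible outputs).
    frame = record.data.reset_index()
    frame.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a patient metadata CSV (``patient_id,birth_weight_g,age_days``)."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    expected = {"patient_id", "birth_weight_g", "age_days"}
    if not expected.issubset(frame.columns):
        raise FormatError(f"{path}: metadata header must contain {sorted(expected)}")
    return frame.set_index("patient_id")


def write_metadata(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "birth_weight_g": r.birth_weight_g,
            "age_days": r.age_days,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
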