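"""Synthetic neonatal cCHD vital-sign generator with ground-truth labels.

Records are drawn around the stratified cohort profiles (cyanotic vs
acyanotic medians and IQR-derived dispersions) as correlated stationary
processes: each parameter is the sum of a slow AR(1) component (physiologic
wander, correlation time on the order of 15 minutes) and a fast AR(1)
component (beat-to-beat and sensor-level jitter, correlation time of
seconds).  Ground truth accompanies every record: injected deterioration
intervals, injected artifact seconds, and ventilation intervals.

The generator emulates stationary physiology, slow drifts, cross-parameter
correlation, ventilation episodes, deterioration events (smooth multi-
parameter shifts) and the artifact classes the dysfunction rules target.  It
does not emulate waveform morphology, pathology-specific hemodynamics, or
circadian structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .exceptions import ValidationError
from .preprocess import Stratum
from .records import PatientRecord

#: Parameter order used by the simulator (raw RR and a single true rSO2).
SIM_PARAMETERS = ("hr", "rr", "spo2", "rso2", "ibp_mean")

#: IQR -> SD conversion under normal theory.
IQR_TO_SD = 1.349


class EventKind(str, Enum):
    DETERIORATION = "DETERIORATION"
    ARTIFACT_JUMP = "ARTIFACT_JUMP"
    ARTIFACT_RSO2_RAIL = "ARTIFACT_RSO2_RAIL"
    ARTIFACT_RR_LOSS = "ARTIFACT_RR_LOSS"
    DROPOUT = "DROPOUT"
    VENTILATION = "VENTILATION"


@dataclass(frozen=True)
class InjectedEvent:
    """A scripted disturbance of the record.

    ``magnitude`` is a per-parameter shift in profile-SD units for
    DETERIORATION, the signed step in scale points for ARTIFACT_JUMP, and
    the rail value for ARTIFACT_RSO2_RAIL.  ``params`` selects the affected
    columns for DROPOUT and ARTIFACT_JUMP.
    """

    kind: EventKind
    start: int
    end: int
    magnitude: Mapping[str, float] | float | None = None
    ramp: int = 300
    params: tuple[str, ...] = ()


def _default_correlation() -> np.ndarray:
    corr = np.eye(5)
    i = {p: k for k, p in enumerate(SIM_PARAMETERS)}
    corr[i["hr"], i["rr"]] = corr[i["rr"], i["hr"]] = 0.3
    corr[i["spo2"], i["rso2"]] = corr[i["rso2"], i["spo2"]] = 0.5
    return corr


@dataclass(frozen=True)
class StratumProfile:
    """Generator parameters for one stratum.

    Central values and dispersions default to the stratified cohort medians
    and IQRs (SD = IQR / 1.349); dynamics split the dispersion between slow
    wander (AR(1), coefficient ``ar_slow``) and fast jitter (coefficient
    ``ar_fast``), with ``slow_frac`` of the SD in the slow component.
    """

    stratum: Stratum
    centers: Mapping[str, float]
    sds: Mapping[str, float]
    correlation: np.ndarray = field(default_factory=_default_correlation)
    clip: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hr": (50.0, 250.0),
            "rr": (6.0, 120.0),
            "spo2": (40.0, 100.0),
            "rso2": (16.0, 94.0),
            "ibp_mean": (10.0, 150.0),
        }
    )
    ar_slow: float = 0.999
    ar_fast: float = 0.9
    slow_frac: float = 0.3
    probe_sd: float = 2.0
    etco2_on: float = 5.0

    def __post_init__(self) -> None:
        if set(self.centers) != set(SIM_PARAMETERS) or set(self.sds) != set(
            SIM_PARAMETERS
        ):
            raise ValidationError(f"profile must define all of {SIM_PARAMETERS}")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ValidationError("correlation must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValidationError("correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr)[0] <= 0:
            raise ValidationError("correlation must be positive definite")
        for p in SIM_PARAMETERS:
            lo, hi = self.clip[p]
            if not lo <= self.centers[p] <= hi:
                raise ValidationError(f"clip range for {p} must contain its center")
        if not 0.0 <= self.slow_frac <= 1.0:
            raise ValidationError("slow_frac must lie in [0, 1]")

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sds[p] for p in SIM_PARAMETERS])


def _profile_from_iqr(
    stratum: Stratum, centers: dict[str, float], iqrs: dict[str, tuple[float, float]]
) -> StratumProfile:
    sds = {p: (q3 - q1) / IQR_TO_SD for p, (q1, q3) in iqrs.items()}
    return StratumProfile(stratum=stratum, centers=centers, sds=sds)


#: Cyanotic stratum (admission-mean SpO2 < 90%): cohort medians and IQRs.
LOW_SAT_PROFILE = _profile_from_iqr(
    Stratum.LOW_SAT,
    centers={"hr": 159.0, "rr": 34.0, "spo2": 77.0, "rso2": 55.0, "ibp_mean": 51.0},
    iqrs={
        "hr": (147.0, 170.0),
        "rr": (30.0, 38.0),
        "spo2": (70.0, 81.0),
        "rso2": (49.0, 63.0),
        "ibp_mean": (47.0, 57.0),
    },
)

#: Acyanotic stratum (admission-mean SpO2 >= 90%).
HIGH_SAT_PROFILE = _profile_from_iqr(
    Stratum.HIGH_SAT,
    centers={"hr": 146.0, "rr": 35.0, "spo2": 97.0, "rso2": 71.5, "ibp_mean": 53.0},
    iqrs={
        "hr": (132.0, 158.0),
        "rr": (30.0, 40.0),
        "spo2": (95.0, 100.0),
        "rso2": (63.5, 80.0),
        "ibp_mean": (47.0, 60.0),
    },
)

PROFILES: Mapping[Stratum, StratumProfile] = {
    Stratum.LOW_SAT: LOW_SAT_PROFILE,
    Stratum.HIGH_SAT: HIGH_SAT_PROFILE,
}


def _ar1(rng: np.random.Generator, n: int, phi: float, chol: np.ndarray) -> np.ndarray:
    """Stationary 5-dim AR(1) with unit marginal variance and given
    cross-sectional correlation (Cholesky factor)."""
    eps = rng.standard_normal((n, 5)) @ chol.T * math.sqrt(1.0 - phi * phi)
    x0 = rng.standard_normal(5) @ chol.T
    zi = (phi * x0)[None, :]
    out, _ = lfilter([1.0], [1.0, -phi], eps, axis=0, zi=zi)
    return out


@dataclass
class GroundTruth:
    """Per-second truth labels accompanying a synthetic record."""

    frame: pd.DataFrame  # columns: t, unstable (bool), artifact (bool)

    @property
    def unstable(self) -> np.ndarray:
        return self.frame["unstable"].to_numpy(dtype=bool)

    @property
    def artifact(self) -> np.ndarray:
        return self.frame["artifact"].to_numpy(dtype=bool)

    def timeline(self, warmup: int = 3600) -> np.ndarray:
        """Truth label names per second (WARMUP/SENSOR_DYSFUNCTION/UNSTABLE/
        STABLE, with dysfunction taking precedence over instability)."""
        t = self.frame["t"].to_numpy()
        return np.select(
            [t < warmup, self.artifact, self.unstable],
            ["WARMUP", "SENSOR_DYSFUNCTION", "UNSTABLE"],
            default="STABLE",
        ).astype(object)


def generate_record(
    profile: StratumProfile,
    duration: int,
    seed: int,
    patient_id: str | None = None,
    birth_weight_g: float = 3400.0,
    age_days: float = 7.0,
) -> tuple[PatientRecord, GroundTruth]:
    """Draw an all-stable record of ``duration`` seconds (>= 7200).

    Reproducible per seed; EtCO2 is zero everywhere (ventilation intervals
    are injected separately).
    """
    if duration < 7200:
        raise ValidationError("duration must be at least 7200 seconds")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(np.asarray(profile.correlation, dtype=float))
    slow = _ar1(rng, duration, profile.ar_slow, chol)
    fast = _ar1(rng, duration, profile.ar_fast, np.eye(5))
    w_slow = profile.slow_frac
    w_fast = math.sqrt(max(0.0, 1.0 - w_slow * w_slow))
    signal = w_slow * slow + w_fast * fast
    centers = np.array([profile.centers[p] for p in SIM_PARAMETERS])
    values = centers + profile.sd_vector() * signal
    cols: dict[str, np.ndarray] = {}
    for j, p in enumerate(SIM_PARAMETERS):
        lo, hi = profile.clip[p]
        cols[p] = np.clip(values[:, j], lo, hi)
    lo, hi = profile.clip["rso2"]
    probe_noise = rng.standard_normal((duration, 2)) * profile.probe_sd
    rso2_left = np.clip(cols["rso2"] + probe_noise[:, 0], lo, hi)
    rso2_right = np.clip(cols["rso2"] + probe_noise[:, 1], lo, hi)
    frame = pd.DataFrame(
        {
            "hr": cols["hr"],
            "rr": cols["rr"],
            "spo2": cols["spo2"],
            "rso2_left": rso2_left,
            "rso2_right": rso2_right,
            "ibp_mean": cols["ibp_mean"],
            "etco2": np.zeros(duration),
        },
        index=pd.RangeIndex(duration, name="t"),
    )
    record = PatientRecord(
        data=frame,
        patient_id=patient_id or f"sim-{profile.stratum.value.lower()}-{seed}",
        birth_weight_g=birth_weight_g,
        age_days=age_days,
    )
    truth = GroundTruth(
        frame=pd.DataFrame(
            {
                "t": np.arange(duration),
                "unstable": np.zeros(duration, dtype=bool),
                "artifact": np.zeros(duration, dtype=bool),
            }
        )
    )
    return record, truth


def _check_span(record: PatientRecord, event: InjectedEvent) -> None:
    if not 0 <= event.start < event.end <= record.duration - 1:
        raise ValidationError(
            f"event [{event.start}, {event.end}] outside record of "
            f"duration {record.duration}"
        )


def inject_deterioration(
    record: PatientRecord,
    truth: GroundTruth,
    event: InjectedEvent,
    profile: StratumProfile,
) -> tuple[PatientRecord, GroundTruth]:
    """Superimpose a smooth multi-parameter deterioration.

    The per-parameter shifts (profile-SD units) follow a logistic ramp over
    ``[start, start+ramp]``, hold to ``end``, then ramp back.  Truth marks
    ``[start, end]`` unstable.  Overlapping deterioration events are
    rejected.
    """
    _check_span(record, event)
    magnitude = event.magnitude or {"hr": 5.0, "ibp_mean": -5.0, "rso2": -5.0}
    if not isinstance(magnitude, Mapping) or len(magnitude) < 2:
        raise ValidationError("deterioration magnitude must shift >= 2 parameters")
    if truth.unstable[event.start : event.end + 1].any():
        raise ValidationError("overlapping deterioration events")
    record = record.copy()
    truth = GroundTruth(frame=truth.frame.copy())
    tt = np.arange(record.duration, dtype=float)
    scale = max(event.ramp / 8.0, 1.0)
    shape = expit((tt - (event.start + event.ramp / 2.0)) / scale) - expit(
        (tt - (event.end + event.ramp / 2.0)) / scale
    )
    for p, mag in magnitude.items():
        if p not in SIM_PARAMETERS:
            raise ValidationError(f"unknown deterioration parameter: {p}")
        shift = mag * profile.sds[p] * shape
        lo, hi = profile.clip[p]
        if p == "rso2":
            for col in ("rso2_left", "rso2_right"):
                record.data[col] = np.clip(record.data[col] + shift, lo, hi)
        else:
            record.data[p] = np.clip(record.data[p] + shift, lo, hi)
    truth.frame.loc[event.start : event.end, "unstable"] = True
    return record, truth


def apply_ventilation(
    record: PatientRecord, event: InjectedEvent, level: float | None = None
) -> PatientRecord:
    """Mark ``[start, end]`` as mechanically ventilated (EtCO2 > 0)."""
    _check_span(record, event)
    record = record.copy()
    value = level if level is not None else float(event.magnitude or 5.0)
    record.data.iloc[
        event.start : event.end + 1, record.data.columns.get_loc("etco2")
    ] = value
    return record


_JUMP_HOLD = 5
_JUMP_DECAY_STEPS = 4


def inject_artifacts(
    record: PatientRecord,
    truth: GroundTruth,
    events: Sequence[InjectedEvent],
    seed: int = 0,
) -> tuple[PatientRecord, GroundTruth]:
    """Superimpose sensor artifacts and record the artifact truth mask.

    ARTIFACT_JUMP steps the chosen channel by >25 points at ``start``, holds
    briefly, then decays in sub-threshold steps (so exactly one jump event
    fires); ARTIFACT_RSO2_RAIL rails both probes; ARTIFACT_RR_LOSS drops RR
    below the malfunction floor; DROPOUT sets channels missing (not an
    artifact in truth -- missing data yields UNKNOWN, not dysfunction).
    """
    record = record.copy()
    truth = GroundTruth(frame=truth.frame.copy())
    artifact = truth.frame["artifact"].to_numpy(dtype=bool).copy()
    data = record.data
    for event in events:
        _check_span(record, event)
        if event.kind == EventKind.ARTIFACT_JUMP:
            param = event.params[0] if event.params else "ibp_mean"
            mag = float(event.magnitude) if event.magnitude is not None else 30.0
            hold_end = min(event.end, event.start + _JUMP_HOLD)
            offset = np.zeros(record.duration)
            offset[event.start : hold_end + 1] = mag
            for k in range(1, _JUMP_DECAY_STEPS):
                i = hold_end + k
                if i < record.duration:
                    offset[i] = mag * (1.0 - k / _JUMP_DECAY_STEPS)
            col = data[param].to_numpy() + offset
            if param in ("spo2",):
                col = np.clip(col, 0.0, 100.0)
            data[param] = col
            artifact[event.start : min(hold_end + _JUMP_DECAY_STEPS, record.duration - 1) + 1] = True
        elif event.kind == EventKind.ARTIFACT_RSO2_RAIL:
            rail = float(event.magnitude) if event.magnitude is not None else 98.0
            rail = min(max(rail, 0.0), 100.0)
            data.iloc[
                event.start : event.end + 1, data.columns.get_loc("rso2_left")
            ] = rail
            data.iloc[
                event.start : event.end + 1, data.columns.get_loc("rso2_right")
            ] = rail
            artifact[event.start : event.end + 1] = True
        elif event.kind == EventKind.ARTIFACT_RR_LOSS:
            value = float(event.magnitude) if event.magnitude is not None else 0.0
            data.iloc[event.start : event.end + 1, data.columns.get_loc("rr")] = value
            artifact[event.start : event.end + 1] = True
        elif event.kind == EventKind.DROPOUT:
            params = event.params or ("hr", "rr", "spo2", "rso2_left", "rso2_right", "ibp_mean")
            for p in params:
                data.iloc[event.start : event.end + 1, data.columns.get_loc(p)] = np.nan
        else:
            raise ValidationError(f"not an artifact event: {event.kind}")
    truth.frame["artifact"] = artifact
    return record, truth


def simulate(
    stratum: Stratum | str,
    duration: int,
    seed: int,
    events: Sequence[InjectedEvent] = (),
    profile: StratumProfile | None = None,
) -> tuple[PatientRecord, GroundTruth]:
    """Generate a record and apply a scripted event list in one call."""
    stratum = Stratum(stratum)
    profile = profile or PROFILES[stratum]
    record, truth = generate_record(profile, duration, seed)
    artifact_events = [
        e
        for e in events
        if e.kind
        in (
            EventKind.ARTIFACT_JUMP,
            EventKind.ARTIFACT_RSO2_RAIL,
            EventKind.ARTIFACT_RR_LOSS,
            EventKind.DROPOUT,
        )
    ]
    for event in events:
        if event.kind == EventKind.DETERIORATION:
            record, truth = inject_deterioration(record, truth, event, profile)
        elif event.kind == EventKind.VENTILATION:
            record = apply_ventilation(record, event)
    if artifact_events:
        record, truth = inject_artifacts(record, truth, artifact_events, seed=seed)
    return record, truth
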