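"""Sensor-dysfunction rules (submodel 1).

Per-second artifact rules: a >25-point jump between consecutive IBP or SpO2
readings, cerebral rSO2 at the scale limits (<=15% or >=95%, where escaping
sensor light rather than physiology is the likely source), and an RR reading
below 5 breaths/min.  Each contiguous run of detections is expanded by one
minute on both sides; flagged seconds are excluded from patient-status
classification.  Heart rate has no dysfunction rule: a true arrest and a
detached lead are indistinguishable from the numeric stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .preprocess import fuse_rso2
from .records import PatientRecord

JUMP_THRESHOLD = 25.0
RSO2_LOW = 15.0
RSO2_HIGH = 95.0
RR_FLOOR = 5.0
WINDOW_PAD = 60


def detect_jump(series: np.ndarray, threshold: float = JUMP_THRESHOLD) -> np.ndarray:
    """Event at t iff |x[t] - x[t-1]| strictly exceeds ``threshold``.

    Both seconds must be non-missing; gaps are not bridged.
    """
    x = np.asarray(series, dtype=float)
    events = np.zeros(x.shape, dtype=bool)
    if x.size < 2:
        return events
    diff = np.abs(x[1:] - x[:-1])
    ok = ~np.isnan(x[1:]) & ~np.isnan(x[:-1])
    events[1:] = ok & (diff > threshold)
    return events


def detect_rso2_limit(
    series: np.ndarray, low: float = RSO2_LOW, high: float = RSO2_HIGH
) -> np.ndarray:
    """Event at t iff the rSO2 reading sits at the scale limits (<=low or >=high)."""
    x = np.asarray(series, dtype=float)
    valid = ~np.isnan(x)
    return valid & ((x <= low) | (x >= high))


def detect_rr_malfunction(series: np.ndarray, floor: float = RR_FLOOR) -> np.ndarray:
    """Event at t iff the raw (unsmoothed) RR reading is strictly below ``floor``."""
    x = np.asarray(series, dtype=float)
    valid = ~np.isnan(x)
    return valid & (x < floor)


def expand_events(events: np.ndarray, pad: int = WINDOW_PAD) -> np.ndarray:
    """Expand per-second events into the +/-pad dysfunction window.

    Each contiguous detection run [first, last] flags [first-pad, last+pad]
    (clipped to the record); the union over runs equals a +/-pad binary
    dilation of the event indicator, which is how it is computed.
    """
    events = np.asarray(events, dtype=bool)
    if not events.any():
        return np.zeros_like(events)
    structure = np.ones(2 * pad + 1, dtype=bool)
    return binary_dilation(events, structure=structure)


@dataclass
class DysfunctionMask:
    """Combined dysfunction mask with per-parameter provenance.

    ``combined[t]`` is True iff any parameter's expanded window covers second
    t; ``per_parameter`` maps parameter name to its own expanded mask and
    ``events`` to the raw (unexpanded) detection seconds.
    """

    combined: np.ndarray
    per_parameter: Mapping[str, np.ndarray]
    events: Mapping[str, np.ndarray]
    t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def provenance(self, i: int) -> tuple[str, ...]:
        """Parameters whose expanded window covers grid position ``i``."""
        return tuple(p for p, m in self.per_parameter.items() if m[i])

    def to_frame(self) -> pd.DataFrame:
        params = [
            ";".join(p for p, m in self.per_parameter.items() if m[i]) if f else ""
            for i, f in enumerate(self.combined)
        ]
        t = self.t if self.t is not None else np.arange(len(self.combined))
        return pd.DataFrame(
            {"t": t, "dysfunction": self.combined.astype(int), "parameters": params}
        )


class SensorFaultDetector:
    """Configurable submodel-1 rule set producing a :class:`DysfunctionMask`.

    All thresholds default to the published rule constants; the rSO2 limit
    rule is applied both to the fused value and to each raw probe (a railing
    probe is an artifact even when the other probe is valid).
    """

    def __init__(
        self,
        jump_threshold: float = JUMP_THRESHOLD,
        rso2_low: float = RSO2_LOW,
        rso2_high: float = RSO2_HIGH,
        rr_floor: float = RR_FLOOR,
        pad: int = WINDOW_PAD,
    ) -> None:
        self.jump_threshold = jump_threshold
        self.rso2_low = rso2_low
        self.rso2_high = rso2_high
        self.rr_floor = rr_floor
        self.pad = pad

    def detect(self, record: PatientRecord) -> DysfunctionMask:
        d = record.data
        rso2_fused = fuse_rso2(d["rso2_left"].to_numpy(), d["rso2_right"].to_numpy())
        events = {
            "ibp_mean": detect_jump(d["ibp_mean"].to_numpy(), self.jump_threshold),
            "spo2": detect_jump(d["spo2"].to_numpy(), self.jump_threshold),
            "rso2": (
                detect_rso2_limit(rso2_fused, self.rso2_low, self.rso2_high)
                | detect_rso2_limit(
                    d["rso2_left"].to_numpy(), self.rso2_low, self.rso2_high
                )
                | detect_rso2_limit(
                    d["rso2_right"].to_numpy(), self.rso2_low, self.rso2_high
                )
            ),
            "rr": detect_rr_malfunction(d["rr"].to_numpy(), self.rr_floor),
        }
        per_parameter = {p: expand_events(e, self.pad) for p, e in events.items()}
        combined = np.zeros(record.duration, dtype=bool)
        for mask in per_parameter.values():
            combined |= mask
        return DysfunctionMask(
            combined=combined, per_parameter=per_parameter, events=events, t=record.t
        )


def export_mask(mask: DysfunctionMask, path: str | Path) -> None:
    """Write the mask CSV ``t,dysfunction,parameters``."""
    mask.to_frame().to_csv(path, index=False)
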