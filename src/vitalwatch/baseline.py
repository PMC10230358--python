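"""Patient-specific baseline-deviation analysis (submodel 3).

The per-second Mahalanobis distance stream d(t) is inflated by 20% while the
patient is mechanically ventilated (EtCO2 > 0), because ventilation
iatrogenically damps parameter variation.  The current trend Z (300-second
moving median preceding t) is compared with the patient's unique baseline B
(median of all adjusted distances preceding t).  Movement toward the
population mean (Z - B < 0) reads as clinical improvement; a drift of at
least 2 SD above baseline (Z - B >= +2 SD) reads as instability, where the
SD is taken causally over the baseline-corrected distances after dropping
their upper 20th percentile (the noise scale of the presumed-stable
seconds).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

VENT_MULTIPLIER = 1.2
TREND_WINDOW = 300
TREND_MIN_OBS = 150
TRIM_PERCENTILE = 20.0
SD_MIN_HISTORY = 600
SD_CADENCE = 60
WARMUP_SECONDS = 3600
DEVIATION_K = 2.0

STABLE = "STABLE"
UNSTABLE = "UNSTABLE"
IMPROVEMENT = "IMPROVEMENT"


class StreamingMedian:
    """Exact running median over an append-only stream (two-heap method)."""

    def __init__(self) -> None:
        self._lo: list[float] = []  # max-heap (negated): lower half
        self._hi: list[float] = []  # min-heap: upper half

    def __len__(self) -> int:
        return len(self._lo) + len(self._hi)

    def push(self, value: float) -> None:
        if self._lo and value > -self._lo[0]:
            heapq.heappush(self._hi, value)
        else:
            heapq.heappush(self._lo, -value)
        # rebalance so len(lo) == len(hi) or len(lo) == len(hi) + 1
        if len(self._lo) > len(self._hi) + 1:
            heapq.heappush(self._hi, -heapq.heappop(self._lo))
        elif len(self._hi) > len(self._lo):
            heapq.heappush(self._lo, -heapq.heappop(self._hi))

    @property
    def median(self) -> float:
        if not self._lo:
            raise ValueError("median of empty stream")
        if len(self._lo) > len(self._hi):
            return -self._lo[0]
        return (-self._lo[0] + self._hi[0]) / 2.0


def adjust_for_ventilation(
    d: float | np.ndarray, ventilated, multiplier: float = VENT_MULTIPLIER
):
    """Inflate the distance by the ventilation multiplier where ventilated."""
    d = np.asarray(d, dtype=float)
    out = np.where(np.asarray(ventilated, dtype=bool), d * multiplier, d)
    return float(out) if out.ndim == 0 else out


def trend_median(
    d_adj: np.ndarray, window: int = TREND_WINDOW, min_obs: int = TREND_MIN_OBS
) -> np.ndarray:
    """Trend Z: moving median of defined d' over ``[t-window, t-1]``.

    NaN where fewer than ``min_obs`` defined values fall in the window.
    """
    s = pd.Series(np.asarray(d_adj, dtype=float))
    return s.shift(1).rolling(window=window, min_periods=min_obs).median().to_numpy()


def trimmed_sd(values: np.ndarray, trim_percentile: float = TRIM_PERCENTILE) -> float:
    """Sample SD after dropping the largest ``trim_percentile`` % of values.

    ``floor(n * trim/100)`` values are removed from the top; ddof=1 on the
    remainder (0.0 when fewer than two values remain or all are equal).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    m = int(math.floor(n * trim_percentile / 100.0))
    if n - m < 2:
        return 0.0
    kept = np.partition(v, n - m - 1)[: n - m] if m > 0 else v
    return float(np.std(kept, ddof=1))


def classify_deviation(zb_delta: float, sd: float, k: float = DEVIATION_K) -> str:
    """Submodel-3 label from the trend-baseline gap.

    IMPROVEMENT if Z-B < 0, UNSTABLE if Z-B >= k*SD, STABLE otherwise.
    IMPROVEMENT counts as non-unstable downstream.
    """
    if zb_delta < 0:
        return IMPROVEMENT
    if zb_delta >= k * sd:
        return UNSTABLE
    return STABLE


@dataclass
class BaselineTrace:
    """Per-second diagnostic trace of the baseline analysis.

    ``labels`` holds -1 (undefined), 0 (stable/improvement) or 1 (unstable);
    the frame columns mirror the diagnostic CSV layout.
    """

    frame: pd.DataFrame
    labels: np.ndarray


class BaselineTracker:
    """Causal driver of the submodel-3 state over one patient record.

    Everything is computed strictly from history: B(t) and Z(t) use samples
    before t only, the trimmed SD is refreshed on a fixed cadence from the
    baseline-corrected values accumulated so far, and no label is emitted
    during the first warm-up hour (state still accumulates).
    """

    def __init__(
        self,
        window: int = TREND_WINDOW,
        min_obs: int = TREND_MIN_OBS,
        k: float = DEVIATION_K,
        trim_percentile: float = TRIM_PERCENTILE,
        vent_multiplier: float = VENT_MULTIPLIER,
        sd_min_history: int = SD_MIN_HISTORY,
        sd_cadence: int = SD_CADENCE,
        warmup: int = WARMUP_SECONDS,
    ) -> None:
        self.window = window
        self.min_obs = min_obs
        self.k = k
        self.trim_percentile = trim_percentile
        self.vent_multiplier = vent_multiplier
        self.sd_min_history = sd_min_history
        self.sd_cadence = sd_cadence
        self.warmup = warmup

    def run(
        self,
        distances: np.ndarray,
        ventilated: np.ndarray,
        t: np.ndarray | None = None,
    ) -> BaselineTrace:
        """Process a full distance stream (NaN = no sample at that second).

        Parameters
        ----------
        distances
            Per-second raw Mahalanobis distances; NaN where the parameter
            vector was incomplete or masked as sensor dysfunction.
        ventilated
            Per-second mechanical-ventilation flag.
        t
            Absolute second axis (defaults to ``0..n-1``); the warm-up gate
            compares against absolute time since admission.
        """
        d = np.asarray(distances, dtype=float)
        vent = np.asarray(ventilated, dtype=bool)
        n = d.size
        tt = np.arange(n) if t is None else np.asarray(t)
        defined = ~np.isnan(d)
        d_adj = adjust_for_ventilation(d, vent, self.vent_multiplier)
        Z = trend_median(d_adj, self.window, self.min_obs)

        B = np.full(n, np.nan)
        SD = np.full(n, np.nan)
        med = StreamingMedian()
        corrected: list[float] = []
        current_sd = np.nan
        for i in range(n):
            if i % self.sd_cadence == 0:
                if len(corrected) >= self.sd_min_history:
                    current_sd = trimmed_sd(
                        np.asarray(corrected), self.trim_percentile
                    )
                else:
                    current_sd = np.nan
            if len(med):
                B[i] = med.median
            SD[i] = current_sd
            if defined[i]:
                if not np.isnan(B[i]):
                    corrected.append(d_adj[i] - B[i])
                med.push(d_adj[i])

        zb = Z - B
        valid = ~np.isnan(Z) & ~np.isnan(B) & ~np.isnan(SD) & (tt >= self.warmup)
        labels = np.full(n, -1, dtype=np.int8)
        labels[valid & (zb >= 0) & (zb < self.k * SD)] = 0
        labels[valid & (zb < 0)] = 0  # improvement: non-unstable
        labels[valid & (zb >= self.k * SD)] = 1
        # keep the three-way reading available in the trace
        label3 = np.full(n, "", dtype=object)
        label3[valid & (zb < 0)] = IMPROVEMENT
        label3[valid & (zb >= self.k * SD)] = UNSTABLE
        label3[valid & (zb >= 0) & (zb < self.k * SD)] = STABLE
        frame = pd.DataFrame(
            {
                "t": tt,
                "d_adj": d_adj,
                "Z": Z,
                "B": B,
                "SD": SD,
                "zb_delta": zb,
                "label3": label3,
            }
        )
        return BaselineTrace(frame=frame, labels=labels)
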