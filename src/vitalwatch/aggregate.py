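"""Fusion of submodel outputs and episode aggregation.

Per-second fusion gives sensor dysfunction precedence over any stability
verdict; a second is UNSTABLE only when free of dysfunction and flagged by
the combination model, the baseline model, or both.  The per-second stream
is then smoothed with the 4-of-5-minute rule (a second is unstable when at
least 240 of the trailing 300 seconds were raw-unstable, nonconsecutive
seconds counting) and cut into maximal constant-label episodes, capped at
two consecutive hours for counting purposes.  No label is emitted during the
first hour of admission (baseline warm-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WARMUP_SECONDS = 3600
SMOOTH_WINDOW = 300
SMOOTH_MIN_UNSTABLE = 240
EPISODE_CAP = 7200
UNKNOWN_GAP = 60

# integer label codes used throughout the aggregation layer
WARMUP, UNKNOWN, SENSOR_DYSFUNCTION, STABLE, UNSTABLE = range(5)
LABEL_NAMES = ("WARMUP", "UNKNOWN", "SENSOR_DYSFUNCTION", "STABLE", "UNSTABLE")
LABEL_CODES = {name: code for code, name in enumerate(LABEL_NAMES)}

# submodel verdict codes fed into fusion: no output / non-unstable / unstable
SUB_NONE, SUB_STABLE, SUB_UNSTABLE = -1, 0, 1


def fuse_seconds(
    t: np.ndarray,
    dysfunction: np.ndarray,
    s2: np.ndarray,
    s3: np.ndarray,
    warmup: int = WARMUP_SECONDS,
) -> np.ndarray:
    """Combine the three submodels into one per-second label code array.

    Precedence: WARMUP (t < warmup), then SENSOR_DYSFUNCTION, then UNKNOWN
    (neither submodel produced a verdict), then UNSTABLE (either submodel),
    else STABLE.
    """
    t = np.asarray(t)
    s2 = np.asarray(s2)
    s3 = np.asarray(s3)
    dysfunction = np.asarray(dysfunction, dtype=bool)
    return np.select(
        [
            t < warmup,
            dysfunction,
            (s2 == SUB_NONE) & (s3 == SUB_NONE),
            (s2 == SUB_UNSTABLE) | (s3 == SUB_UNSTABLE),
        ],
        [WARMUP, SENSOR_DYSFUNCTION, UNKNOWN, UNSTABLE],
        default=STABLE,
    ).astype(np.int8)


def smooth_labels(
    labels: np.ndarray,
    window: int = SMOOTH_WINDOW,
    min_unstable: int = SMOOTH_MIN_UNSTABLE,
) -> np.ndarray:
    """Apply the 4-of-5-minute rule to the raw fused labels.

    A STABLE/UNSTABLE second becomes UNSTABLE iff at least ``min_unstable``
    of the trailing ``window`` seconds (including itself) are raw UNSTABLE;
    otherwise STABLE.  WARMUP/UNKNOWN/SENSOR_DYSFUNCTION pass through, and
    such seconds count as non-unstable inside the window.
    """
    labels = np.asarray(labels)
    unstable = (labels == UNSTABLE).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(unstable)])
    idx = np.arange(labels.size)
    lo = np.maximum(idx - window + 1, 0)
    counts = csum[idx + 1] - csum[lo]
    out = labels.copy()
    classifiable = (labels == STABLE) | (labels == UNSTABLE)
    out[classifiable] = np.where(counts[classifiable] >= min_unstable, UNSTABLE, STABLE)
    return out


@dataclass(frozen=True)
class Episode:
    """A maximal constant-label stretch (inclusive bounds), cap-split."""

    start: int
    end: int
    label: str

    @property
    def duration(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "Episode") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """(start_idx, end_idx, code) for maximal constant runs."""
    if codes.size == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [codes.size - 1]])
    return [(int(s), int(e), int(codes[s])) for s, e in zip(starts, ends)]


def segment_episodes(
    smoothed: np.ndarray,
    t: np.ndarray | None = None,
    cap: int = EPISODE_CAP,
    unknown_gap: int = UNKNOWN_GAP,
) -> list[Episode]:
    """Convert the smoothed per-second labels into counted episodes.

    WARMUP and UNKNOWN seconds never belong to episodes, except that an
    UNKNOWN run of at most ``unknown_gap`` seconds flanked by the same label
    on both sides is absorbed into that episode.  Runs longer than ``cap``
    seconds are split left-to-right into chunks of at most ``cap``.
    """
    codes = np.asarray(smoothed).copy()
    tt = np.arange(codes.size) if t is None else np.asarray(t)
    runs = _runs(codes)
    for i, (s, e, c) in enumerate(runs):
        if (
            c == UNKNOWN
            and e - s + 1 <= unknown_gap
            and 0 < i < len(runs) - 1
            and runs[i - 1][2] == runs[i + 1][2]
            and runs[i - 1][2] in (STABLE, UNSTABLE, SENSOR_DYSFUNCTION)
        ):
            codes[s : e + 1] = runs[i - 1][2]
    episodes: list[Episode] = []
    for s, e, c in _runs(codes):
        if c not in (STABLE, UNSTABLE, SENSOR_DYSFUNCTION):
            continue
        chunk_start = s
        while chunk_start <= e:
            chunk_end = min(chunk_start + cap - 1, e)
            episodes.append(
                Episode(
                    start=int(tt[chunk_start]),
                    end=int(tt[chunk_end]),
                    label=LABEL_NAMES[c],
                )
            )
            chunk_start = chunk_end + 1
    return episodes


def episodes_to_frame(episodes: list[Episode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"start": ep.start, "end": ep.end, "label": ep.label, "duration_s": ep.duration}
            for ep in episodes
        ],
        columns=["start", "end", "label", "duration_s"],
    )


def labels_to_names(codes: np.ndarray) -> np.ndarray:
    return np.asarray(LABEL_NAMES, dtype=object)[np.asarray(codes)]
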