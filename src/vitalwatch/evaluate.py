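"""Performance scoring in the episodic / time-percentual scheme.

The reference evaluation of this method scored the detector against
expert adjudication; with
synthetic ground truth the analogue is interval overlap: a truth episode
counts as correctly detected when at least one predicted episode of the same
class overlaps it, and as "partially correct" when the total same-class
overlap covers less than half of its duration.  Time-percentual correctness
is the per-class fraction of truth seconds carrying the matching predicted
label.  Warm-up and unknown (missing-data) seconds are excluded from all
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import EPISODE_CAP, Episode
from .exceptions import ValidationError

SCORED_CLASSES = ("STABLE", "UNSTABLE", "SENSOR_DYSFUNCTION")
_EXCLUDED = ("WARMUP", "UNKNOWN")


@dataclass
class ClassScore:
    """Scores for one label class within one stratum."""

    episodic_occurrence: int = 0
    episodic_correct: int = 0
    episodic_partial: int = 0
    time_occurrence_h: float = 0.0
    time_correct_h: float = 0.0

    @property
    def episodic_pct(self) -> float:
        if self.episodic_occurrence == 0:
            return float("nan")
        return 100.0 * self.episodic_correct / self.episodic_occurrence

    @property
    def time_pct(self) -> float:
        if self.time_occurrence_h == 0:
            return float("nan")
        return 100.0 * self.time_correct_h / self.time_occurrence_h

    def __iadd__(self, other: "ClassScore") -> "ClassScore":
        self.episodic_occurrence += other.episodic_occurrence
        self.episodic_correct += other.episodic_correct
        self.episodic_partial += other.episodic_partial
        self.time_occurrence_h += other.time_occurrence_h
        self.time_correct_h += other.time_correct_h
        return self


def split_at_cap(episodes: Sequence[Episode], cap: int = EPISODE_CAP) -> list[Episode]:
    """Split episodes left-to-right into chunks of at most ``cap`` seconds."""
    out: list[Episode] = []
    for ep in episodes:
        start = ep.start
        while start <= ep.end:
            end = min(start + cap - 1, ep.end)
            out.append(Episode(start=start, end=end, label=ep.label))
            start = end + 1
    return out


def episodic_score(
    predicted: Sequence[Episode],
    truth: Sequence[Episode],
    match_fraction: float = 0.5,
    cap: int = EPISODE_CAP,
) -> dict[str, ClassScore]:
    """Count truth episodes detected by same-class predicted episodes.

    Truth episodes are pre-split at the cap.  A truth episode is correct if
    any same-class predicted episode overlaps it by at least one second, and
    additionally partial if the summed same-class overlap is below
    ``match_fraction`` of its duration.
    """
    scores = {c: ClassScore() for c in SCORED_CLASSES}
    by_class: dict[str, list[Episode]] = {c: [] for c in SCORED_CLASSES}
    for ep in predicted:
        if ep.label in by_class:
            by_class[ep.label].append(ep)
    for ep in split_at_cap(truth, cap):
        if ep.label not in scores:
            continue
        score = scores[ep.label]
        score.episodic_occurrence += 1
        overlap = sum(ep.overlap(p) for p in by_class[ep.label])
        if overlap >= 1:
            score.episodic_correct += 1
            if overlap < match_fraction * ep.duration:
                score.episodic_partial += 1
    return scores


def time_score(
    predicted_labels: np.ndarray, truth_labels: np.ndarray
) -> dict[str, ClassScore]:
    """Per-class occurrence hours and correctly-labelled hours.

    Seconds where either stream is WARMUP or UNKNOWN are excluded from both
    numerator and denominator.
    """
    pred = np.asarray(predicted_labels, dtype=object)
    truth = np.asarray(truth_labels, dtype=object)
    if pred.shape != truth.shape:
        raise ValidationError("predicted and truth label streams differ in length")
    valid = ~np.isin(pred, _EXCLUDED) & ~np.isin(truth, _EXCLUDED)
    scores = {c: ClassScore() for c in SCORED_CLASSES}
    for c in SCORED_CLASSES:
        occ = valid & (truth == c)
        scores[c].time_occurrence_h = float(occ.sum()) / 3600.0
        scores[c].time_correct_h = float((occ & (pred == c)).sum()) / 3600.0
    return scores


def merge_scores(
    episodic: Mapping[str, ClassScore], time: Mapping[str, ClassScore]
) -> dict[str, ClassScore]:
    out = {}
    for c in SCORED_CLASSES:
        s = ClassScore()
        s += episodic[c]
        s.time_occurrence_h = time[c].time_occurrence_h
        s.time_correct_h = time[c].time_correct_h
        out[c] = s
    return out


@dataclass
class PerformanceReport:
    """Per-stratum and overall scores for every label class."""

    strata: dict[str, dict[str, ClassScore]] = field(default_factory=dict)
    cutoffs_note: str = ""

    def add_stratum(self, name: str, scores: dict[str, ClassScore]) -> None:
        self.strata[name] = scores

    @property
    def overall(self) -> dict[str, ClassScore]:
        out = {c: ClassScore() for c in SCORED_CLASSES}
        for scores in self.strata.values():
            for c in SCORED_CLASSES:
                out[c] += scores[c]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        named = list(self.strata.items()) + [("Total", self.overall)]
        for stratum, scores in named:
            for c in SCORED_CLASSES:
                s = scores[c]
                rows.append(
                    {
                        "stratum": stratum,
                        "class": c,
                        "episodic_occurrence": s.episodic_occurrence,
                        "episodic_correct": s.episodic_correct,
                        "episodic_correct_pct": round(s.episodic_pct, 1),
                        "episodic_partial": s.episodic_partial,
                        "time_occurrence_h": round(s.time_occurrence_h, 2),
                        "time_correct_h": round(s.time_correct_h, 2),
                        "time_correct_pct": round(s.time_pct, 1),
                    }
                )
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        lines = ["Performance analysis overview", "=" * 29]
        named = list(self.strata.items()) + [("Total", self.overall)]
        for stratum, scores in named:
            lines.append(f"\n[{stratum}]")
            for c in SCORED_CLASSES:
                s = scores[c]
                ep_pct = "n/a" if s.episodic_occurrence == 0 else f"{s.episodic_pct:.0f}%"
                tm_pct = "n/a" if s.time_occurrence_h == 0 else f"{s.time_pct:.0f}%"
                lines.append(
                    f"  {c:<20s} episodes {s.episodic_correct}/{s.episodic_occurrence}"
                    f" ({ep_pct})"
                    + (f", {s.episodic_partial} partial" if s.episodic_partial else "")
                    + f"; time {s.time_correct_h:.1f}/{s.time_occurrence_h:.1f} h"
                    f" ({tm_pct})"
                )
        if self.cutoffs_note:
            lines.append("\nStatic cutoffs in force: " + self.cutoffs_note)
        return "\n".join(lines) + "\n"

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "report.csv", index=False)
        (directory / "report.txt").write_text(self.render_text())
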