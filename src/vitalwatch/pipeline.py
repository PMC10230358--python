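"""End-to-end deterioration detector.

``DeteriorationDetector`` is the estimator façade over the whole method:
``fit`` consumes a training cohort of patient records (stratified by
admission-mean SpO2) and trains one :class:`~vitalwatch.combination.
CombinationModel` per stratum; ``predict_record`` runs the full per-second
pipeline on a new record -- preprocessing, sensor-dysfunction masking, the
population combination model, the patient-baseline deviation model, label
fusion, 4-of-5-minute smoothing and episode segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from . import aggregate
from .aggregate import (
    Episode,
    episodes_to_frame,
    fuse_seconds,
    labels_to_names,
    segment_episodes,
    smooth_labels,
)
from .baseline import BaselineTracker, BaselineTrace
from .combination import CombinationModel, StaticCutoffs
from .dysfunction import DysfunctionMask, SensorFaultDetector
from .exceptions import InsufficientDataError, ValidationError
from .preprocess import Stratum, parameter_matrix, stratify, ventilation_status
from .records import PatientRecord


@dataclass
class ClassificationResult:
    """Everything the pipeline produces for one record."""

    timeline: pd.DataFrame  # t, label, sources
    episodes: list[Episode]
    trace: BaselineTrace
    mask: DysfunctionMask
    stratum: Stratum

    @property
    def labels(self) -> np.ndarray:
        return self.timeline["label"].to_numpy(dtype=object)

    def episode_frame(self) -> pd.DataFrame:
        return episodes_to_frame(self.episodes)


class DeteriorationDetector(BaseEstimator):
    """Three-submodel per-second deterioration classifier.

    Parameters mirror the individual modules; all published rule constants
    are defaults and every threshold is overridable.  ``max_train_vectors``
    bounds the number of complete vectors pooled per stratum before the SVM
    fit (subsampled with ``random_state``).
    """

    def __init__(
        self,
        jump_threshold: float = 25.0,
        rso2_low: float = 15.0,
        rso2_high: float = 95.0,
        rr_floor: float = 5.0,
        pad: int = 60,
        nu: float = 0.05,
        gamma: float | None = None,
        prefilter_percentile: float = 80.0,
        train_fraction: float = 0.8,
        cutoffs: StaticCutoffs | None = None,
        k: float = 2.0,
        trend_window: int = 300,
        trend_min_obs: int = 150,
        vent_multiplier: float = 1.2,
        trim_percentile: float = 20.0,
        sd_cadence: int = 60,
        sd_min_history: int = 600,
        warmup: int = 3600,
        smooth_window: int = 300,
        smooth_min_unstable: int = 240,
        episode_cap: int = 7200,
        unknown_gap: int = 60,
        max_train_vectors: int = 20000,
        random_state: int | None = 0,
    ) -> None:
        self.jump_threshold = jump_threshold
        self.rso2_low = rso2_low
        self.rso2_high = rso2_high
        self.rr_floor = rr_floor
        self.pad = pad
        self.nu = nu
        self.gamma = gamma
        self.prefilter_percentile = prefilter_percentile
        self.train_fraction = train_fraction
        self.cutoffs = cutoffs
        self.k = k
        self.trend_window = trend_window
        self.trend_min_obs = trend_min_obs
        self.vent_multiplier = vent_multiplier
        self.trim_percentile = trim_percentile
        self.sd_cadence = sd_cadence
        self.sd_min_history = sd_min_history
        self.warmup = warmup
        self.smooth_window = smooth_window
        self.smooth_min_unstable = smooth_min_unstable
        self.episode_cap = episode_cap
        self.unknown_gap = unknown_gap
        self.max_train_vectors = max_train_vectors
        self.random_state = random_state

    # ------------------------------------------------------------ helpers
    def _fault_detector(self) -> SensorFaultDetector:
        return SensorFaultDetector(
            jump_threshold=self.jump_threshold,
            rso2_low=self.rso2_low,
            rso2_high=self.rso2_high,
            rr_floor=self.rr_floor,
            pad=self.pad,
        )

    def _tracker(self) -> BaselineTracker:
        return BaselineTracker(
            window=self.trend_window,
            min_obs=self.trend_min_obs,
            k=self.k,
            trim_percentile=self.trim_percentile,
            vent_multiplier=self.vent_multiplier,
            sd_min_history=self.sd_min_history,
            sd_cadence=self.sd_cadence,
            warmup=self.warmup,
        )

    # ---------------------------------------------------------------- fit
    def fit(self, records: Iterable[PatientRecord], y=None) -> "DeteriorationDetector":
        """Train one combination model per stratum from a cohort of records."""
        pools: dict[Stratum, list[np.ndarray]] = {s: [] for s in Stratum}
        for record in records:
            stratum = stratify(record)
            X, complete = parameter_matrix(
                record, window=self.trend_window, min_obs=self.trend_min_obs
            )
            pools[stratum].append(X[complete])
        rng = check_random_state(self.random_state)
        self.models_ = {}
        for stratum, chunks in pools.items():
            if not chunks:
                continue
            X = np.vstack(chunks)
            if X.shape[0] > self.max_train_vectors:
                idx = rng.choice(X.shape[0], self.max_train_vectors, replace=False)
                X = X[np.sort(idx)]
            model = CombinationModel(
                nu=self.nu,
                gamma=self.gamma,
                prefilter_percentile=self.prefilter_percentile,
                train_fraction=self.train_fraction,
                cutoffs=self.cutoffs,
                stratum=stratum,
                random_state=rng.randint(2**31 - 1),
            )
            model.fit(X)
            self.models_[stratum] = model
        if not self.models_:
            raise InsufficientDataError("no training records supplied")
        return self

    # ------------------------------------------------------------ predict
    def predict_record(
        self, record: PatientRecord, stratum: Stratum | None = None
    ) -> ClassificationResult:
        """Classify one record second by second and derive episodes."""
        if not hasattr(self, "models_"):
            raise ValidationError("detector is not fitted")
        stratum = stratum or stratify(record)
        if stratum not in self.models_:
            raise ValidationError(f"no fitted model for stratum {stratum.value}")
        model = self.models_[stratum]

        X, complete = parameter_matrix(
            record, window=self.trend_window, min_obs=self.trend_min_obs
        )
        mask = self._fault_detector().detect(record)
        vent = ventilation_status(record.data["etco2"].to_numpy())

        # submodel 2 verdict per second (no verdict without a complete vector)
        s2 = np.full(record.duration, aggregate.SUB_NONE, dtype=np.int8)
        if complete.any():
            verdicts = model.classify(X[complete])
            s2[complete] = np.where(
                verdicts == "UNSTABLE", aggregate.SUB_UNSTABLE, aggregate.SUB_STABLE
            )

        # submodel 3: distance stream over clean, complete seconds only
        d = np.full(record.duration, np.nan)
        clean = complete & ~mask.combined
        if clean.any():
            d[clean] = model.mahalanobis(X[clean])
        trace = self._tracker().run(d, vent, t=record.t)
        s3 = np.full(record.duration, aggregate.SUB_NONE, dtype=np.int8)
        s3[trace.labels == 0] = aggregate.SUB_STABLE
        s3[trace.labels == 1] = aggregate.SUB_UNSTABLE

        raw = fuse_seconds(record.t, mask.combined, s2, s3, warmup=self.warmup)
        smoothed = smooth_labels(
            raw, window=self.smooth_window, min_unstable=self.smooth_min_unstable
        )
        episodes = segment_episodes(
            smoothed, t=record.t, cap=self.episode_cap, unknown_gap=self.unknown_gap
        )
        sources = _source_column(mask, s2, s3, smoothed)
        timeline = pd.DataFrame(
            {"t": record.t, "label": labels_to_names(smoothed), "sources": sources}
        )
        return ClassificationResult(
            timeline=timeline, episodes=episodes, trace=trace, mask=mask, stratum=stratum
        )

    # -------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        for stratum, model in self.models_.items():
            model.save(directory / stratum.value)

    def load_models(self, directory: str | Path) -> "DeteriorationDetector":
        directory = Path(directory)
        self.models_ = {}
        for stratum in Stratum:
            sub = directory / stratum.value
            if (sub / "svm.txt").exists():
                self.models_[stratum] = CombinationModel.load(sub)
        if not self.models_:
            raise ValidationError(f"no stratum models found under {directory}")
        return self


def _source_column(
    mask: DysfunctionMask, s2: np.ndarray, s3: np.ndarray, smoothed: np.ndarray
) -> list[str]:
    out = []
    for i, code in enumerate(smoothed):
        if code == aggregate.SENSOR_DYSFUNCTION:
            out.append(";".join(mask.provenance(i)))
        elif code == aggregate.UNSTABLE:
            fired = []
            if s2[i] == aggregate.SUB_UNSTABLE:
                fired.append("s2")
            if s3[i] == aggregate.SUB_UNSTABLE:
                fired.append("s3")
            out.append(";".join(fired))
        else:
            out.append("")
    return out
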