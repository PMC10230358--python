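"""Population-level parameter-combination model (submodel 2).

A 5-parameter vector is judged against its stratum's population: vectors are
z-scored, reduced to a Mahalanobis distance, the worst 20% (beyond the 80th
percentile) are discarded as presumed-unstable, and a one-class SVM with an
RBF (square-exponential) kernel and a 5% soft margin (nu) is trained on the
remainder.  At prediction time a vector is UNSTABLE when the SVM places it
outside the learned support or when a single parameter crosses a static
clinical cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.svm import OneClassSVM
from sklearn.utils import check_random_state

from .exceptions import InsufficientDataError, ValidationError
from .preprocess import (
    PARAMETERS,
    Stratum,
    StratumStatistics,
    fit_stratum_statistics,
    load_statistics,
    normalize,
    save_statistics,
)

PREFILTER_PERCENTILE = 80.0

#: Placeholder static clinical cutoffs (original units).  The intensivist-
#: consensus values used clinically were never published; these defaults are
#: the package's own and every evaluation report states the cutoffs in force.
DEFAULT_CUTOFFS: Mapping[str, tuple[float | None, float | None]] = {
    "hr": (60.0, 230.0),
    "rr_trend": (None, 90.0),
    "ibp_mean": (20.0, 90.0),
}


def mahalanobis_distance(z: np.ndarray, covariance: np.ndarray) -> np.ndarray | float:
    """``sqrt(z' Sigma^-1 z)`` for one z-scored vector or a stack of them."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    factor = cho_factor(np.asarray(covariance, dtype=float))
    sq = np.einsum("ij,ij->i", Z, cho_solve(factor, Z.T).T)
    d = np.sqrt(np.clip(sq, 0.0, None))
    return float(d[0]) if single else d


def percentile_prefilter(
    distances: np.ndarray, percentile: float = PREFILTER_PERCENTILE
) -> np.ndarray:
    """Indices of distances at or below the (linearly interpolated) percentile.

    Ties at the threshold are retained; at least five distances required.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 5:
        raise InsufficientDataError("need at least 5 distances to prefilter")
    threshold = np.percentile(d, percentile)
    return np.flatnonzero(d <= threshold)


@dataclass
class StaticCutoffs:
    """Optional per-parameter clinical limits; crossing either bound flags a
    violation.  Keys follow :data:`~vitalwatch.preprocess.PARAMETERS`."""

    limits: Mapping[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.limits.items():
            if name not in PARAMETERS:
                raise ValidationError(f"unknown parameter in cutoffs: {name}")
            if lo is not None and hi is not None and not lo < hi:
                raise ValidationError(f"cutoff for {name}: lower must be < upper")

    def violation(self, X: np.ndarray) -> np.ndarray:
        """Boolean per-row flag: any configured limit crossed."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(X.shape[0], dtype=bool)
        for name, (lo, hi) in self.limits.items():
            col = X[:, PARAMETERS.index(name)]
            if lo is not None:
                out |= col < lo
            if hi is not None:
                out |= col > hi
        return out


class CombinationModel(BaseEstimator, OutlierMixin):
    """One-class-SVM stability classifier for 5-parameter vectors.

    Parameters
    ----------
    nu
        Soft margin of the one-class SVM; upper-bounds the fraction of
        training vectors treated as outliers.  Default 0.05.
    gamma
        RBF kernel scale.  ``None`` selects ``1 / (5 * mean per-axis
        variance of the training z-scores)``.
    prefilter_percentile
        Mahalanobis percentile above which candidate training vectors are
        discarded as presumed-unstable.
    train_fraction
        Fraction of retained vectors used to fit the SVM; the held-out rest
        only yields a logged inlier rate.
    cutoffs
        :class:`StaticCutoffs` applied on the original scales (``None`` for
        the package defaults).
    ridge
        Relative ridge used if the z-score covariance is not positive
        definite.
    min_train
        Minimum number of post-prefilter vectors required to fit.
    random_state
        Seed for the train/test shuffle.

    Attributes (after :meth:`fit`)
    ------------------------------
    stats_ : StratumStatistics
    gamma_ : float
    support_vectors_, dual_coef_, intercept_ : SVM expansion terms
    threshold_ : float -- prefilter distance threshold
    train_indices_ : indices (into the fit X) of the SVM training partition
    holdout_inlier_rate_ : float
    fit_log_ : dict
    """

    def __init__(
        self,
        nu: float = 0.05,
        gamma: float | None = None,
        prefilter_percentile: float = PREFILTER_PERCENTILE,
        train_fraction: float = 0.8,
        cutoffs: StaticCutoffs | None = None,
        ridge: float = 1e-6,
        min_train: int = 500,
        stratum: Stratum = Stratum.LOW_SAT,
        random_state: int | None = 0,
    ) -> None:
        self.nu = nu
        self.gamma = gamma
        self.prefilter_percentile = prefilter_percentile
        self.train_fraction = train_fraction
        self.cutoffs = cutoffs
        self.ridge = ridge
        self.min_train = min_train
        self.stratum = stratum
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X: np.ndarray, y=None) -> "CombinationModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(PARAMETERS):
            raise ValidationError("X must be an (n, 5) array of complete vectors")
        if not 0 < self.nu < 1:
            raise ValidationError("nu must lie in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        self.stats_ = fit_stratum_statistics(X, stratum=self.stratum, ridge=self.ridge)
        z = normalize(X, self.stats_)
        d = mahalanobis_distance(z, self.stats_.covariance)
        self.threshold_ = float(np.percentile(d, self.prefilter_percentile))
        retained = percentile_prefilter(d, self.prefilter_percentile)
        if retained.size < self.min_train:
            raise InsufficientDataError(
                f"need >= {self.min_train} vectors after prefilter, got {retained.size}"
            )
        rng = check_random_state(self.random_state)
        perm = rng.permutation(retained.size)
        n_train = int(round(self.train_fraction * retained.size))
        self.train_indices_ = np.sort(retained[perm[:n_train]])
        holdout_indices = np.sort(retained[perm[n_train:]])

        z_train = z[self.train_indices_]
        if self.gamma is None:
            self.gamma_ = float(1.0 / (5.0 * z_train.var(axis=0, ddof=1).mean()))
        else:
            self.gamma_ = float(self.gamma)
        svm = OneClassSVM(kernel="rbf", nu=self.nu, gamma=self.gamma_)
        svm.fit(z_train)
        self.support_vectors_ = svm.support_vectors_.copy()
        self.dual_coef_ = svm.dual_coef_[0].copy()
        self.intercept_ = float(svm.intercept_[0])
        self.cutoffs_ = self.cutoffs if self.cutoffs is not None else StaticCutoffs()

        train_outlier = float(np.mean(self.predict(X[self.train_indices_]) == -1))
        if holdout_indices.size:
            holdout_inlier = float(np.mean(self.predict(X[holdout_indices]) == 1))
        else:
            holdout_inlier = float("nan")
        self.holdout_inlier_rate_ = holdout_inlier
        self.fit_log_ = {
            "n_vectors": int(X.shape[0]),
            "n_retained": int(retained.size),
            "n_train": int(n_train),
            "n_holdout": int(holdout_indices.size),
            "prefilter_threshold": self.threshold_,
            "gamma": self.gamma_,
            "nu": float(self.nu),
            "train_outlier_fraction": train_outlier,
            "holdout_inlier_rate": holdout_inlier,
            "n_support": int(self.support_vectors_.shape[0]),
        }
        return self

    # ------------------------------------------------------------- predict
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the SVM boundary (positive = inlier).

        Evaluated from the persisted expansion
        ``f(z) = sum_i a_i exp(-gamma ||z - sv_i||^2) + b`` so that a model
        reloaded from its text bundle reproduces decisions bit-identically.
        """
        z = normalize(np.atleast_2d(np.asarray(X, dtype=float)), self.stats_)
        K = np.exp(-self.gamma_ * cdist(z, self.support_vectors_, "sqeuclidean"))
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 for SVM inliers, -1 for outliers (static cutoffs not applied)."""
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Final submodel-2 label per vector: ``"UNSTABLE"`` iff the SVM
        rejects the vector or a static cutoff is crossed, else ``"STABLE"``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        unstable = (self.predict(X) == -1) | self.cutoffs_.violation(X)
        return np.where(unstable, "UNSTABLE", "STABLE")

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of raw vectors under the fitted statistics."""
        z = normalize(np.atleast_2d(np.asarray(X, dtype=float)), self.stats_)
        return mahalanobis_distance(z, self.stats_.covariance)

    # --------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        """Persist the fitted model as a directory of plain-text files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_statistics(self.stats_, directory / "statistics.txt")
        lines = [
            "schema_version: 1",
            f"gamma: {self.gamma_!r}",
            f"nu: {float(self.nu)!r}",
            f"intercept: {self.intercept_!r}",
            f"threshold: {self.threshold_!r}",
            "dual_coef: " + " ".join(repr(float(v)) for v in self.dual_coef_),
            "support_vectors:",
        ]
        lines += [
            "  " + " ".join(repr(float(v)) for v in row) for row in self.support_vectors_
        ]
        (directory / "svm.txt").write_text("\n".join(lines) + "\n")
        cut = {
            name: [lo, hi] for name, (lo, hi) in self.cutoffs_.limits.items()
        }
        (directory / "cutoffs.json").write_text(json.dumps(cut, indent=1) + "\n")
        (directory / "config.json").write_text(
            json.dumps(
                {
                    "nu": self.nu,
                    "gamma": self.gamma,
                    "prefilter_percentile": self.prefilter_percentile,
                    "train_fraction": self.train_fraction,
                    "ridge": self.ridge,
                    "min_train": self.min_train,
                    "stratum": self.stats_.stratum.value,
                    "random_state": self.random_state,
                },
                indent=1,
            )
            + "\n"
        )
        (directory / "fit_log.json").write_text(
            json.dumps(self.fit_log_, indent=1) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "CombinationModel":
        directory = Path(directory)
        config = json.loads((directory / "config.json").read_text())
        cut_raw = json.loads((directory / "cutoffs.json").read_text())
        cutoffs = StaticCutoffs(
            {
                name: (
                    None if lo is None else float(lo),
                    None if hi is None else float(hi),
                )
                for name, (lo, hi) in cut_raw.items()
            }
        )
        model = cls(
            nu=config["nu"],
            gamma=config["gamma"],
            prefilter_percentile=config["prefilter_percentile"],
            train_fraction=config["train_fraction"],
            cutoffs=cutoffs,
            ridge=config["ridge"],
            min_train=config["min_train"],
            stratum=Stratum(config["stratum"]),
            random_state=config["random_state"],
        )
        model.stats_ = load_statistics(directory / "statistics.txt")
        fields: dict[str, str] = {}
        rows: list[list[float]] = []
        in_matrix = False
        for line in (directory / "svm.txt").read_text().splitlines():
            if in_matrix:
                rows.append([float(v) for v in line.split()])
            elif line.startswith("support_vectors:"):
                in_matrix = True
            else:
                key, _, value = line.partition(":")
                fields[key.strip()] = value.strip()
        model.gamma_ = float(fields["gamma"])
        model.intercept_ = float(fields["intercept"])
        model.threshold_ = float(fields["threshold"])
        model.dual_coef_ = np.array([float(v) for v in fields["dual_coef"].split()])
        model.support_vectors_ = np.array(rows)
        model.cutoffs_ = cutoffs
        if (directory / "fit_log.json").exists():
            model.fit_log_ = json.loads((directory / "fit_log.json").read_text())
        return model
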