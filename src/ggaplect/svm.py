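"""RBF-kernel SVM training, grid search and cross-validation engines.

The classifier is a C-SVM with RBF kernel.  Hyperparameters are chosen by
an exhaustive grid search over geometric grids

    c     in 2^-5 .. 2^15   (multiplicative step 2)
    gamma in 2^-15 .. 2^-5  (multiplicative step 2)

scored by stratified k-fold cross-validation accuracy with a single seeded
fold split shared across the whole grid, so the search is deterministic;
ties are broken toward smaller c, then smaller gamma.

Two evaluation engines are provided: seeded stratified k-fold CV and the
jackknife (leave-one-out) test.  The jackknife result is unique for a fixed
dataset and fixed (c, gamma) — there is no randomness to average over —
which is why it is the confirmatory protocol of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .features import encode_sequences
from .metrics import ConfusionCounts, Metrics, compute_metrics
from .sequences import NEGATIVE, POSITIVE, ProteinSequence

MODEL_FORMAT_VERSION = 1


def default_c_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16)


def default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, -4)


@dataclass
class SVMConfig:
    """Grid-search and cross-validation settings."""

    c_grid: np.ndarray = field(default_factory=default_c_grid)
    gamma_grid: np.ndarray = field(default_factory=default_gamma_grid)
    tuning_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = np.sort(np.asarray(self.c_grid, dtype=float))
        self.gamma_grid = np.sort(np.asarray(self.gamma_grid, dtype=float))
        for name, grid in (("c_grid", self.c_grid), ("gamma_grid", self.gamma_grid)):
            if grid.size == 0 or np.any(grid <= 0):
                raise ValueError(f"{name} must be non-empty and strictly positive")
        if self.tuning_folds < 2:
            raise ValueError("tuning_folds must be >= 2")


@dataclass
class CVResult:
    """Cross-validation output: aligned predictions plus pooled metrics."""

    y_pred: np.ndarray
    counts: ConfusionCounts
    metrics: Metrics


def _new_svc(c: float, gamma: float) -> SVC:
    return SVC(C=c, gamma=gamma, kernel="rbf", cache_size=200)


def _check_two_classes(y: np.ndarray) -> tuple[int, int]:
    y = np.asarray(y)
    n_pos = int(np.sum(y == POSITIVE))
    n_neg = int(np.sum(y == NEGATIVE))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def _stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    n_pos, n_neg = _check_two_classes(y)
    if k > min(n_pos, n_neg):
        raise ValueError(
            f"cannot stratify {k} folds with class sizes ({n_pos}, {n_neg}); "
            f"use at most {min(n_pos, n_neg)} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(y), y))


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    c: float,
    gamma: float,
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold CV at fixed hyperparameters.

    Predictions from all held-out folds are pooled into one confusion
    table.  ``k == n_samples`` reduces to the jackknife (which needs no
    stratification or shuffling).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k == y.size:
        return jackknife_cv(X, y, c, gamma)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in _stratified_folds(y, k, seed):
        clf = _new_svc(c, gamma).fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = clf.predict(X[test_idx])
    counts = ConfusionCounts.from_predictions(y, y_pred)
    return CVResult(y_pred=y_pred, counts=counts, metrics=compute_metrics(counts))


def jackknife_cv(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float
) -> CVResult:
    """Leave-one-out CV at fixed hyperparameters.

    Each sample is predicted by a model trained on the other N - 1; the
    result is unique (invariant to sample order up to alignment).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    n_pos, n_neg = _check_two_classes(y)
    if min(n_pos, n_neg) < 2:
        raise ValueError("each class needs at least 2 members for the jackknife")
    y_pred = np.empty_like(y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _new_svc(c, gamma).fit(X[mask], y[mask])
        y_pred[i] = clf.predict(X[i : i + 1])[0]
        mask[i] = True
    counts = ConfusionCounts.from_predictions(y, y_pred)
    return CVResult(y_pred=y_pred, counts=counts, metrics=compute_metrics(counts))


from sklearn.base import BaseEstimator, ClassifierMixin  # noqa: E402


class RBFGridSVC(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with exhaustive, deterministic (c, gamma) grid search.

    Every grid pair is scored by pooled stratified ``tuning_folds``-fold CV
    accuracy on one seeded fold split; the best pair (ties toward smaller c,
    then smaller gamma) is refit on the full data.

    Attributes
    ----------
    best_c_, best_gamma_ : float
        Selected hyperparameters.
    best_cv_accuracy_ : float
        Pooled CV accuracy (fraction) of the winning pair.
    grid_scores_ : pandas.DataFrame
        Accuracy of every (c, gamma) pair evaluated.
    estimator_ : sklearn.svm.SVC
        The refit classifier.
    """

    def __init__(
        self,
        c_grid: np.ndarray | None = None,
        gamma_grid: np.ndarray | None = None,
        tuning_folds: int = 10,
        random_state: int = 0,
    ):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.tuning_folds = tuning_folds
        self.random_state = random_state

    def _config(self) -> SVMConfig:
        return SVMConfig(
            c_grid=self.c_grid if self.c_grid is not None else default_c_grid(),
            gamma_grid=(
                self.gamma_grid if self.gamma_grid is not None else default_gamma_grid()
            ),
            tuning_folds=self.tuning_folds,
            seed=self.random_state,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFGridSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cfg = self._config()
        folds = _stratified_folds(y, cfg.tuning_folds, cfg.seed)
        # Fit every fold model once per pair; pool held-out hits.
        records = []
        best = (-1.0, None, None)
        for c in cfg.c_grid:
            for gamma in cfg.gamma_grid:
                hits = 0
                for train_idx, test_idx in folds:
                    clf = _new_svc(c, gamma).fit(X[train_idx], y[train_idx])
                    hits += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
                acc = hits / y.size
                records.append({"c": c, "gamma": gamma, "cv_accuracy": acc})
                if acc > best[0]:  # strict: earlier (smaller) c/gamma win ties
                    best = (acc, c, gamma)
        self.best_cv_accuracy_, self.best_c_, self.best_gamma_ = best
        self.grid_scores_ = pd.DataFrame.from_records(records)
        self.estimator_ = _new_svc(self.best_c_, self.best_gamma_).fit(X, y)
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.estimator_.decision_function(np.asarray(X, dtype=float))


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the feature-subset descriptor it expects.

    ``gap`` and ``feature_indices`` record how raw sequences must be
    encoded and which ranked columns (in stored order) feed the decision
    function, so the model is self-contained for sequence prediction.
    """

    c: float
    gamma: float
    svc: SVC
    gap: int | None = None
    feature_indices: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        if self.feature_indices is not None:
            return int(len(self.feature_indices))
        return int(self.svc.n_features_in_)


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    gap: int | None = None,
    feature_indices: np.ndarray | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Grid-search (c, gamma), refit on all data, return the model + report."""
    config = config or SVMConfig()
    clf = RBFGridSVC(
        c_grid=config.c_grid,
        gamma_grid=config.gamma_grid,
        tuning_folds=config.tuning_folds,
        random_state=config.seed,
    ).fit(X, y)
    model = TrainedModel(
        c=clf.best_c_,
        gamma=clf.best_gamma_,
        svc=clf.estimator_,
        gap=gap,
        feature_indices=(
            None if feature_indices is None else np.asarray(feature_indices, dtype=int)
        ),
    )
    return model, clf.grid_scores_


@dataclass
class PredictionRecord:
    """Per-sequence prediction; ``error`` is set instead of a label when the
    record could not be encoded (e.g. shorter than gap + 2)."""

    id: str
    label: int | None
    decision_value: float | None
    error: str | None = None


def predict(
    model: TrainedModel, sequences: Sequence[ProteinSequence]
) -> list[PredictionRecord]:
    """Predict a class for each sequence using the model's own encoding.

    Sequences that cannot be encoded at the model's gap yield a per-record
    error entry; the rest are still predicted.
    """
    if model.gap is None:
        raise ValueError("model carries no gap; cannot encode raw sequences")
    out: list[PredictionRecord] = []
    for seq in sequences:
        try:
            row, _ = encode_sequences([seq], model.gap, short_policy="error")
        except ValueError as exc:
            out.append(PredictionRecord(seq.id, None, None, error=str(exc)))
            continue
        if model.feature_indices is not None:
            row = row[:, model.feature_indices]
        if row.shape[1] != model.svc.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: encoded {row.shape[1]}, "
                f"model expects {model.svc.n_features_in_}"
            )
        label = int(model.svc.predict(row)[0])
        dv = float(model.svc.decision_function(row)[0])
        out.append(PredictionRecord(seq.id, label, dv))
    return out


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (format-versioned archive)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "c": model.c,
        "gamma": model.gamma,
        "gap": model.gap,
        "feature_indices": model.feature_indices,
        "svc": model.svc,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version: {payload.get('format_version')}"
        )
    return TrainedModel(
        c=payload["c"],
        gamma=payload["gamma"],
        svc=payload["svc"],
        gap=payload["gap"],
        feature_indices=payload["feature_indices"],
    )
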