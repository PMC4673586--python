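"""Incremental feature selection (IFS) over gap values.

Protocol: for each gap g in a range (default 0..10), encode the dataset as
g-gap dipeptide compositions, rank the 400 features by ANOVA F value, and
sweep nested subsets along the ranking — the subset of size epsilon is
exactly the top-epsilon features, so subset(e) is contained in subset(e+1).
Each subset is scored by cross-validation; the accuracy-vs-size curves have
a peak, and the global argmax over all curves fixes the winning gap g_phi
and subset size epsilon_0.

The sweep uses a fast CV protocol (10-fold by default); the confirmed
optimum is then re-scored by the jackknife, which yields a unique result.
Hyperparameters (c, gamma) are grid-searched once per gap on the full
400-feature matrix and reused across subset sizes; per-subset re-tuning is
available but multiplies the cost by the grid size.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import __version__ as _pkg_version
from .features import N_FEATURES, ShortPolicy, encode_dataset
from .metrics import Metrics
from .ranking import FValueTable, rank_features
from .sequences import LabeledDataset, ProteinSequence, as_protein_sequences
from .svm import (
    CVResult,
    SVMConfig,
    TrainedModel,
    _new_svc,
    grid_search_train,
    jackknife_cv,
    kfold_cv,
    predict as _predict_sequences,
)


def sweep_sizes(stride: int = 1, n_features: int = N_FEATURES) -> list[int]:
    """Subset sizes 1, 1+stride, ... up to ``n_features``."""
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    return list(range(1, n_features + 1, stride))


def sweep_schedule(
    gaps: Iterable[int], stride: int = 1, n_features: int = N_FEATURES
) -> list[tuple[int, int]]:
    """All (gap, subset size) evaluations of a sweep, in execution order.

    With gaps 0..10 and stride 1 this enumerates 11 x 400 = 4,400 pairs.
    """
    sizes = sweep_sizes(stride, n_features)
    return [(g, e) for g in gaps for e in sizes]


def _parse_cv_mode(cv: str) -> tuple[str, int | None]:
    if cv == "jackknife":
        return "jackknife", None
    m = re.fullmatch(r"kfold(\d+)", cv)
    if m:
        k = int(m.group(1))
        if k < 2:
            raise ValueError("k-fold CV needs k >= 2")
        return "kfold", k
    raise ValueError(f"unknown cv mode {cv!r}; use 'kfold<k>' or 'jackknife'")


@dataclass
class IFSCurve:
    """Accuracy-vs-subset-size curve for one gap value."""

    gap: int
    epsilons: np.ndarray
    acc: np.ndarray  # percent
    sn: np.ndarray  # percent
    sp: np.ndarray  # percent
    f_table: FValueTable
    c: float
    gamma: float


@dataclass
class OptimalSubset:
    """The winning (gap, subset size) point of an IFS sweep."""

    gap: int
    epsilon: int
    f_threshold: float  # F value of the last (epsilon-th) included feature
    acc: float  # percent, under the sweep's CV protocol
    sn: float
    sp: float
    feature_indices: np.ndarray  # top-epsilon ranked column indices
    c: float
    gamma: float


def _evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    k: int | None,
    c: float,
    gamma: float,
    seed: int,
) -> CVResult:
    if mode == "jackknife":
        return jackknife_cv(X, y, c, gamma)
    return kfold_cv(X, y, k, c, gamma, seed=seed)


def run_ifs(
    dataset: LabeledDataset,
    gaps: Iterable[int] = range(0, 11),
    cv: str = "kfold10",
    config: SVMConfig | None = None,
    stride: int = 1,
    short_policy: ShortPolicy = "error",
    tune_per_subset: bool = False,
) -> list[IFSCurve]:
    """Run the full IFS sweep and return one curve per gap.

    For each gap the dataset is encoded, features are ranked by F, (c,
    gamma) are tuned once on the full matrix, and every nested subset size
    in the stride schedule is scored under the requested CV protocol with
    the config's seed.  ``tune_per_subset=True`` re-runs the grid search for
    every subset instead.
    """
    config = config or SVMConfig()
    mode, k = _parse_cv_mode(cv)
    curves: list[IFSCurve] = []
    for g in gaps:
        mat = encode_dataset(dataset, g, short_policy=short_policy)
        table = rank_features(mat)
        model, _ = grid_search_train(mat.X, mat.labels, config)
        accs, sns, sps = [], [], []
        sizes = sweep_sizes(stride)
        for eps in sizes:
            cols = table.order[:eps]
            if tune_per_subset:
                sub_model, _ = grid_search_train(mat.X[:, cols], mat.labels, config)
                c, gamma = sub_model.c, sub_model.gamma
            else:
                c, gamma = model.c, model.gamma
            res = _evaluate_subset(
                mat.X[:, cols], mat.labels, mode, k, c, gamma, config.seed
            )
            accs.append(res.metrics.acc_pct)
            sns.append(res.metrics.sn_pct)
            sps.append(res.metrics.sp_pct)
        curves.append(
            IFSCurve(
                gap=g,
                epsilons=np.asarray(sizes, dtype=int),
                acc=np.asarray(accs),
                sn=np.asarray(sns),
                sp=np.asarray(sps),
                f_table=table,
                c=model.c,
                gamma=model.gamma,
            )
        )
    return curves


def select_optimal(curves: Sequence[IFSCurve]) -> OptimalSubset:
    """Argmax accuracy over all curve points.

    Ties are broken toward the smaller subset size, then the smaller gap,
    so the selection is deterministic.
    """
    if not curves or all(c.epsilons.size == 0 for c in curves):
        raise ValueError("no IFS curve points to select from")
    best: tuple[float, int, int] | None = None
    best_curve: IFSCurve | None = None
    best_i: int | None = None
    for curve in curves:
        for i, eps in enumerate(curve.epsilons):
            key = (curve.acc[i], -int(eps), -curve.gap)
            if best is None or key > best:
                best = key
                best_curve, best_i = curve, i
    assert best_curve is not None and best_i is not None
    eps = int(best_curve.epsilons[best_i])
    order = best_curve.f_table.order
    return OptimalSubset(
        gap=best_curve.gap,
        epsilon=eps,
        f_threshold=float(best_curve.f_table.F[order[eps - 1]]),
        acc=float(best_curve.acc[best_i]),
        sn=float(best_curve.sn[best_i]),
        sp=float(best_curve.sp[best_i]),
        feature_indices=order[:eps].copy(),
        c=best_curve.c,
        gamma=best_curve.gamma,
    )


def confirm_by_jackknife(
    dataset: LabeledDataset,
    optimal: OptimalSubset,
    short_policy: ShortPolicy = "error",
) -> Metrics:
    """Re-score exactly the optimal feature subset under the jackknife."""
    mat = encode_dataset(dataset, optimal.gap, short_policy=short_policy)
    X = mat.X[:, optimal.feature_indices]
    res = jackknife_cv(X, mat.labels, optimal.c, optimal.gamma)
    return res.metrics


def curves_to_tsv(curves: Sequence[IFSCurve], path: str | Path) -> None:
    """Write all curves to one TSV: columns g, epsilon, acc, sn, sp."""
    rows = []
    for curve in curves:
        for i, eps in enumerate(curve.epsilons):
            rows.append(
                {
                    "g": curve.gap,
                    "epsilon": int(eps),
                    "acc": curve.acc[i],
                    "sn": curve.sn[i],
                    "sp": curve.sp[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.2f")


def optimal_to_json(optimal: OptimalSubset, path: str | Path) -> None:
    payload = {
        "g_phi": optimal.gap,
        "epsilon_0": optimal.epsilon,
        "F_threshold": optimal.f_threshold,
        "Acc": optimal.acc,
        "Sn": optimal.sn,
        "Sp": optimal.sp,
        "c": optimal.c,
        "gamma": optimal.gamma,
        "feature_indices": [int(i) for i in optimal.feature_indices],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (seed, grids, CV mode, package version)."""
    payload = {"package_version": _pkg_version, **entries}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, default=str)
        handle.write("\n")


class GGapIFSClassifier(ClassifierMixin, BaseEstimator):
    """Full pipeline estimator: sequences in, class labels out.

    ``fit`` runs the complete protocol — g-gap encoding for every gap in
    ``gaps``, ANOVA F ranking, per-gap (c, gamma) grid search, the nested
    subset sweep under ``cv``, global selection of (g_phi, epsilon_0) — and
    refits an RBF-SVM on the winning subset.  With
    ``confirm_jackknife=True`` the optimum is additionally re-scored by
    leave-one-out CV (``jackknife_metrics_``).

    Parameters
    ----------
    gaps : iterable of int, default=range(0, 11)
    stride : int, default=1
        Subset-size step of the sweep (1 = every size 1..400).
    cv : str, default="kfold10"
        "kfold<k>" or "jackknife"; protocol used to score each subset.
    c_grid, gamma_grid : array-like or None
        Hyperparameter grids; None means the default geometric grids.
    tuning_folds : int, default=10
    random_state : int, default=0
        Seed for fold shuffling (tuning and sweep).
    short_policy : {"error", "drop"}, default="error"
    confirm_jackknife : bool, default=False

    Attributes
    ----------
    curves_ : list of IFSCurve
    optimal_ : OptimalSubset
    best_gap_, n_features_selected_, f_threshold_ : selection summary
    model_ : TrainedModel fitted on the full data at the optimum
    jackknife_metrics_ : Metrics (only when ``confirm_jackknife``)
    """

    def __init__(
        self,
        gaps: Iterable[int] = range(0, 11),
        stride: int = 1,
        cv: str = "kfold10",
        c_grid=None,
        gamma_grid=None,
        tuning_folds: int = 10,
        random_state: int = 0,
        short_policy: ShortPolicy = "error",
        confirm_jackknife: bool = False,
        tune_per_subset: bool = False,
    ):
        self.gaps = gaps
        self.stride = stride
        self.cv = cv
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.tuning_folds = tuning_folds
        self.random_state = random_state
        self.short_policy = short_policy
        self.confirm_jackknife = confirm_jackknife
        self.tune_per_subset = tune_per_subset

    def _svm_config(self) -> SVMConfig:
        kwargs = {}
        if self.c_grid is not None:
            kwargs["c_grid"] = np.asarray(self.c_grid, dtype=float)
        if self.gamma_grid is not None:
            kwargs["gamma_grid"] = np.asarray(self.gamma_grid, dtype=float)
        return SVMConfig(
            tuning_folds=self.tuning_folds, seed=self.random_state, **kwargs
        )

    def fit(self, X, y) -> "GGapIFSClassifier":
        sequences = as_protein_sequences(X)
        dataset = LabeledDataset(sequences=sequences, labels=np.asarray(y))
        config = self._svm_config()
        self.curves_ = run_ifs(
            dataset,
            gaps=self.gaps,
            cv=self.cv,
            config=config,
            stride=self.stride,
            short_policy=self.short_policy,
            tune_per_subset=self.tune_per_subset,
        )
        self.optimal_ = select_optimal(self.curves_)
        self.best_gap_ = self.optimal_.gap
        self.n_features_selected_ = self.optimal_.epsilon
        self.f_threshold_ = self.optimal_.f_threshold
        mat = encode_dataset(dataset, self.optimal_.gap, self.short_policy)
        X_opt = mat.X[:, self.optimal_.feature_indices]
        svc = _new_svc(self.optimal_.c, self.optimal_.gamma).fit(X_opt, mat.labels)
        self.model_ = TrainedModel(
            c=self.optimal_.c,
            gamma=self.optimal_.gamma,
            svc=svc,
            gap=self.optimal_.gap,
            feature_indices=self.optimal_.feature_indices,
        )
        self.classes_ = svc.classes_
        if self.confirm_jackknife:
            self.jackknife_metrics_ = confirm_by_jackknife(
                dataset, self.optimal_, self.short_policy
            )
        return self

    def predict(self, X) -> np.ndarray:
        sequences = as_protein_sequences(X)
        records = _predict_sequences(self.model_, sequences)
        bad = [r.id for r in records if r.error]
        if bad:
            raise ValueError(f"could not encode sequence(s): {bad[:5]}")
        return np.asarray([r.label for r in records], dtype=int)

    def decision_function(self, X) -> np.ndarray:
        sequences = as_protein_sequences(X)
        records = _predict_sequences(self.model_, sequences)
        bad = [r.id for r in records if r.error]
        if bad:
            raise ValueError(f"could not encode sequence(s): {bad[:5]}")
        return np.asarray([r.decision_value for r in records], dtype=float)
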