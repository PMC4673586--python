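"""One-way ANOVA F-value feature ranking and signed preference scores.

For feature *u* with two groups of sizes m1, m2 (N = m1 + m2, K = 2):

    SS_B(u) = sum_i m_i (mean_i - grand_mean)^2
    SS_W(u) = sum_i sum_j (x_ij - mean_i)^2
    F(u)    = (SS_B / df_B) / (SS_W / df_W),  df_B = K - 1, df_W = N - K

A large F marks a feature whose between-class spread dominates its
within-class spread; features are ranked by descending F (ties broken by
ascending dipeptide index so the ranking — and hence every incremental
feature-selection curve built on it — is deterministic).  The F value is
used purely for ranking, never for hypothesis testing, so no multiplicity
correction is applied.

Degenerate columns are given total, deterministic ranks: a constant column
(SS_W = SS_B = 0) gets F = 0; a perfectly separated column (SS_W = 0,
SS_B > 0) gets F = +inf, ranked above all finite values.

For feature analysis the F values are min-max normalised to [0, 1] and
signed by which class has the larger mean frequency:

    F0(u) = sgn(mean_pos_u - mean_neg_u) * (F(u) - F_min) / (F_max - F_min)

|F0| near 1 marks strongly class-preferring dipeptides; F0 > 0 means the
dipeptide is enriched in the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import DIPEPTIDES, GGapFeatureMatrix
from .sequences import NEGATIVE, POSITIVE


class ConstantFeaturesError(ValueError):
    """All features have identical F values; normalisation is undefined."""


@dataclass
class FValueTable:
    """Per-feature ANOVA statistics and the descending-F rank order."""

    F: np.ndarray
    ss_between: np.ndarray
    ss_within: np.ndarray
    df_between: int
    df_within: int
    order: np.ndarray  # permutation: order[0] is the top-ranked feature index

    @property
    def msb(self) -> np.ndarray:
        return self.ss_between / self.df_between

    @property
    def msw(self) -> np.ndarray:
        return self.ss_within / self.df_within

    @property
    def ranks(self) -> np.ndarray:
        """rank[u] = 1-based rank of feature u (1 = largest F)."""
        r = np.empty_like(self.order)
        r[self.order] = np.arange(1, self.order.size + 1)
        return r


@dataclass
class PreferenceTable:
    """Signed, normalised preference scores F0 in [-1, 1] per feature."""

    f0: np.ndarray
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    f_min: float
    f_max: float


def _group_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    y = np.asarray(y)
    pos = X[y == POSITIVE]
    neg = X[y == NEGATIVE]
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both classes must be present to compute F values")
    return pos, neg


def f_values(X: np.ndarray, y: np.ndarray) -> FValueTable:
    """Compute the ANOVA F value of every column of ``X`` (two classes).

    Vectorised over columns.  Requires N >= 3 so df_W = N - K > 0.
    """
    X = np.asarray(X, dtype=float)
    pos, neg = _group_stats(X, y)
    m1, m2 = pos.shape[0], neg.shape[0]
    n = m1 + m2
    if n < 3:
        raise ValueError(f"need at least 3 samples (got {n}); df_W would be <= 0")
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    grand = (m1 * mean_pos + m2 * mean_neg) / n
    ss_b = m1 * (mean_pos - grand) ** 2 + m2 * (mean_neg - grand) ** 2
    ss_w = ((pos - mean_pos) ** 2).sum(axis=0) + ((neg - mean_neg) ** 2).sum(axis=0)
    df_b, df_w = 1, n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_b / df_b) / (ss_w / df_w)
    # total, deterministic ranking on degenerate columns
    zero_w = ss_w == 0
    F = np.where(zero_w & (ss_b > 0), np.inf, F)
    F = np.where(zero_w & (ss_b == 0), 0.0, F)
    order = np.lexsort((np.arange(F.size), -F))
    return FValueTable(
        F=F, ss_between=ss_b, ss_within=ss_w,
        df_between=df_b, df_within=df_w, order=order,
    )


def f_value(column: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """F statistic of a single feature column; see :func:`f_values`."""
    table = f_values(np.asarray(column, dtype=float).reshape(-1, 1), y)
    return {
        "F": float(table.F[0]),
        "ss_between": float(table.ss_between[0]),
        "ss_within": float(table.ss_within[0]),
    }


def rank_features(
    matrix: GGapFeatureMatrix | np.ndarray, y: np.ndarray | None = None
) -> FValueTable:
    """Rank the features of a g-gap matrix by descending ANOVA F value."""
    if isinstance(matrix, GGapFeatureMatrix):
        X, y = matrix.X, matrix.labels
    else:
        X = matrix
        if y is None:
            raise ValueError("labels required when passing a raw array")
    return f_values(X, y)


def preference_scores(
    table: FValueTable, X: np.ndarray | GGapFeatureMatrix, y: np.ndarray | None = None
) -> PreferenceTable:
    """Signed min-max normalised preference score F0 for every feature.

    Perfectly separated features (F = +inf) are assigned |F0| = 1; the
    remaining features are normalised over the finite F range.
    """
    if isinstance(X, GGapFeatureMatrix):
        X, y = X.X, X.labels
    pos, neg = _group_stats(np.asarray(X, dtype=float), y)
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    F = table.F
    finite = np.isfinite(F)
    f_min = float(F[finite].min()) if finite.any() else 0.0
    f_max_all = float(F.max())
    f_max_finite = float(F[finite].max()) if finite.any() else 0.0
    if f_max_all == f_min:
        raise ConstantFeaturesError(
            "all features have identical F values; F0 is undefined"
        )
    magnitude = np.ones_like(F)
    if f_max_finite > f_min:
        magnitude[finite] = (F[finite] - f_min) / (f_max_finite - f_min)
    else:
        magnitude[finite] = 0.0
    f0 = np.sign(mean_pos - mean_neg) * magnitude
    return PreferenceTable(
        f0=f0, mean_pos=mean_pos, mean_neg=mean_neg,
        f_min=f_min, f_max=f_max_all,
    )


def preference_heatmap_data(pref: PreferenceTable) -> pd.DataFrame:
    """20x20 grid of F0, rows = first residue, columns = second residue."""
    from .sequences import AMINO_ACIDS

    grid = pref.f0.reshape(20, 20)
    return pd.DataFrame(grid, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


def ranking_to_tsv(
    table: FValueTable,
    pref: PreferenceTable | None,
    path: str | Path,
) -> None:
    """Export per-feature statistics as TSV in the fixed dipeptide order."""
    df = pd.DataFrame(
        {
            "dipeptide": DIPEPTIDES,
            "F": table.F,
            "SS_B": table.ss_between,
            "SS_W": table.ss_within,
            "rank": table.ranks,
        }
    )
    if pref is not None:
        df["F0"] = pref.f0
        df["mean_pos"] = pref.mean_pos
        df["mean_neg"] = pref.mean_neg
    df.to_csv(path, sep="\t", index=False)


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class AnovaRankSelector(TransformerMixin, BaseEstimator):
    """Select the top-k features by ANOVA F value (two-class).

    The selection is nested in ``k``: the top-(k+1) set always contains the
    top-k set, which is what incremental feature selection sweeps rely on.

    Attributes
    ----------
    f_table_ : FValueTable
        Full per-feature statistics computed at fit time.
    support_indices_ : ndarray
        Column indices of the selected features, in rank order.
    """

    def __init__(self, k: int = 400):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AnovaRankSelector":
        X = np.asarray(X, dtype=float)
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in 1..{X.shape[1]}, got {self.k}")
        self.f_table_ = f_values(X, y)
        self.support_indices_ = self.f_table_.order[: self.k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X[:, self.support_indices_]
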