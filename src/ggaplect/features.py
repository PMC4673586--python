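"""g-gap dipeptide composition encoding.

A *g*-gap dipeptide is an ordered residue pair separated by exactly ``g``
intervening residues; ``g = 0`` recovers the classic adjacent dipeptide
composition.  A sequence of length ``L`` contains ``L - g - 1`` such pairs,
so each protein maps to a 400-dimensional frequency vector

    f_u = n_u / (L - g - 1),   u = 1..400,

where ``n_u`` counts occurrences of the *u*-th dipeptide.  The denominator
is the number of pairs, which makes each vector an exact probability vector
(sums to 1).  Dipeptides are indexed lexicographically by (first, second)
residue: AA, AC, AD, ..., YY.  This fixed order is shared by every module
and serialized output.

Sequences shorter than ``g + 2`` residues contain no g-gap pair at all;
encoding them is an error by default, with an explicit drop policy for
dataset-level encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sequences import (
    AMINO_ACIDS,
    LabeledDataset,
    ProteinSequence,
    as_protein_sequences,
)

N_FEATURES: int = 400

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Dipeptide labels in the fixed lexicographic order (AA, AC, ..., YY).
DIPEPTIDES: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


class DegenerateSequenceError(ValueError):
    """Sequence too short to contain any g-gap pair (L < g + 2)."""

    def __init__(self, seq_id: str, length: int, gap: int):
        self.seq_id = seq_id
        self.length = length
        self.gap = gap
        super().__init__(
            f"sequence {seq_id!r} has length {length} < {gap + 2} required "
            f"for gap {gap}"
        )


def dipeptide_index(first: str, second: str) -> int:
    """Column index of the dipeptide (first, second) in the fixed order."""
    return _AA_INDEX[first] * 20 + _AA_INDEX[second]


def feature_labels(gap: int) -> list[str]:
    """Column labels of the form ``A.gap1.C`` for TSV export."""
    return [f"{d[0]}.gap{gap}.{d[1]}" for d in DIPEPTIDES]


def _encode_residues(seq: ProteinSequence) -> np.ndarray:
    return np.frombuffer(
        seq.residues.encode("ascii"), dtype=np.uint8
    )


_CODE_TO_INDEX = np.full(128, -1, dtype=np.int64)
for _aa, _i in _AA_INDEX.items():
    _CODE_TO_INDEX[ord(_aa)] = _i


def count_ggap_dipeptides(seq: ProteinSequence, gap: int) -> np.ndarray:
    """Count the 400 g-gap dipeptides of ``seq``.

    Pair ``i`` joins residues at positions ``i`` and ``i + gap + 1``
    (0-based), for ``i = 0 .. L - gap - 2``; the counts sum to
    ``L - gap - 1``.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    L = seq.length
    if L < gap + 2:
        raise DegenerateSequenceError(seq.id, L, gap)
    codes = _CODE_TO_INDEX[_encode_residues(seq)]
    first = codes[: L - gap - 1]
    second = codes[gap + 1 :]
    return np.bincount(first * 20 + second, minlength=N_FEATURES).astype(np.int64)


def ggap_frequencies(seq: ProteinSequence, gap: int) -> np.ndarray:
    """The 400-vector of g-gap dipeptide frequencies; sums to 1."""
    counts = count_ggap_dipeptides(seq, gap)
    return counts / float(seq.length - gap - 1)


@dataclass
class GGapFeatureMatrix:
    """An (n_samples, 400) frequency matrix for one gap value.

    ``kept_indices`` maps rows back to positions in the source dataset when
    the drop policy removed degenerate sequences; ``labels`` are re-aligned
    accordingly.
    """

    gap: int
    X: np.ndarray
    labels: np.ndarray
    kept_indices: np.ndarray

    @property
    def m1(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def m2(self) -> int:
        return int(np.sum(self.labels == 0))


ShortPolicy = Literal["error", "drop"]


def encode_sequences(
    sequences: Sequence[ProteinSequence],
    gap: int,
    short_policy: ShortPolicy = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a sequence list; returns (matrix, kept row indices)."""
    rows: list[np.ndarray] = []
    kept: list[int] = []
    for i, seq in enumerate(sequences):
        try:
            rows.append(ggap_frequencies(seq, gap))
        except DegenerateSequenceError:
            if short_policy == "error":
                raise
            continue
        kept.append(i)
    if not rows:
        raise DegenerateSequenceError("<all>", 0, gap)
    return np.vstack(rows), np.asarray(kept, dtype=int)


def encode_dataset(
    dataset: LabeledDataset,
    gap: int,
    short_policy: ShortPolicy = "error",
) -> GGapFeatureMatrix:
    """Encode every sequence of a labeled dataset at one gap value.

    With ``short_policy="drop"``, sequences shorter than ``gap + 2`` are
    removed; the returned ``kept_indices`` records the survivors and the
    group sizes are implicitly recomputed from the re-aligned labels.
    """
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    X, kept = encode_sequences(dataset.sequences, gap, short_policy)
    return GGapFeatureMatrix(
        gap=gap, X=X, labels=dataset.labels[kept], kept_indices=kept
    )


def matrix_to_tsv(matrix: GGapFeatureMatrix, path: str | Path) -> None:
    """Export a feature matrix as TSV: one label column + 400 data columns."""
    df = pd.DataFrame(matrix.X, columns=feature_labels(matrix.gap))
    df.insert(0, "label", matrix.labels)
    df.to_csv(path, sep="\t", index=False)


def matrix_to_libsvm(matrix: GGapFeatureMatrix, path: str | Path) -> None:
    """Export in LibSVM sparse format (1-based feature indices)."""
    with open(path, "w") as handle:
        for row, label in zip(matrix.X, matrix.labels):
            nz = np.nonzero(row)[0]
            feats = " ".join(f"{j + 1}:{row[j]:.10g}" for j in nz)
            handle.write(f"{1 if label == 1 else -1} {feats}\n")


class GGapEncoder(TransformerMixin, BaseEstimator):
    """Transform protein sequences into g-gap dipeptide compositions.

    Parameters
    ----------
    gap : int, default=1
        Number of residues between the two members of each pair.
    short_policy : {"error", "drop"}, default="error"
        What to do with sequences shorter than ``gap + 2``.  Note that
        ``"drop"`` changes the number of output rows; the indices of the
        surviving inputs are stored in ``kept_indices_`` after each
        ``transform`` call.
    """

    def __init__(self, gap: int = 1, short_policy: ShortPolicy = "error"):
        self.gap = gap
        self.short_policy = short_policy

    def fit(self, X: Iterable[ProteinSequence | str], y=None) -> "GGapEncoder":
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.short_policy not in ("error", "drop"):
            raise ValueError("short_policy must be 'error' or 'drop'")
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: Iterable[ProteinSequence | str]) -> np.ndarray:
        self.fit(X)
        sequences = as_protein_sequences(X)
        mat, kept = encode_sequences(sequences, self.gap, self.short_policy)
        self.kept_indices_ = kept
        return mat

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_labels(self.gap), dtype=object)
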