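"""Synthetic two-class sequence benchmarks with planted dipeptide signal.

The generator emulates the structure of a curated two-class protein
benchmark (by default 178 positives vs 226 negatives) without any real
data.  Negatives are drawn i.i.d. from a background residue distribution.
Positives use the same background except that, whenever the residue g*+1
positions back matches the first member of a planted pair (a, b), the
conditional probability of emitting ``b`` is multiplied by the enrichment
factor rho and the position's distribution renormalised.  The class signal
therefore lives exactly in the feature family the pipeline measures —
g-gap dipeptide frequencies at the planted gap — and rho translates
directly into a mean frequency shift for the planted pairs.

With rho = 1 the two classes are exchangeable (a calibration null); the
generator is fully determined by its integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import dipeptide_index, encode_dataset
from .sequences import (
    AMINO_ACIDS,
    NEGATIVE,
    POSITIVE,
    LabeledDataset,
    ProteinSequence,
    write_fasta,
)

#: Approximate natural amino-acid background (SwissProt-like composition),
#: offered as an alternative to the uniform default.
NATURAL_AA_FREQS: dict[str, float] = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

_DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("A", "K"), ("C", "D"), ("E", "F"), ("G", "H"), ("I", "L"),
)


def natural_background() -> np.ndarray:
    p = np.array([NATURAL_AA_FREQS[a] for a in AMINO_ACIDS])
    return p / p.sum()


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic benchmark.

    ``enrichment`` (rho) >= 1 multiplies the conditional probability of the
    second residue of each planted pair at offset gap+1 after its first
    residue, in positives only; rho = 1 is the null.
    """

    n_pos: int = 178
    n_neg: int = 226
    length_range: tuple[int, int] = (80, 300)
    background: np.ndarray | None = None  # None = uniform over 20 residues
    gap: int = 1
    planted_pairs: tuple[tuple[str, str], ...] = _DEFAULT_PAIRS
    enrichment: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both class sizes must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < self.gap + 2:
            raise ValueError(
                f"length range {self.length_range} invalid: need "
                f"L_min >= gap + 2 = {self.gap + 2} and L_min <= L_max"
            )
        if self.enrichment < 1:
            raise ValueError("enrichment factor rho must be >= 1")
        if not np.isfinite(self.enrichment):
            raise ValueError("enrichment factor rho must be finite")
        if len(set(self.planted_pairs)) != len(self.planted_pairs):
            raise ValueError("planted pairs must be distinct")
        for a, b in self.planted_pairs:
            if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
                raise ValueError(f"planted pair ({a}, {b}) outside the alphabet")
        if self.background is not None:
            p = np.asarray(self.background, dtype=float)
            if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("background must be a 20-vector summing to 1")
            self.background = p

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 0.05)
        return self.background

    def to_jsonable(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "length_range": list(self.length_range),
            "background": (
                None if self.background is None else [float(x) for x in self.background]
            ),
            "gap": self.gap,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "enrichment": self.enrichment,
            "seed": self.seed,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "GeneratorSpec":
        return cls(
            n_pos=d["n_pos"],
            n_neg=d["n_neg"],
            length_range=tuple(d["length_range"]),
            background=(None if d["background"] is None else np.asarray(d["background"])),
            gap=d["gap"],
            planted_pairs=tuple(tuple(p) for p in d["planted_pairs"]),
            enrichment=d["enrichment"],
            seed=d["seed"],
        )


@dataclass
class GroundTruth:
    """What was planted, plus the realised per-pair frequency shifts."""

    gap: int
    planted_pairs: tuple[tuple[str, str], ...]
    enrichment: float
    mean_freq_diff: dict[str, float]  # pair label -> mean_pos - mean_neg
    majority_fraction: float


_AA_ARRAY = np.array(list(AMINO_ACIDS))
_AA_TO_INT = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _draw_background_sequence(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    codes = rng.choice(20, size=length, p=p)
    return "".join(_AA_ARRAY[codes])


def _draw_boosted_sequence(
    rng: np.random.Generator,
    length: int,
    p: np.ndarray,
    gap: int,
    boost: dict[int, list[int]],
    rho: float,
) -> str:
    codes = np.empty(length, dtype=int)
    cum_base = np.cumsum(p)
    for i in range(length):
        prev = codes[i - gap - 1] if i >= gap + 1 else -1
        targets = boost.get(prev)
        if targets:
            q = p.copy()
            q[targets] *= rho
            q /= q.sum()
            cum = np.cumsum(q)
        else:
            cum = cum_base
        codes[i] = int(np.searchsorted(cum, rng.random(), side="right"))
    return "".join(_AA_ARRAY[codes])


def generate(spec: GeneratorSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Generate a labeled dataset and its ground-truth record.

    Deterministic given ``spec.seed``.  The ground truth reports the
    realised mean frequency difference (positives minus negatives) of every
    planted pair at the planted gap, computed by encoding the generated
    sequences.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.background_probs()
    lo, hi = spec.length_range
    boost: dict[int, list[int]] = {}
    for a, b in spec.planted_pairs:
        boost.setdefault(_AA_TO_INT[a], []).append(_AA_TO_INT[b])

    sequences: list[ProteinSequence] = []
    for j in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        if spec.enrichment == 1.0:
            residues = _draw_background_sequence(rng, L, p)
        else:
            residues = _draw_boosted_sequence(rng, L, p, spec.gap, boost, spec.enrichment)
        sequences.append(ProteinSequence(id=f"pos_{j}", residues=residues))
    for j in range(spec.n_neg):
        L = int(rng.integers(lo, hi + 1))
        sequences.append(
            ProteinSequence(id=f"neg_{j}", residues=_draw_background_sequence(rng, L, p))
        )
    labels = np.array(
        [POSITIVE] * spec.n_pos + [NEGATIVE] * spec.n_neg, dtype=int
    )
    dataset = LabeledDataset(sequences=sequences, labels=labels)

    mat = encode_dataset(dataset, spec.gap)
    pos_mean = mat.X[mat.labels == POSITIVE].mean(axis=0)
    neg_mean = mat.X[mat.labels == NEGATIVE].mean(axis=0)
    diffs = {
        a + b: float(pos_mean[dipeptide_index(a, b)] - neg_mean[dipeptide_index(a, b)])
        for a, b in spec.planted_pairs
    }
    truth = GroundTruth(
        gap=spec.gap,
        planted_pairs=spec.planted_pairs,
        enrichment=spec.enrichment,
        mean_freq_diff=diffs,
        majority_fraction=max(spec.n_pos, spec.n_neg) / (spec.n_pos + spec.n_neg),
    )
    return dataset, truth


def planted_feature_indices(spec: GeneratorSpec) -> np.ndarray:
    """Column indices of the planted pairs in the fixed dipeptide order."""
    return np.asarray([dipeptide_index(a, b) for a, b in spec.planted_pairs])


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write small canonical FASTA fixtures plus a JSON manifest.

    Fixtures: ``null`` (rho = 1), ``strong_signal`` (rho = 6), ``short_edge``
    (strong signal plus one sequence of length gap + 1, which cannot be
    encoded at the planted gap and exercises the drop policy) and
    ``single_class`` (an empty negative file, the ANOVA error case).
    Returns the manifest dict; the manifest's specs and seeds reproduce the
    FASTA files byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = {
        "null": GeneratorSpec(
            n_pos=20, n_neg=20, length_range=(30, 60), enrichment=1.0, seed=seed
        ),
        "strong_signal": GeneratorSpec(
            n_pos=30, n_neg=30, length_range=(60, 120), enrichment=6.0, seed=seed + 1
        ),
        "short_edge": GeneratorSpec(
            n_pos=15, n_neg=15, length_range=(30, 60), enrichment=6.0, seed=seed + 2
        ),
    }
    manifest: dict = {"seed": seed, "fixtures": {}}
    for name, spec in specs.items():
        dataset, _ = generate(spec)
        pos = [s for s, y in zip(dataset.sequences, dataset.labels) if y == POSITIVE]
        neg = [s for s, y in zip(dataset.sequences, dataset.labels) if y == NEGATIVE]
        if name == "short_edge":
            # one sequence with no pair at the planted gap (L = gap + 1)
            pos = pos + [ProteinSequence(id="pos_short", residues="AC"[: spec.gap + 1])]
        pos_path = out_dir / f"{name}_pos.fasta"
        neg_path = out_dir / f"{name}_neg.fasta"
        write_fasta(pos, pos_path)
        write_fasta(neg, neg_path)
        manifest["fixtures"][name] = {
            "spec": spec.to_jsonable(),
            "positives": pos_path.name,
            "negatives": neg_path.name,
            "extra_short_record": name == "short_edge",
        }
    # error-case fixture: a positives file with records, an empty negatives file
    sc_spec = GeneratorSpec(
        n_pos=5, n_neg=1, length_range=(30, 60), enrichment=1.0, seed=seed + 3
    )
    sc_data, _ = generate(sc_spec)
    pos = [s for s, y in zip(sc_data.sequences, sc_data.labels) if y == POSITIVE]
    write_fasta(pos, out_dir / "single_class_pos.fasta")
    (out_dir / "single_class_neg.fasta").write_text("")
    manifest["fixtures"]["single_class"] = {
        "spec": sc_spec.to_jsonable(),
        "positives": "single_class_pos.fasta",
        "negatives": "single_class_neg.fasta",
        "note": "negative file intentionally empty; loading raises EmptyClassError",
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
        handle.write("\n")
    return manifest
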