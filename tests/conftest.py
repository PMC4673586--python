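import numpy as np
import pytest

from ggaplect import GeneratorSpec, LabeledDataset, ProteinSequence, generate
from ggaplect.sequences import write_fasta


@pytest.fixture
def toy_dataset() -> LabeledDataset:
    """Tiny hand-built two-class dataset (all lengths >= 3)."""
    seqs = [
        ProteinSequence("p1", "ACACACAC"),
        ProteinSequence("p2", "ACACAAC"),
        ProteinSequence("p3", "CACACACA"),
        ProteinSequence("n1", "DEDEDEDE"),
        ProteinSequence("n2", "EDEDEDE"),
        ProteinSequence("n3", "DEDEEDED"),
    ]
    return LabeledDataset(sequences=seqs, labels=np.array([1, 1, 1, 0, 0, 0]))


@pytest.fixture(scope="session")
def planted_dataset():
    """Small strong-signal synthetic benchmark shared across tests."""
    spec = GeneratorSpec(
        n_pos=25, n_neg=35, length_range=(100, 200), enrichment=6.0, seed=7
    )
    dataset, truth = generate(spec)
    return spec, dataset, truth


@pytest.fixture
def fasta_pair(tmp_path, planted_dataset):
    """The planted dataset written out as a (positives, negatives) FASTA pair."""
    spec, dataset, _ = planted_dataset
    pos = [s for s, y in zip(dataset.sequences, dataset.labels) if y == 1]
    neg = [s for s, y in zip(dataset.sequences, dataset.labels) if y == 0]
    pos_path = tmp_path / "pos.fasta"
    neg_path = tmp_path / "neg.fasta"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    return pos_path, neg_path
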