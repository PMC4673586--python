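"""Protein sequence I/O and validation.

Sequences are plain strings over the 20 standard one-letter amino-acid
codes.  FASTA reading/writing goes through Biopython; input is normalised
(uppercased, line wrapping removed) before validation.  Records containing
non-standard codes such as ``B``, ``X``, ``U`` or ``Z`` are rejected in
strict mode and dropped (with a report) in lenient mode — they are never
silently repaired, because residue substitution would change dipeptide
counts downstream.

Class labels come from file membership: one FASTA file of positives and one
of negatives, mirroring the S+ / S- decomposition of a two-class benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Integer class labels used throughout the package.
POSITIVE: int = 1
NEGATIVE: int = 0


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input (e.g. an empty file)."""


class SequenceValidationError(ValueError):
    """Raised when a record contains residues outside the 20-letter alphabet."""

    def __init__(self, record_id: str, bad_chars: Iterable[str]):
        self.record_id = record_id
        self.bad_chars = sorted(set(bad_chars))
        super().__init__(
            f"record {record_id!r} contains illegal character(s) "
            f"{', '.join(repr(c) for c in self.bad_chars)}; "
            f"allowed residues are {AMINO_ACIDS}"
        )


class DuplicateIdError(ValueError):
    """Raised when the same record id appears in both class files."""


class EmptyClassError(ValueError):
    """Raised when a class has no sequences (group statistics undefined)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence: an identifier plus a residue string."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class DroppedRecord:
    """One record removed by lenient-mode validation, with the reason."""

    id: str
    reason: str


@dataclass
class LabeledDataset:
    """Index-aligned sequences and binary class labels.

    ``m1``/``m2`` are the positive/negative group sizes, ``n_total`` the
    sample count and ``n_groups`` the number of classes (always 2).
    """

    sequences: list[ProteinSequence]
    labels: np.ndarray  # int array, POSITIVE / NEGATIVE

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != self.labels.size:
            raise ValueError("sequences and labels must be index-aligned")

    @property
    def m1(self) -> int:
        return int(np.sum(self.labels == POSITIVE))

    @property
    def m2(self) -> int:
        return int(np.sum(self.labels == NEGATIVE))

    @property
    def n_total(self) -> int:
        return len(self.sequences)

    @property
    def n_groups(self) -> int:
        return 2

    def __len__(self) -> int:
        return len(self.sequences)


def validate_residues(record_id: str, residues: str) -> str:
    """Uppercase ``residues`` and check it against the 20-letter alphabet.

    Idempotent on already-valid sequences.  Raises
    :class:`SequenceValidationError` naming the record and the offending
    characters otherwise; empty sequences are also rejected.
    """
    residues = residues.upper()
    if not residues:
        raise SequenceValidationError(record_id, ["<empty>"])
    bad = set(residues) - _AA_SET
    if bad:
        raise SequenceValidationError(record_id, bad)
    return residues


def read_fasta(
    path: str | Path,
    strict: bool = True,
    dropped: list[DroppedRecord] | None = None,
) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Line-wrapped and lowercase records are normalised to a single uppercase
    residue string.  In strict mode any record containing a character
    outside the 20 standard codes raises :class:`SequenceValidationError`.
    In lenient mode (``strict=False``) such records are dropped, logged, and
    appended to ``dropped`` when a list is supplied.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`FastaFormatError` for a file with no FASTA records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[ProteinSequence] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        try:
            residues = validate_residues(record.id, str(record.seq))
        except SequenceValidationError as exc:
            if strict:
                raise
            logger.warning("dropping record %s: %s", record.id, exc)
            if dropped is not None:
                dropped.append(DroppedRecord(id=record.id, reason=str(exc)))
            continue
        out.append(ProteinSequence(id=record.id, residues=residues))
    if n_records == 0:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    """Write sequences to ``path`` in FASTA format (60-column wrapping).

    Round-trips with :func:`read_fasta`: ids and residues are preserved.
    An empty sequence list produces an empty file.
    """
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_dropped_report(dropped: Sequence[DroppedRecord], path: str | Path) -> None:
    """Write a tab-separated report of records removed by lenient validation."""
    with open(path, "w") as handle:
        handle.write("record_id\treason\n")
        for rec in dropped:
            handle.write(f"{rec.id}\t{rec.reason}\n")


def load_labeled_dataset(
    positives: str | Path,
    negatives: str | Path,
    strict: bool = True,
    dropped: list[DroppedRecord] | None = None,
) -> LabeledDataset:
    """Load a two-class dataset from a positive and a negative FASTA file.

    Both classes must be non-empty after validation (the between/within
    group statistics are undefined for an empty group), and record ids must
    not collide across the two files.
    """
    pos = read_fasta(positives, strict=strict, dropped=dropped)
    neg = read_fasta(negatives, strict=strict, dropped=dropped)
    if not pos:
        raise EmptyClassError(f"empty positive class after validation: {positives}")
    if not neg:
        raise EmptyClassError(f"empty negative class after validation: {negatives}")
    shared = {s.id for s in pos} & {s.id for s in neg}
    if shared:
        raise DuplicateIdError(
            f"record id(s) present in both classes: {sorted(shared)[:5]}"
        )
    sequences = list(pos) + list(neg)
    labels = np.array([POSITIVE] * len(pos) + [NEGATIVE] * len(neg), dtype=int)
    return LabeledDataset(sequences=sequences, labels=labels)


def as_protein_sequences(
    sequences: Iterable[ProteinSequence | str],
) -> list[ProteinSequence]:
    """Coerce raw strings to validated :class:`ProteinSequence` objects."""
    out: list[ProteinSequence] = []
    for i, s in enumerate(sequences):
        if isinstance(s, ProteinSequence):
            out.append(s)
        else:
            out.append(ProteinSequence(id=f"seq{i}", residues=validate_residues(f"seq{i}", s)))
    return out
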