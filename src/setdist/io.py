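"""Reading and writing sequence-sets, labeled collections and results.

One FASTA file holds one composite data point (a sequence-set, e.g. the
eight segments of an influenza genome); one directory of FASTA files holds
one labeled class of sequence-sets.  Distance matrices travel as TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .features import DNA, Alphabet
from .metric import DistanceMatrix

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "LabeledCollection",
    "read_sequence_set",
    "read_collection",
    "write_fasta",
    "write_distance_matrix",
    "read_distance_matrix",
]

FASTA_SUFFIXES = {".fasta", ".fa", ".fna"}


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence of a set: an identifier plus residues over an alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """A composite data point: an identifier plus >= 1 sequences.

    ``filtered_counts`` reports, per record, how many symbols outside the
    alphabet were dropped while reading (IUPAC ambiguity codes, N, gaps).
    """

    set_id: str
    sequences: list[SequenceRecord]
    filtered_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("set_id must be nonempty")
        if len(self.sequences) < 1:
            raise ValueError(f"sequence-set {self.set_id!r} must contain >= 1 sequence")
        ids = [r.id for r in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sequence ids in set {self.set_id!r}")

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class LabeledCollection:
    """A labeled class: an ordered collection of sequence-sets."""

    label: str
    sets: list[SequenceSet]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("collection label must be nonempty")
        if len(self.sets) < 1:
            raise ValueError(f"collection {self.label!r} must contain >= 1 set")
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate set_ids in collection {self.label!r}")

    def __len__(self) -> int:
        return len(self.sets)


def read_sequence_set(path, alphabet: Alphabet = DNA) -> SequenceSet:
    """Read one sequence-set from a FASTA file.

    Residues are uppercased; symbols outside the alphabet are removed and
    counted per record in ``filtered_counts``.  A record left empty by
    filtering is an error (it carries no countable information).
    """
    path = Path(path)
    keep = set(alphabet.symbols)
    records: list[SequenceRecord] = []
    filtered: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        kept = "".join(c for c in raw if c in keep)
        if not kept:
            raise ValueError(f"record {rec.id!r} in {path} is empty after alphabet filtering")
        records.append(SequenceRecord(rec.id, kept))
        filtered[rec.id] = len(raw) - len(kept)
    if not records:
        raise ValueError(f"no records in {path}")
    return SequenceSet(path.stem, records, filtered)


def read_collection(directory, alphabet: Alphabet = DNA) -> LabeledCollection:
    """Read one labeled class from a directory of FASTA files.

    The label is the directory name; sets are ordered lexicographically by
    filename.  Files without a FASTA suffix are skipped with a warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValueError(f"{directory} is not a directory")
    sets = []
    for entry in sorted(directory.iterdir(), key=lambda p: p.name):
        if not entry.is_file():
            continue
        if entry.suffix.lower() not in FASTA_SUFFIXES:
            warnings.warn(f"skipping non-FASTA file {entry.name}", stacklevel=2)
            continue
        sets.append(read_sequence_set(entry, alphabet))
    if not sets:
        raise ValueError(f"no FASTA files in {directory}")
    return LabeledCollection(directory.name, sets)


def write_fasta(S: SequenceSet, path, width: int = 60) -> None:
    """Write a sequence-set as FASTA with fixed line wrapping (deterministic bytes)."""
    lines = []
    for rec in S.sequences:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.residues), width):
            lines.append(rec.residues[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    """Write a labeled distance matrix as TSV with full float precision."""
    lines = ["\t".join(["set_id", *D.labels])]
    for label, row in zip(D.labels, D.values):
        lines.append("\t".join([label, *(f"{v:.17g}" for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a TSV distance matrix written by :func:`write_distance_matrix`."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    labels = tuple(header[1:])
    values = np.empty((len(labels), len(labels)))
    for i, line in enumerate(lines[1:]):
        parts = line.split("\t")
        if parts[0] != labels[i]:
            raise ValueError(f"row label {parts[0]!r} does not match column label {labels[i]!r}")
        values[i] = [float(v) for v in parts[1:]]
    return DistanceMatrix(labels, values)
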