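"""Word-count feature extraction and feature-space transformations.

Every sequence of a sequence-set is mapped to a vector of occurrence counts
over a word set Ω (by default all 1-grams of the alphabet).  A transformation
function φ then carries the count vector into a further — possibly
non-linear — feature space: φ₁ is the identity (linear feature space) and
φ₂ squares every component (quadratic feature space).  Stacking the
transformed vectors of all sequences of a set gives the set's feature
matrix, from which its covariance structure is estimated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "DNA",
    "RNA",
    "PROTEIN",
    "WordSet",
    "DNA_1GRAMS",
    "TransformSpec",
    "PHI1",
    "PHI2",
    "FeatureMatrix",
    "count_words",
    "apply_transform",
    "embed_sequence_set",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered finite alphabet of single-character symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("alphabet must be nonempty")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("alphabet symbols must be single characters")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


DNA = Alphabet(("A", "C", "G", "T"))
RNA = Alphabet(("A", "C", "G", "U"))
PROTEIN = Alphabet(tuple("ARNDCQEGHILKMFPSTWYV"))

ALPHABETS = {"DNA": DNA, "RNA": RNA, "PROTEIN": PROTEIN}


@dataclass(frozen=True)
class WordSet:
    """An ordered set of p distinct nonempty words over an alphabet."""

    words: tuple[str, ...]
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("word set must contain at least one word")
        if any(w == "" for w in self.words):
            raise ValueError("the empty word is not allowed")
        if len(set(self.words)) != len(self.words):
            raise ValueError("words must be distinct")
        bad = [w for w in self.words if any(c not in self.alphabet for c in w)]
        if bad:
            raise ValueError(f"words outside the alphabet: {bad}")

    @property
    def p(self) -> int:
        return len(self.words)

    @classmethod
    def ngrams(cls, alphabet: Alphabet = DNA, n: int = 1) -> "WordSet":
        """All n-grams of the alphabet in lexicographic (product) order."""
        if n < 1:
            raise ValueError("n must be >= 1")
        words = tuple("".join(t) for t in itertools.product(alphabet.symbols, repeat=n))
        return cls(words, alphabet)


DNA_1GRAMS = WordSet.ngrams(DNA, 1)


@dataclass(frozen=True)
class TransformSpec:
    """A transformation function φ: R^p -> R^p'.

    Kinds:

    - ``identity`` — φ₁, returns the count vector unchanged (p' = p).
    - ``power`` — elementwise x ** q; q = 2 gives φ₂, the quadratic map
      (p' = p).  Non-integer exponents on negative inputs are rejected;
      count vectors are non-negative, so φ₂ is always safe.
    - ``composite`` — a declared sequence of vector-valued functions whose
      outputs are concatenated; must declare ``output_dim`` and be total on
      R^p (allows dimension-raising maps, p' >= p or otherwise).
    """

    kind: str
    exponent: float = 1.0
    funcs: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()
    input_dim: int | None = None
    output_dim: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"identity", "power", "composite"}:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "power" and not self.exponent > 0:
            raise ValueError("power exponent must be positive")
        if self.kind == "composite":
            if not self.funcs:
                raise ValueError("composite transform needs at least one function")
            if self.output_dim is None:
                raise ValueError("composite transform must declare output_dim")

    @classmethod
    def identity(cls, input_dim: int | None = None) -> "TransformSpec":
        return cls("identity", input_dim=input_dim, output_dim=input_dim)

    @classmethod
    def elementwise_power(cls, q: float, input_dim: int | None = None) -> "TransformSpec":
        return cls("power", exponent=float(q), input_dim=input_dim, output_dim=input_dim)

    @classmethod
    def composite(
        cls,
        funcs: Sequence[Callable[[np.ndarray], np.ndarray]],
        output_dim: int,
        input_dim: int | None = None,
    ) -> "TransformSpec":
        return cls("composite", funcs=tuple(funcs), input_dim=input_dim, output_dim=int(output_dim))


PHI1 = TransformSpec.identity()
PHI2 = TransformSpec.elementwise_power(2.0)


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x p' matrix of transformed feature vectors, one row per sequence."""

    values: np.ndarray
    row_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1:
            raise ValueError("feature matrix must be 2-D with >= 1 row")
        if len(self.row_ids) != values.shape[0]:
            raise ValueError("row_ids length must equal the number of rows")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _count_overlapping(text: str, word: str) -> int:
    count = 0
    start = text.find(word)
    while start != -1:
        count += 1
        start = text.find(word, start + 1)
    return count


def count_words(seq, words: WordSet) -> np.ndarray:
    """Occurrence counts of each word of ``words`` in a sequence record.

    Occurrences of words longer than one symbol are counted with overlap
    (the standard n-gram convention); a word longer than the sequence simply
    scores 0.
    """
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    counts = np.empty(words.p, dtype=float)
    for l, word in enumerate(words.words):
        if len(word) == 1:
            counts[l] = residues.count(word)
        else:
            counts[l] = _count_overlapping(residues, word)
    return counts


def apply_transform(x: np.ndarray, phi: TransformSpec) -> np.ndarray:
    """Apply a transformation function φ to one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("feature vector must be 1-D")
    if phi.input_dim is not None and x.shape[0] != phi.input_dim:
        raise ValueError(f"dimension mismatch: vector has dim {x.shape[0]}, transform expects {phi.input_dim}")
    if phi.kind == "identity":
        return x.copy()
    if phi.kind == "power":
        q = phi.exponent
        if q != int(q) and np.any(x < 0):
            raise ValueError("non-integer power of a negative component is undefined")
        out = np.power(x, q)
    else:  # composite
        pieces = [np.atleast_1d(np.asarray(f(x), dtype=float)) for f in phi.funcs]
        out = np.concatenate(pieces)
        if out.shape[0] != phi.output_dim:
            raise ValueError(
                f"composite transform produced dim {out.shape[0]}, declared output_dim {phi.output_dim}"
            )
    if not np.all(np.isfinite(out)):
        raise ValueError("transform produced non-finite values")
    return out


def embed_sequence_set(
    S,
    words: WordSet = DNA_1GRAMS,
    phi: TransformSpec = PHI1,
    frequencies: bool = False,
) -> FeatureMatrix:
    """Map a sequence-set into feature space, one transformed row per sequence.

    With ``frequencies=True`` counts are divided by the retained sequence
    length before the transform (length-normalized features); the default is
    raw counts, which is what makes length-scaling experiments meaningful.
    """
    rows = []
    ids = []
    for record in S.sequences:
        x = count_words(record, words)
        if frequencies:
            x = x / len(record.residues)
        rows.append(apply_transform(x, phi))
        ids.append(record.id)
    return FeatureMatrix(np.vstack(rows), tuple(ids))
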