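"""Variance-covariance structure of a sequence-set in feature space.

A sequence-set's representation is the p' x p' covariance matrix of its
transformed feature vectors.  Two estimators are provided:

- ``centered=True`` (default): the sample covariance with mean subtraction
  and divisor n - 1.  Real count data have a nonzero mean, so this is the
  literal "variance-covariance" structure.
- ``centered=False``: the uncentered second moment (1/n) Σ x xᵀ, the exact
  algebra of a model that assumes E[φ(X)] = 0.

Rank-deficient (singular) matrices are first-class citizens here — the
distance metric downstream never inverts anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import DNA_1GRAMS, PHI1, FeatureMatrix, TransformSpec, WordSet, embed_sequence_set

__all__ = ["CovStructure", "estimate_cov", "cov_of_set"]


@dataclass(frozen=True)
class CovStructure:
    """The p' x p' covariance structure of one sequence-set."""

    matrix: np.ndarray
    mean: np.ndarray
    n: int
    centered: bool
    set_id: str = ""

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("covariance matrix contains non-finite values")
        if np.max(np.abs(matrix - matrix.T), initial=0.0) > 1e-12 * max(1.0, np.max(np.abs(matrix), initial=0.0)):
            raise ValueError("covariance matrix must be symmetric")
        if mean.shape != (matrix.shape[0],):
            raise ValueError("mean vector dimension must match the matrix")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "mean", mean)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def estimate_cov(F: FeatureMatrix, centered: bool = True, set_id: str = "") -> CovStructure:
    """Estimate the covariance structure of a feature matrix.

    For a single row the centered estimator returns the zero matrix (no
    variation is observable), so singleton sets remain comparable.
    """
    X = F.values
    n = X.shape[0]
    mean = X.mean(axis=0)
    if centered:
        if n == 1:
            M = np.zeros((X.shape[1], X.shape[1]))
        else:
            Xc = X - mean
            M = Xc.T @ Xc / (n - 1)
    else:
        M = X.T @ X / n
    M = (M + M.T) / 2.0
    return CovStructure(M, mean, n, centered, set_id)


def cov_of_set(
    S,
    words: WordSet = DNA_1GRAMS,
    phi: TransformSpec = PHI1,
    centered: bool = True,
    frequencies: bool = False,
) -> CovStructure:
    """Embed a sequence-set and estimate its covariance structure."""
    F = embed_sequence_set(S, words, phi, frequencies=frequencies)
    return estimate_cov(F, centered=centered, set_id=S.set_id)
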