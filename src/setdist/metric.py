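"""The largest-eigenvalue distance δ between covariance structures.

δ(Ψ₁, Ψ₂) is the maximum deviation in variation between two sequence-sets:
the largest |κᵀ(Ψ₁ − Ψ₂)κ| over unit vectors κ, i.e. the largest-magnitude
eigenvalue — the spectral norm — of the symmetric difference Ψ₁ − Ψ₂.  It
is a metric on covariance structures, needs no matrix inverse, and is
therefore well defined on singular (rank-deficient) structures where
Mahalanobis- or Förstner-type measures break down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import CovStructure

__all__ = [
    "MetricResult",
    "DistanceMatrix",
    "delta",
    "pairwise_distances",
    "spectral_norm_oracle",
]


@dataclass(frozen=True)
class MetricResult:
    """δ together with the achieving eigenpair.

    ``eigenvalue`` is the signed largest-magnitude eigenvalue of Ψ₁ − Ψ₂;
    ``value`` = |eigenvalue| is the distance.  The eigenvector κ₁ is unit
    length with its first nonzero component made positive (reproducibility).
    """

    value: float
    eigenvalue: float
    eigenvector: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.eigenvector, dtype=float)
        object.__setattr__(self, "eigenvector", vec)


@dataclass(frozen=True)
class DistanceMatrix:
    """A labeled square symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = tuple(self.labels)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if values.shape != (n, n):
            raise ValueError("distance matrix must be square and match its labels")
        if not np.array_equal(values, values.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diag(values) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)


def _as_matrix(psi) -> np.ndarray:
    M = psi.matrix if isinstance(psi, CovStructure) else np.asarray(psi, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("covariance structure must be a square matrix")
    return M


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    for v in vec:
        if v != 0.0:
            return vec if v > 0 else -vec
    return vec


def delta(psi1, psi2) -> MetricResult:
    """Distance between two covariance structures.

    Accepts :class:`~setdist.covariance.CovStructure` objects or plain
    symmetric arrays.  The sign of the difference matrix is canonicalized
    before the eigensolve so δ(A, B) and δ(B, A) are bitwise identical, and
    an exactly diagonal difference short-circuits to its diagonal entries.
    On a magnitude tie between the extreme eigenvalues the positive
    eigenvalue's pair is reported.
    """
    A, B = _as_matrix(psi1), _as_matrix(psi2)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("covariance structures contain non-finite entries")
    M = A - B
    M = (M + M.T) / 2.0

    d = np.diag(M).copy()
    if np.array_equal(M, np.diag(d)):
        # Diagonal difference: eigenvalues are the diagonal entries.
        hi, lo = int(np.argmax(d)), int(np.argmin(d))
        idx = hi if abs(d[hi]) >= abs(d[lo]) else lo
        lam = d[idx]
        vec = np.zeros(M.shape[0])
        vec[idx] = 1.0
        return MetricResult(abs(lam), lam, vec)

    # Canonical sign: make the first nonzero entry (row-major) positive so
    # that delta(A, B) and delta(B, A) run the identical eigensolve.
    flat = M.ravel()
    nz = np.flatnonzero(flat)
    s = 1.0 if flat[nz[0]] > 0 else -1.0
    w, V = np.linalg.eigh(s * M)
    candidates = [(s * w[0], V[:, 0]), (s * w[-1], V[:, -1])]
    candidates.sort(key=lambda c: (-abs(c[0]), -c[0]))
    lam, vec = candidates[0]
    return MetricResult(abs(lam), lam, _fix_sign(vec))


def pairwise_distances(structures) -> DistanceMatrix:
    """δ between every unordered pair of covariance structures."""
    structures = list(structures)
    if len(structures) < 2:
        raise ValueError("need >= 2 structures for a pairwise distance matrix")
    dims = {(_as_matrix(s).shape[0]) for s in structures}
    if len(dims) != 1:
        raise ValueError("all structures must share one dimension")
    labels = tuple(
        s.set_id if isinstance(s, CovStructure) and s.set_id else f"set{i}"
        for i, s in enumerate(structures)
    )
    n = len(structures)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = delta(structures[i], structures[j]).value
            values[i, j] = v
            values[j, i] = v
    return DistanceMatrix(labels, values)


def spectral_norm_oracle(M: np.ndarray) -> float:
    """Spectral norm by an independent route (largest singular value).

    Verification aid only — the production path is :func:`delta`.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    return float(np.linalg.svd(M, compute_uv=False)[0]) if M.size else 0.0
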