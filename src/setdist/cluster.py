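"""Clustering of sequence-sets from the δ distance matrix.

Agglomerative clustering on the precomputed δ matrix, a classical-MDS 2D
projection, and dispersion maps: per cluster, the medoid and every member's
δ to it, summarizing how tightly a cluster holds together.  A *limiting*
dispersion map regenerates the sets at a large length factor n' before
redoing the whole pipeline, showing the cluster geometry once composition
estimates have converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .covariance import cov_of_set
from .features import DNA_1GRAMS, PHI1, TransformSpec, WordSet
from .metric import DistanceMatrix, pairwise_distances
from .simulate import SimulationConfig, estimate_composition, generate_sequence_set

__all__ = [
    "ClusterAssignment",
    "DispersionMap",
    "hierarchical_cluster",
    "embed_2d",
    "dispersion_map",
    "limiting_dispersion_map",
]

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class ClusterAssignment:
    labels: tuple[str, ...]
    cluster_of: dict
    k: int
    linkage: str

    def __post_init__(self) -> None:
        if set(self.cluster_of) != set(self.labels):
            raise ValueError("every set must be assigned exactly one cluster")
        present = set(self.cluster_of.values())
        if present != set(range(self.k)):
            raise ValueError("all k clusters must be nonempty, numbered 0..k-1")

    def members(self, cluster: int) -> list[str]:
        return [lab for lab in self.labels if self.cluster_of[lab] == cluster]


@dataclass(frozen=True)
class DispersionMap:
    """Medoid-referenced view of one cluster's internal spread."""

    cluster_index: int
    medoid_id: str
    member_distances: dict
    spread_mean: float
    spread_max: float
    coords2d: dict | None = None
    mode: str = "exact"
    factor: float | None = None
    seed: int | None = None


def hierarchical_cluster(D: DistanceMatrix, k: int, linkage: str = "average") -> ClusterAssignment:
    """Agglomerative clustering of a δ matrix, cut at exactly k clusters.

    Rows are pre-sorted lexicographically by label so merge ties break
    deterministically on the smallest label pair; the cut uses the first
    n − k merges, so all k clusters are nonempty even under tied heights.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    n = D.n
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if n == 1 or k == n:
        cluster_of = {lab: i if k == n else 0 for i, lab in enumerate(D.labels)}
        return ClusterAssignment(D.labels, cluster_of, k, linkage)
    order = np.argsort(np.array(D.labels))
    values = D.values[np.ix_(order, order)]
    Z = scipy_linkage(squareform(values, checks=False), method=linkage)
    flat = cut_tree(Z, n_clusters=k).ravel()
    raw = {D.labels[order[i]]: int(flat[i]) for i in range(n)}
    # canonical numbering: clusters in order of first appearance over D.labels
    renumber: dict = {}
    for lab in D.labels:
        renumber.setdefault(raw[lab], len(renumber))
    cluster_of = {lab: renumber[raw[lab]] for lab in D.labels}
    return ClusterAssignment(D.labels, cluster_of, k, linkage)


def embed_2d(D: DistanceMatrix) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a δ matrix into two dimensions.

    Double-centers the squared distances, keeps the top-2 eigenpairs
    (non-positive eigenvalues yield a zero axis), and fixes orientation so
    the first nonzero coordinate of each axis is positive.  Whenever D is
    exactly 2-embeddable the pairwise Euclidean distances of the embedding
    reproduce D.
    """
    n = D.n
    if n < 2:
        raise ValueError("need >= 2 sets to embed")
    D2 = D.values**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    top = np.argsort(w)[::-1][:2]
    floor = 1e-12 * max(1.0, float(np.abs(w).max()))
    coords = np.zeros((n, 2))
    for axis, i in enumerate(top):
        if w[i] > floor:
            coords[:, axis] = V[:, i] * np.sqrt(w[i])
    for axis in range(2):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return pd.DataFrame(coords, index=pd.Index(D.labels, name="set_id"), columns=["x", "y"])


def dispersion_map(
    D: DistanceMatrix,
    assignment: ClusterAssignment,
    coords: pd.DataFrame | None = None,
    mode: str = "exact",
    factor: float | None = None,
    seed: int | None = None,
) -> list[DispersionMap]:
    """Per-cluster medoid, member-to-medoid δ values and spread summaries."""
    if tuple(assignment.labels) != D.labels:
        raise ValueError("assignment labels do not match the distance matrix")
    idx = {lab: i for i, lab in enumerate(D.labels)}
    maps = []
    for c in range(assignment.k):
        members = assignment.members(c)
        rows = [idx[m] for m in members]
        sub = D.values[np.ix_(rows, rows)]
        sums = sub.sum(axis=1)
        best = sums.min()
        medoid = min(m for m, s in zip(members, sums) if s <= best)
        dists = {m: float(D.values[idx[m], idx[medoid]]) for m in members}
        vals = np.array(list(dists.values()))
        maps.append(
            DispersionMap(
                cluster_index=c,
                medoid_id=medoid,
                member_distances=dists,
                spread_mean=float(vals.mean()),
                spread_max=float(vals.max()),
                coords2d=(
                    {m: (float(coords.loc[m, "x"]), float(coords.loc[m, "y"])) for m in members}
                    if coords is not None
                    else None
                ),
                mode=mode,
                factor=factor,
                seed=seed,
            )
        )
    return maps


def limiting_dispersion_map(
    prototype_sets,
    factor: float,
    seed: int,
    words: WordSet = DNA_1GRAMS,
    phi: TransformSpec = PHI1,
    centered: bool = True,
    k: int = 2,
    linkage: str = "average",
) -> list[DispersionMap]:
    """Dispersion maps after regenerating every set at length factor n'.

    Each prototype set is reduced to its composition profile, regenerated
    at the given factor (seeded, one substream per prototype), and the full
    distance/cluster/embedding/dispersion pipeline is recomputed.
    """
    prototype_sets = list(prototype_sets)
    if factor < 1:
        raise ValueError("length factor must be >= 1")
    cfg = SimulationConfig(factor=factor, seed=seed, m=1)
    regenerated = []
    for i, S in enumerate(prototype_sets):
        profile = estimate_composition(S, words.alphabet)
        regenerated.append(generate_sequence_set(profile, cfg, replicate_index=i, set_id=S.set_id))
    covs = [cov_of_set(s, words, phi, centered) for s in regenerated]
    D = pairwise_distances(covs)
    assignment = hierarchical_cluster(D, k, linkage)
    coords = embed_2d(D)
    return dispersion_map(D, assignment, coords, mode="limiting", factor=factor, seed=seed)
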