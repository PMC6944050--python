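"""End-to-end simulation experiments: classification and clustering recovery.

These orchestrate the full pipeline — synthetic heterogeneous prototypes,
sequence generation at a length factor n', covariance structures, the δ
metric, and the mean-rule classifier or average-linkage clustering — and
score the outcome against the known ground truth.  They are the package's
reference experiments for how length scaling affects recoverability: at
large n' composition estimates converge and classes separate cleanly; at
n' = 1 the sampling noise of short sequences can wash the structure out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .classify import classify
from .cluster import ClusterAssignment, hierarchical_cluster
from .covariance import cov_of_set
from .features import DNA_1GRAMS, PHI1, TransformSpec, WordSet
from .metric import pairwise_distances
from .simulate import SimulationConfig, generate_collection, generate_sequence_set, sample_profile

__all__ = ["ClassificationRecovery", "ClusteringRecovery", "classification_recovery", "clustering_recovery"]


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent 31-bit child seeds from one master seed
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass(frozen=True)
class ClassificationRecovery:
    accuracy_pct: float
    n_queries: int
    confusion: dict


@dataclass(frozen=True)
class ClusteringRecovery:
    ari: float
    n_sets: int
    assignment: ClusterAssignment


def classification_recovery(
    seed: int,
    class_probs=((0.4, 0.3, 0.2, 0.1), (0.1, 0.2, 0.3, 0.4)),
    n_sequences: int = 8,
    base_length: int = 1000,
    n_train: int = 10,
    n_query: int = 10,
    factor: float = 100.0,
    words: WordSet = DNA_1GRAMS,
    phi: TransformSpec = PHI1,
    centered: bool = True,
    rule: str = "mean",
) -> ClassificationRecovery:
    """Train-and-query recovery experiment with known class prototypes.

    One heterogeneous composition prototype per class (per-sequence
    compositions scattered around the class base composition), ``n_train``
    generated training sets and ``n_query`` generated queries per class at
    length factor n'.  Returns the percent of queries assigned to their
    true class.
    """
    k = len(class_probs)
    seeds = _child_seeds(seed, 3 * k)
    profiles = [
        sample_profile(f"class{i}", probs, n_sequences, base_length, seed=seeds[i])
        for i, probs in enumerate(class_probs)
    ]
    classes = [
        generate_collection(p, SimulationConfig(factor=factor, seed=seeds[k + i], m=n_train))
        for i, p in enumerate(profiles)
    ]
    correct = 0
    confusion: dict = {}
    for i, p in enumerate(profiles):
        qcfg = SimulationConfig(factor=factor, seed=seeds[2 * k + i], m=n_query)
        for r in range(n_query):
            query = generate_sequence_set(p, qcfg, replicate_index=r, set_id=f"query_{p.set_id}_{r}")
            result = classify(query, classes, rule=rule, words=words, phi=phi, centered=centered)
            key = (classes[i].label, result.label)
            confusion[key] = confusion.get(key, 0) + 1
            correct += result.label == classes[i].label
    n_total = k * n_query
    return ClassificationRecovery(100.0 * correct / n_total, n_total, confusion)


def clustering_recovery(
    seed: int,
    class_probs=((0.4, 0.3, 0.2, 0.1), (0.1, 0.2, 0.3, 0.4), (0.25, 0.25, 0.25, 0.25)),
    n_sequences: int = 8,
    base_length: int = 1000,
    n_sets: int = 10,
    factor: float = 100.0,
    words: WordSet = DNA_1GRAMS,
    phi: TransformSpec = PHI1,
    centered: bool = True,
    linkage: str = "average",
) -> ClusteringRecovery:
    """Cluster generated sets from known prototypes and score against truth.

    Generates ``n_sets`` sets per class at length factor n', clusters the
    pooled δ matrix with the chosen linkage cut at k = number of classes,
    and reports the adjusted Rand index against the generating classes.
    """
    k = len(class_probs)
    seeds = _child_seeds(seed, 2 * k)
    truth = []
    covs = []
    for i, probs in enumerate(class_probs):
        profile = sample_profile(f"class{i}", probs, n_sequences, base_length, seed=seeds[i])
        coll = generate_collection(profile, SimulationConfig(factor=factor, seed=seeds[k + i], m=n_sets))
        for s in coll.sets:
            covs.append(cov_of_set(s, words, phi, centered))
            truth.append(i)
    D = pairwise_distances(covs)
    assignment = hierarchical_cluster(D, k, linkage)
    predicted = [assignment.cluster_of[lab] for lab in D.labels]
    ari = float(adjusted_rand_score(truth, predicted))
    return ClusteringRecovery(ari, len(truth), assignment)
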