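"""Clustering simulated sequence-sets and reading their dispersion maps.

Generates sets from three composition prototypes, clusters the pooled δ
matrix with average linkage, projects the sets into 2D with classical MDS,
and prints the dispersion map of each cluster: its medoid, how far each
member sits from the medoid, and the spread summaries.  The exact map uses
the sets as generated; the limiting map regenerates them at a large length
factor, showing the cluster geometry once compositions have converged.
"""

from setdist import (
    SimulationConfig,
    cov_of_set,
    dispersion_map,
    embed_2d,
    generate_collection,
    hierarchical_cluster,
    limiting_dispersion_map,
    pairwise_distances,
    sample_profile,
)

prototypes = {
    "alpha": (0.4, 0.3, 0.2, 0.1),
    "beta": (0.1, 0.2, 0.3, 0.4),
    "gamma": (0.25, 0.25, 0.25, 0.25),
}

sets = []
for i, (name, probs) in enumerate(prototypes.items()):
    profile = sample_profile(name, probs, n_sequences=8, length=1000, seed=100 + i)
    sets.extend(generate_collection(profile, SimulationConfig(factor=100, seed=200 + i, m=5)).sets)

covs = [cov_of_set(s) for s in sets]
D = pairwise_distances(covs)
assignment = hierarchical_cluster(D, k=3, linkage="average")
coords = embed_2d(D)

for m in dispersion_map(D, assignment, coords):
    print(f"cluster {m.cluster_index}: medoid {m.medoid_id}")
    print(f"  members: {sorted(m.member_distances)}")
    print(f"  spread: mean δ to medoid = {m.spread_mean:.4g}, max = {m.spread_max:.4g}")

# limiting dispersion map: same prototypes regenerated at a larger factor
print("\nlimiting dispersion maps (factor 200):")
for m in limiting_dispersion_map(sets[:6], factor=200, seed=7, k=2):
    print(
        f"cluster {m.cluster_index}: medoid {m.medoid_id}, "
        f"spread mean = {m.spread_mean:.4g} (mode={m.mode}, factor={m.factor:g})"
    )
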