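"""Distance between two sequence-sets via their covariance structures.

Builds two tiny composite data points, embeds them in 1-gram feature space,
estimates each set's covariance structure and prints δ — the spectral norm
of the difference of the two structures — together with the direction
(eigenvector) in which the two sets' variation differs most.
"""

from setdist import SequenceRecord, SequenceSet, cov_of_set, delta, pairwise_distances

set_a = SequenceSet("genomeA", [SequenceRecord("seg1", "AAAACCGT"), SequenceRecord("seg2", "CCCCAAGT")])
set_b = SequenceSet("genomeB", [SequenceRecord("seg1", "ACGTACGT"), SequenceRecord("seg2", "AGCTAGCT")])

psi_a = cov_of_set(set_a)
psi_b = cov_of_set(set_b)
print("covariance structure of genomeA:\n", psi_a.matrix)
print("covariance structure of genomeB:\n", psi_b.matrix)

result = delta(psi_a, psi_b)
# value = max |kappa' (Psi_A - Psi_B) kappa| over unit vectors kappa:
# the largest deviation in variation between the two sets.
print(f"\ndelta(A, B) = {result.value:.6g}")
print(f"achieving eigenvalue {result.eigenvalue:.6g}, eigenvector {result.eigenvector}")

D = pairwise_distances([psi_a, psi_b])
print("\npairwise distance matrix:")
print(D.labels)
print(D.values)
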