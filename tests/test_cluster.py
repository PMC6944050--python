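import numpy as np
import pytest

from setdist import (
    CompositionProfile,
    DistanceMatrix,
    SequenceComposition,
    SimulationConfig,
    dispersion_map,
    embed_2d,
    generate_sequence_set,
    hierarchical_cluster,
    limiting_dispersion_map,
)


def dmat(labels, values):
    return DistanceMatrix(tuple(labels), np.array(values, dtype=float))


class TestHierarchicalCluster:
    def test_two_sets_two_clusters(self):
        a = hierarchical_cluster(dmat("ab", [[0, 2], [2, 0]]), k=2)
        assert sorted(a.cluster_of.values()) == [0, 1]

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_close_pair_merges_first(self, linkage):
        D = dmat("abc", [[0, 1, 10], [1, 0, 10], [10, 10, 0]])
        a = hierarchical_cluster(D, k=2, linkage=linkage)
        assert a.cluster_of["a"] == a.cluster_of["b"] != a.cluster_of["c"]

    def test_k_one_puts_everything_together(self):
        a = hierarchical_cluster(dmat("abc", [[0, 1, 2], [1, 0, 3], [2, 3, 0]]), k=1)
        assert set(a.cluster_of.values()) == {0}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            hierarchical_cluster(dmat("ab", [[0, 1], [1, 0]]), k=3)

    def test_all_zero_distances_still_yield_k_nonempty_clusters(self):
        a = hierarchical_cluster(dmat("abc", np.zeros((3, 3))), k=2)
        assert set(a.cluster_of.values()) == {0, 1}

    def test_label_permutation_invariance_up_to_relabeling(self, rng):
        n = 6
        base = rng.uniform(1, 5, size=(n, n))
        values = np.triu(base, 1)
        values = values + values.T
        labels = [f"s{i}" for i in range(n)]
        a = hierarchical_cluster(dmat(labels, values), k=3)
        perm = rng.permutation(n)
        Dp = dmat([labels[i] for i in perm], values[np.ix_(perm, perm)])
        b = hierarchical_cluster(Dp, k=3)
        groups_a = {frozenset(a.members(c)) for c in range(3)}
        groups_b = {frozenset(b.members(c)) for c in range(3)}
        assert groups_a == groups_b


class TestEmbed2D:
    def test_two_points_at_mutual_distance(self):
        coords = embed_2d(dmat("ab", [[0, 2], [2, 0]]))
        d = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert d == pytest.approx(2.0, abs=1e-9)
        assert coords["y"].abs().max() <= 1e-9

    def test_all_zero_distances_collapse_to_origin(self):
        coords = embed_2d(dmat("abc", np.zeros((3, 3))))
        assert np.abs(coords.values).max() == 0.0

    def test_equilateral_triangle_embeds_exactly(self):
        D = dmat("abc", [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        coords = embed_2d(D)
        for i, a in enumerate("abc"):
            for b in "abc"[i + 1 :]:
                d = np.linalg.norm(coords.loc[a] - coords.loc[b])
                assert d == pytest.approx(1.0, abs=1e-9)

    def test_planar_configuration_reproduced_exactly(self, rng):
        pts = rng.normal(size=(5, 2))
        values = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(values, 0.0)
        values = (values + values.T) / 2
        D = dmat([f"p{i}" for i in range(5)], values)
        coords = embed_2d(D)
        got = np.linalg.norm(coords.values[:, None] - coords.values[None, :], axis=2)
        assert np.abs(got - values).max() <= 1e-9

    def test_orientation_first_nonzero_positive(self, rng):
        pts = rng.normal(size=(4, 2))
        values = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0.0)
        coords = embed_2d(dmat([f"p{i}" for i in range(4)], values))
        for axis in ["x", "y"]:
            col = coords[axis].values
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if nz.size:
                assert col[nz[0]] > 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            embed_2d(dmat("a", [[0.0]]))


class TestDispersionMap:
    def test_identical_members_have_zero_spread(self):
        D = dmat("abc", np.zeros((3, 3)))
        a = hierarchical_cluster(D, k=1)
        (m,) = dispersion_map(D, a)
        assert m.spread_mean == m.spread_max == 0.0
        assert m.member_distances[m.medoid_id] == 0.0

    def test_medoid_minimizes_summed_distance(self):
        D = dmat("abc", [[0, 1, 1], [1, 0, 2], [1, 2, 0]])
        a = hierarchical_cluster(D, k=1)
        (m,) = dispersion_map(D, a)
        assert m.medoid_id == "a"  # row sums 2, 3, 3
        assert m.spread_max == 1.0

    def test_singleton_cluster(self):
        D = dmat("ab", [[0, 5], [5, 0]])
        a = hierarchical_cluster(D, k=2)
        maps = dispersion_map(D, a)
        for m in maps:
            assert len(m.member_distances) == 1
            assert m.spread_mean == 0.0

    def test_spread_bounded_by_matrix_maximum(self, rng):
        n = 7
        base = rng.uniform(0, 9, size=(n, n))
        values = np.triu(base, 1)
        values = values + values.T
        D = dmat([f"s{i}" for i in range(n)], values)
        a = hierarchical_cluster(D, k=3)
        for m in dispersion_map(D, a):
            assert m.spread_max <= values.max()


class TestLimitingDispersionMap:
    @staticmethod
    def _prototypes():
        # Group 0: strongly heterogeneous sets (each sequence dominated by a
        # different base); group 1: compositionally uniform sets.  Their
        # covariance structures differ by orders of magnitude.
        hetero = [
            (0.7, 0.1, 0.1, 0.1),
            (0.1, 0.7, 0.1, 0.1),
            (0.1, 0.1, 0.7, 0.1),
            (0.1, 0.1, 0.1, 0.7),
        ]
        uniform = [(0.25, 0.25, 0.25, 0.25)] * 4
        sets = []
        for i, comps in enumerate([hetero, uniform]):
            for j in range(3):
                profile = CompositionProfile(
                    f"g{i}{j}",
                    tuple(SequenceComposition(f"s{k}", np.array(p), 300) for k, p in enumerate(comps)),
                )
                sets.append(
                    generate_sequence_set(
                        profile, SimulationConfig(factor=1, seed=100 * i + j, m=1), 0, set_id=f"g{i}{j}"
                    )
                )
        return sets

    def test_deterministic_under_fixed_seed(self):
        sets = self._prototypes()
        a = limiting_dispersion_map(sets, factor=1, seed=5, k=2)
        b = limiting_dispersion_map(sets, factor=1, seed=5, k=2)
        assert [m.medoid_id for m in a] == [m.medoid_id for m in b]
        assert [m.member_distances for m in a] == [m.member_distances for m in b]
        assert all(m.mode == "limiting" and m.factor == 1 and m.seed == 5 for m in a)

    def test_separated_groups_recovered_at_large_factor(self):
        from sklearn.metrics import adjusted_rand_score

        sets = self._prototypes()
        maps = limiting_dispersion_map(sets, factor=100, seed=5, k=2)
        truth = {s.set_id: s.set_id[1] for s in sets}
        predicted, expected = [], []
        for m in maps:
            for sid in m.member_distances:
                predicted.append(m.cluster_index)
                expected.append(truth[sid])
        assert adjusted_rand_score(expected, predicted) == 1.0

    def test_relative_spread_shrinks_with_factor(self):
        sets = self._prototypes()

        def relative_spread(maps):
            medoids = [m.medoid_id for m in maps]
            all_ids = [sid for m in maps for sid in m.member_distances]
            # between-medoid distance from the embedding coordinates
            c = {sid: np.array(xy) for m in maps for sid, xy in m.coords2d.items()}
            between = np.linalg.norm(c[medoids[0]] - c[medoids[1]])
            mean_spread = np.mean([m.spread_mean for m in maps])
            return mean_spread / between

        small = limiting_dispersion_map(sets, factor=100, seed=5, k=2)
        large = limiting_dispersion_map(sets, factor=1, seed=5, k=2)
        assert relative_spread(small) < relative_spread(large)
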