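import numpy as np
import pytest

from setdist import (
    DNA,
    SequenceRecord,
    SimulationConfig,
    convergence_diagnostic,
    estimate_composition,
    generate_collection,
    generate_sequence,
    generate_sequence_set,
    sample_profile,
    sliding_window_composition,
    write_fasta,
)
from tests.conftest import make_set


class TestEstimateComposition:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("AACG", [0.5, 0.25, 0.25, 0.0]),
            ("TTTT", [0.0, 0.0, 0.0, 1.0]),
        ],
    )
    def test_relative_frequencies(self, residues, expected):
        profile = estimate_composition(make_set("x", [residues]))
        assert profile.per_sequence[0].base_probs.tolist() == expected
        assert profile.per_sequence[0].length == len(residues)

    def test_order_preserved(self):
        profile = estimate_composition(make_set("x", ["AAAA", "CCCC"]))
        assert [r.seq_id for r in profile.per_sequence] == ["s1", "s2"]

    def test_pseudocount_removes_zeros(self):
        profile = estimate_composition(make_set("x", ["TTTT"]), pseudocount=1.0)
        assert np.all(profile.per_sequence[0].base_probs > 0)


class TestGenerateSequence:
    def test_degenerate_distribution(self):
        rng = np.random.default_rng(0)
        rec = generate_sequence([1.0, 0.0, 0.0, 0.0], 10, rng)
        assert rec.residues == "A" * 10

    def test_empirical_frequencies_converge(self):
        rng = np.random.default_rng(42)
        rec = generate_sequence([0.25] * 4, 10**5, rng)
        for c in DNA.symbols:
            assert rec.residues.count(c) / 10**5 == pytest.approx(0.25, abs=0.01)

    def test_same_seed_same_sequence(self):
        a = generate_sequence([0.4, 0.3, 0.2, 0.1], 500, np.random.default_rng(9))
        b = generate_sequence([0.4, 0.3, 0.2, 0.1], 500, np.random.default_rng(9))
        assert a.residues == b.residues

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_sequence([1.0, 0, 0, 0], 0, np.random.default_rng(0))


class TestGenerateSequenceSet:
    @pytest.mark.parametrize("factor,expected", [(1, 250), (100, 25000), (200, 50000)])
    def test_length_scaling(self, factor, expected):
        profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=2, length=250, seed=3)
        S = generate_sequence_set(profile, SimulationConfig(factor=factor, seed=1, m=1), 0)
        assert all(len(r) == expected for r in S.sequences)

    def test_one_sequence_per_prototype_row(self):
        profile = sample_profile("p", (0.25,) * 4, n_sequences=5, length=100, seed=3)
        S = generate_sequence_set(profile, SimulationConfig(factor=1, seed=1, m=1), 0)
        assert len(S) == 5
        assert [r.id for r in S.sequences] == [c.seq_id for c in profile.per_sequence]


class TestGenerateCollection:
    def test_m_sets_with_replicate_suffixes(self):
        profile = sample_profile("p", (0.25,) * 4, n_sequences=2, length=50, seed=3)
        coll = generate_collection(profile, SimulationConfig(factor=1, seed=1, m=20))
        assert len(coll) == 20
        assert coll.sets[0].set_id != coll.sets[1].set_id

    def test_same_seed_identical_collections(self):
        profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=2, length=80, seed=3)
        cfg = SimulationConfig(factor=2, seed=5, m=3)
        a, b = generate_collection(profile, cfg), generate_collection(profile, cfg)
        for sa, sb in zip(a.sets, b.sets):
            assert [r.residues for r in sa.sequences] == [r.residues for r in sb.sequences]

    def test_different_seeds_differ(self):
        profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=2, length=80, seed=3)
        a = generate_collection(profile, SimulationConfig(factor=1, seed=5, m=1))
        b = generate_collection(profile, SimulationConfig(factor=1, seed=6, m=1))
        assert [r.residues for r in a.sets[0].sequences] != [r.residues for r in b.sets[0].sequences]

    def test_fasta_output_byte_deterministic(self, tmp_path):
        profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=2, length=100, seed=3)
        cfg = SimulationConfig(factor=1, seed=5, m=2)
        for run in ("one", "two"):
            d = tmp_path / run
            d.mkdir()
            for s in generate_collection(profile, cfg).sets:
                write_fasta(s, d / f"{s.set_id}.fasta")
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()


class TestConvergenceDiagnostic:
    def test_median_tv_decreases_with_factor(self):
        profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=4, length=500, seed=3)
        report = convergence_diagnostic(profile, [1, 10, 100], reps=10, seed=11)
        m = [report.median(f) for f in (1.0, 10.0, 100.0)]
        assert m[0] > m[1] > m[2]

    def test_tv_within_unit_interval(self):
        profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=2, length=100, seed=3)
        report = convergence_diagnostic(profile, [1, 5], reps=5, seed=11)
        for f in report.factors:
            assert np.all((report.tv[f] >= 0) & (report.tv[f] <= 1))

    def test_degenerate_composition_has_zero_tv(self):
        S = make_set("p", ["AAAA" * 25])
        profile = estimate_composition(S)
        report = convergence_diagnostic(profile, [1, 10], reps=3, seed=1)
        for f in report.factors:
            assert np.all(report.tv[f] == 0.0)

    def test_invalid_inputs_rejected(self):
        profile = sample_profile("p", (0.25,) * 4, n_sequences=2, length=50, seed=3)
        with pytest.raises(ValueError):
            convergence_diagnostic(profile, [0.5, 1], reps=5, seed=1)
        with pytest.raises(ValueError):
            convergence_diagnostic(profile, [1, 10], reps=2, seed=1)


def test_round_trip_composition_recovery():
    profile = sample_profile("p", (0.4, 0.3, 0.2, 0.1), n_sequences=4, length=100, seed=3)
    S = generate_sequence_set(profile, SimulationConfig(factor=1000, seed=2, m=1), 0)
    est = estimate_composition(S)
    for got, want in zip(est.per_sequence, profile.per_sequence):
        assert np.abs(got.base_probs - want.base_probs).max() < 0.01


class TestSlidingWindowComposition:
    def test_block_sequence(self):
        table = sliding_window_composition(SequenceRecord("s", "AAAACCCC"), window=4, step=4)
        assert table.values.tolist() == [[1, 0, 0, 0], [0, 1, 0, 0]]
        assert table.index.tolist() == [0, 4]

    def test_full_window_matches_composition(self):
        rec = SequenceRecord("s", "AACGTTGG")
        table = sliding_window_composition(rec, window=len(rec.residues), step=1)
        profile = estimate_composition(make_set("x", [rec.residues]))
        assert table.iloc[0].values.tolist() == profile.per_sequence[0].base_probs.tolist()

    def test_step_one_offsets(self):
        table = sliding_window_composition(SequenceRecord("s", "ACGT"), window=2, step=1)
        assert len(table) == 3

    def test_window_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_composition(SequenceRecord("s", "ACG"), window=4, step=1)
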