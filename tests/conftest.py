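import numpy as np
import pytest

from setdist import SequenceRecord, SequenceSet


def make_set(set_id, residues_list):
    return SequenceSet(set_id, [SequenceRecord(f"s{i+1}", r) for i, r in enumerate(residues_list)])


def random_psd(rng, dim, rank=None):
    """Random PSD matrix of the given dimension; rank < dim gives a singular one."""
    G = rng.normal(size=(dim, rank if rank is not None else dim))
    M = G @ G.T
    return (M + M.T) / 2.0


@pytest.fixture
def fasta_file(tmp_path):
    def _write(name, records):
        lines = []
        for rid, seq in records:
            lines.append(f">{rid}")
            lines.append(seq)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def class_dir(tmp_path):
    def _write(dirname, files):
        d = tmp_path / dirname
        d.mkdir(parents=True, exist_ok=True)
        for fname, records in files.items():
            lines = []
            for rid, seq in records:
                lines.append(f">{rid}")
                lines.append(seq)
            (d / fname).write_text("\n".join(lines) + "\n")
        return d

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
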