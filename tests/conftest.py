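import numpy as np
import pytest

from seqsvm.groups import PropertyGroupTable
from seqsvm.matrix import LabeledFeatureMatrix


@pytest.fixture(scope="session")
def table() -> PropertyGroupTable:
    return PropertyGroupTable.default()


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write a FASTA file from (id, sequence) pairs; returns the path."""

    def _write(entries, name="in.fasta", wrap=None):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n")
                if wrap:
                    for i in range(0, len(seq), wrap):
                        fh.write(seq[i : i + wrap] + "\n")
                else:
                    fh.write(seq + "\n")
        return path

    return _write


def random_peptide(rng: np.random.Generator, min_len: int = 1, max_len: int = 10) -> str:
    from seqsvm.groups import AMINO_ACIDS

    L = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=L))


@pytest.fixture
def blobs_matrix():
    """Well-separated two-class Gaussian blobs as a LabeledFeatureMatrix."""

    def _make(n_pos=20, n_neg=20, d=4, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        Xp = rng.normal(sep, 1.0, size=(n_pos, d))
        Xn = rng.normal(0.0, 1.0, size=(n_neg, d))
        return LabeledFeatureMatrix(
            X=np.vstack([Xp, Xn]),
            y=np.array([1] * n_pos + [-1] * n_neg),
            feature_names=[f"f{i}" for i in range(d)],
        )

    return _make
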