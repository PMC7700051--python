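import numpy as np
import pytest

from amyloidkit.io_fasta import ProteinRecord, write_fasta
from amyloidkit.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fasta_pair(tmp_path):
    """Two small FASTA files: 2 positives, 3 negatives."""
    pos = [
        ProteinRecord("p1", "ACDEFGHIKL", 1),
        ProteinRecord("p2", "MNPQRSTVWY", 1),
    ]
    neg = [
        ProteinRecord("n1", "AAAACCCC", 0),
        ProteinRecord("n2", "KLVFFAKLVFFA", 0),
        ProteinRecord("n3", "GGGSSGGSS", 0),
    ]
    ppath = tmp_path / "pos.fasta"
    npath = tmp_path / "neg.fasta"
    write_fasta(pos, ppath)
    write_fasta(neg, npath)
    return ppath, npath


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic records (20 pos / 40 neg), lengths 30-80, no planted signal."""
    spec = SyntheticSpec(n_pos=20, n_neg=40, length_range=(30, 80), seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def separable_xy():
    """Linearly separable 2-feature binary problem, 200 samples."""
    rng = np.random.default_rng(5)
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2))
    X[y == 1, 0] += 8.0
    return X, y
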