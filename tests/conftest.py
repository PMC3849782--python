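import numpy as np
import pytest

import fuzzyfam as ff


@pytest.fixture
def two_entry_fasta(tmp_path):
    p = tmp_path / "two.fasta"
    p.write_text(">a\nACDE\n>b\nMKV\n")
    return p


@pytest.fixture
def line_dissim():
    """Four points on a line at {0, 0.1, 10, 10.1}: two obvious pairs."""
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    d = np.abs(pts[:, None] - pts[None, :])
    return ff.DissimilarityMatrix([f"p{i}" for i in range(4)], d)


@pytest.fixture
def family_set():
    """Default two-family synthetic set with its encoding."""
    spec = ff.FamilySpec(seed=7)
    records, hits, truth = ff.generate_family_set(spec)
    space, vectors = ff.build_feature_matrix(records, hits)
    D = ff.dissimilarity_matrix(space, vectors)
    return records, hits, truth, D


def random_dissim(rng, n):
    """Euclidean dissimilarity over random planar points."""
    X = rng.random((n, 2)) * 10
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return ff.DissimilarityMatrix([f"o{i}" for i in range(n)], d)
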