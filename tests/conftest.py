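import numpy as np
import pytest

from snpclust import SNPMatrix


@pytest.fixture
def tiny_matrix() -> SNPMatrix:
    """3 samples x 4 loci, biallelic, no missing data."""
    calls = np.array([
        ["A", "T", "G", "C"],
        ["A", "C", "G", "C"],
        ["T", "C", "A", "C"],
    ])
    return SNPMatrix(["s1", "s2", "s3"], ["l1", "l2", "l3", "l4"], calls)


@pytest.fixture
def matrix_with_missing() -> SNPMatrix:
    calls = np.array([
        ["A", "T", "N"],
        ["A", "N", "G"],
        ["T", "T", "G"],
        ["A", "T", "G"],
    ])
    return SNPMatrix(["a", "b", "c", "d"], ["l1", "l2", "l3"], calls)


def random_snp_matrix(rng: np.random.Generator, n: int = 5, L: int = 5,
                      missing_rate: float = 0.0) -> SNPMatrix:
    """Random biallelic homozygous panel for property tests."""
    letters = np.array(list("ACGT"))
    calls = np.empty((n, L), dtype="<U1")
    for j in range(L):
        pair = rng.choice(4, size=2, replace=False)
        calls[:, j] = letters[np.where(rng.random(n) < 0.5, pair[0], pair[1])]
    if missing_rate:
        calls[rng.random((n, L)) < missing_rate] = "N"
    return SNPMatrix([f"s{i}" for i in range(n)], [f"l{j}" for j in range(L)], calls)
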