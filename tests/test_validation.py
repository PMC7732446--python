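"""Validity indexes against brute-force oracles and scikit-learn, plus the
optimal-K scan and selection rules."""

import numpy as np
import pytest

from snpclust import davies_bouldin, scan_k, select_k, silhouette
from snpclust.validation import ValidationTable, selection_report


# ------------------------------------------------------------------ oracles

def brute_silhouette(X, labels):
    n = len(X)
    D = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in set(labels) if c != labels[i]
        )
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return sum(vals) / n


def brute_davies_bouldin(X, labels):
    cl = sorted(set(labels))
    cent = {c: X[[i for i, l in enumerate(labels) if l == c]].mean(axis=0) for c in cl}
    S = {c: np.mean([np.linalg.norm(X[i] - cent[c])
                     for i, l in enumerate(labels) if l == c]) for c in cl}
    total = 0.0
    for ci in cl:
        total += max(
            (S[ci] + S[cj]) / np.linalg.norm(cent[ci] - cent[cj])
            for cj in cl if cj != ci
        )
    return total / len(cl)


def random_instances(n_instances=60, max_n=12):
    for seed in range(n_instances):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, max_n + 1))
        K = int(rng.integers(2, min(n, 5)))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        labels = np.concatenate([np.arange(K), rng.integers(0, K, n - K)])
        rng.shuffle(labels)
        yield X, labels


def test_silhouette_matches_brute_force():
    for X, labels in random_instances():
        assert silhouette(X, labels) == pytest.approx(
            brute_silhouette(X, labels), abs=1e-12)


def test_davies_bouldin_matches_brute_force():
    for X, labels in random_instances():
        assert davies_bouldin(X, labels) == pytest.approx(
            brute_davies_bouldin(X, labels), abs=1e-12)


def test_indexes_match_sklearn():
    from sklearn.metrics import davies_bouldin_score, silhouette_score

    for X, labels in random_instances(20):
        assert silhouette(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-9)
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels), rel=1e-6)


# ---------------------------------------------------------- special values

def test_duplicated_point_clusters():
    X = np.repeat([[0.0, 0.0], [5.0, 5.0]], 3, axis=0)
    labels = [0, 0, 0, 1, 1, 1]
    assert silhouette(X, labels) == 1.0      # a = 0, b > 0
    assert davies_bouldin(X, labels) == 0.0  # zero scatter


def test_all_singletons_silhouette_zero():
    X = np.array([[0.0], [1.0], [3.0], [7.0]])
    assert silhouette(X, [0, 1, 2, 3]) == 0.0


def test_davies_bouldin_hand_example():
    X = np.array([0.0, 2.0, 10.0, 12.0])[:, None]
    assert davies_bouldin(X, [0, 0, 1, 1]) == pytest.approx(0.2)


def test_degenerate_inputs():
    X = np.zeros((4, 2))
    X[2:] = 1.0
    with pytest.raises(ValueError, match="2 clusters"):
        silhouette(X, [0, 0, 0, 0])
    with pytest.raises(ValueError, match="coincident"):
        davies_bouldin(np.zeros((4, 2)), [0, 0, 1, 1])
    with pytest.raises(ValueError, match="3 samples"):
        silhouette(np.zeros((2, 1)), [0, 1])


def test_range_bounds_on_random_labelings():
    """SC in [-1, 1] and DBI >= 0 over 1,000 random labelings."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(4, 10))
        X = rng.normal(size=(n, 2))
        K = int(rng.integers(2, n))
        labels = np.concatenate([np.arange(K), rng.integers(0, K, n - K)])
        rng.shuffle(labels)
        assert -1.0 <= silhouette(X, labels) <= 1.0
        cent = [X[labels == c].mean(axis=0) for c in np.unique(labels)]
        if len(np.unique(np.round(np.array(cent), 12), axis=0)) == len(cent):
            assert davies_bouldin(X, labels) >= 0.0


def test_rigid_motion_and_scale_invariance():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(15, 3))
    labels = rng.integers(0, 3, 15)
    labels[:3] = [0, 1, 2]
    sc0, db0 = silhouette(X, labels), davies_bouldin(X, labels)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    Y = 3.5 * (X @ R.T) + np.array([2.0, -1.0, 0.5])
    assert silhouette(Y, labels) == pytest.approx(sc0, abs=1e-9)
    assert davies_bouldin(Y, labels) == pytest.approx(db0, abs=1e-9)


# ------------------------------------------------------------------- scans

def two_blob_embedding(seed=0, n=30):
    rng = np.random.default_rng(seed)
    return np.vstack([rng.normal(0.0, 0.5, size=(n, 2)),
                      rng.normal(6.0, 0.5, size=(n, 2))])


@pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
def test_scan_selects_two_for_separated_blobs(method):
    emb = two_blob_embedding()
    table = scan_k(emb, method, range(2, 10), seed=0)
    df = table.to_frame()
    assert len(df) == 8 and sorted(df["K"]) == list(range(2, 10))
    assert select_k(table) == 2
    assert df.loc[df["K"] == 2, "sc"].item() == df["sc"].max()


def test_scan_single_k_and_determinism():
    emb = two_blob_embedding(1)
    t1 = scan_k(emb, "kmeans", [2], seed=5)
    assert len(t1.rows) == 1
    t2 = scan_k(emb, "kmeans", range(2, 6), seed=5)
    t3 = scan_k(emb, "kmeans", range(2, 6), seed=5)
    assert t2.rows == t3.rows
    with pytest.raises(ValueError, match="empty"):
        scan_k(emb, "kmeans", [], seed=0)
    with pytest.raises(ValueError, match="exceeds"):
        scan_k(emb[:4], "kmeans", range(2, 10), seed=0)


def test_select_k_tie_breaks_and_criteria():
    t = ValidationTable()
    for K, sc, dbi in [(2, 0.08, 2.9), (3, 0.07, 2.7), (4, 0.08, 2.5), (5, 0.08, 2.7)]:
        t.add(K, "le", "hierarchical", sc, dbi)
    assert select_k(t, "sc_max") == 2          # tie at K=2,4,5 -> smallest
    assert select_k(t, "dbi_min") == 4
    rep = selection_report(t)
    assert rep == {"k_sc": 2, "k_dbi": 4, "agree": False}
    with pytest.raises(ValueError, match="criterion"):
        select_k(t, "gap")
    with pytest.raises(ValueError, match="empty"):
        select_k(ValidationTable())


def test_validation_table_invariants():
    t = ValidationTable()
    t.add(2, "pca", "kmeans", 0.5, 0.4)
    with pytest.raises(ValueError, match="duplicate"):
        t.add(2, "pca", "kmeans", 0.6, 0.3)
    with pytest.raises(ValueError, match="outside"):
        t.add(3, "pca", "kmeans", 1.5, 0.3)
    with pytest.raises(ValueError, match="negative"):
        t.add(3, "pca", "kmeans", 0.5, -0.1)
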