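"""K-means and agglomerative hierarchical clustering of sample embeddings.

K-means is Lloyd's algorithm with k-means++ seeding, multiple seeded
restarts (best of by within-cluster sum of squares), a 300-iteration cap,
and empty-cluster repair by reassigning the farthest point. The WCSS is
checked to be non-increasing across Lloyd iterations on every run.

Hierarchical clustering delegates to scipy's agglomerative linkage on
Euclidean distances; labels come from cutting the merge tree at K clusters
and are renumbered by first appearance so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = ["ClusteringResult", "kmeans", "hierarchical", "pairwise_distances"]

LINKAGES = ("ward", "average", "complete", "single")


@dataclass
class ClusteringResult:
    """Cluster labels plus method metadata.

    ``labels`` are integers in [0, K) with every index used at least once.
    ``objective`` is the WCSS for K-means, None for hierarchical.
    ``merge_history`` (hierarchical only) is a list of
    ``(cluster_a, cluster_b, height, size)`` rows in scipy linkage
    convention.
    """

    labels: np.ndarray
    K: int
    method: str
    objective: Optional[float] = None
    merge_history: Optional[list] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        used = np.unique(self.labels)
        if not (used.min() >= 0 and used.max() < self.K and len(used) == self.K):
            raise ValueError(f"labels must use every index in [0, {self.K})")


def pairwise_distances(emb: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    emb = _check_embedding(emb)
    return squareform(pdist(emb, metric="euclidean"))


def _check_embedding(emb: np.ndarray) -> np.ndarray:
    emb = np.asarray(emb, dtype=np.float64)
    if emb.ndim == 1:
        emb = emb[:, None]
    if emb.ndim != 2 or emb.shape[0] == 0:
        raise ValueError("embedding must be a non-empty 2-D array")
    if not np.isfinite(emb).all():
        raise ValueError("embedding contains non-finite values")
    return emb


def _wcss(emb: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((emb - centers[labels]) ** 2).sum())


def _kmeans_pp(emb: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: D^2-weighted sequential center choice."""
    n = emb.shape[0]
    centers = np.empty((K, emb.shape[1]))
    centers[0] = emb[rng.integers(n)]
    d2 = ((emb - centers[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[k] = emb[idx]
        d2 = np.minimum(d2, ((emb - centers[k]) ** 2).sum(axis=1))
    return centers


def _lloyd(emb: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """Lloyd iterations to an assignment fixed point; returns labels, centers,
    final WCSS. Asserts the per-iteration WCSS monotonicity invariant."""
    K = centers.shape[0]
    prev_labels = None
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = cdist(emb, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        # empty-cluster repair: move each empty center to the farthest point
        for k in range(K):
            if not (labels == k).any():
                far = d2[np.arange(len(labels)), labels].argmax()
                centers[k] = emb[far]
                labels[far] = k
        obj = _wcss(emb, labels, centers)
        if obj > prev_obj + 1e-9 * max(1.0, prev_obj):
            raise AssertionError("WCSS increased across a Lloyd iteration")
        for k in range(K):
            centers[k] = emb[labels == k].mean(axis=0)
        obj = _wcss(emb, labels, centers)
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels, prev_obj = labels, obj
    return labels, centers, _wcss(emb, labels, centers)


def kmeans(emb: np.ndarray, K: int, n_restarts: int = 10, seed: int = 0) -> ClusteringResult:
    """Best-of-``n_restarts`` K-means (k-means++ / Lloyd), seeded."""
    emb = _check_embedding(emb)
    n = emb.shape[0]
    if not 2 <= K <= n:
        raise ValueError(f"K must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers = _kmeans_pp(emb, K, rng)
        labels, centers, obj = _lloyd(emb, centers)
        if best is None or obj < best[2]:
            best = (labels, centers, obj)
    labels, centers, obj = best
    labels = _relabel_by_first_appearance(labels, K)
    return ClusteringResult(labels, K, "kmeans", objective=obj,
                            params={"n_restarts": n_restarts, "seed": seed})


def _relabel_by_first_appearance(labels: np.ndarray, K: int) -> np.ndarray:
    mapping, nxt = {}, 0
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = nxt
            nxt += 1
        out[i] = mapping[l]
    assert nxt == K
    return out


def hierarchical(emb: np.ndarray, K: int, linkage_method: str = "ward") -> ClusteringResult:
    """Agglomerative clustering on Euclidean distances, cut at K clusters."""
    emb = _check_embedding(emb)
    n = emb.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}]")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    Z = linkage(emb, method=linkage_method, metric="euclidean")
    labels = fcluster(Z, t=K, criterion="maxclust") - 1
    labels = _relabel_by_first_appearance(labels, len(np.unique(labels)))
    merge_history = [
        (int(a), int(b), float(h), int(sz)) for a, b, h, sz in Z
    ]
    return ClusteringResult(labels, int(labels.max()) + 1, "hierarchical",
                            merge_history=merge_history,
                            params={"linkage": linkage_method})
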