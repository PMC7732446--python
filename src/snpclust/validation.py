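"""Internal cluster validity: silhouette coefficient, Davies-Bouldin index,
and the optimal-K scan.

Silhouette: s(i) = (b(i) - a(i)) / max(a(i), b(i)), where a(i) is the mean
distance to the other members of i's cluster and b(i) the smallest mean
distance to another cluster; singleton clusters get s(i) = 0, as does the
degenerate a = b = 0 case. The score is the mean over samples, in [-1, 1].

Davies-Bouldin: DBI = (1/K) sum_i max_{j != i} (S_i + S_j) / M_ij with S_i
the mean member-to-centroid distance and M_ij the centroid separation;
non-negative, lower is better. Coincident centroids raise (the ratio is
undefined).

Both indexes are computed in the same embedding space used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cluster import hierarchical, kmeans, pairwise_distances

__all__ = ["ValidationTable", "silhouette", "davies_bouldin", "scan_k", "select_k"]


def _check_labels(emb: np.ndarray, labels) -> tuple:
    emb = np.asarray(emb, dtype=np.float64)
    if emb.ndim == 1:
        emb = emb[:, None]
    labels = np.asarray(labels)
    if labels.shape[0] != emb.shape[0]:
        raise ValueError("labels length must equal number of samples")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    return emb, labels, uniq


def silhouette(emb: np.ndarray, labels) -> float:
    """Mean silhouette coefficient (see module docstring)."""
    emb, labels, uniq = _check_labels(emb, labels)
    n = emb.shape[0]
    if n < 3:
        raise ValueError("silhouette needs at least 3 samples")
    D = pairwise_distances(emb)
    # mean distance from every point to every cluster
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        ci = labels[i]
        own = members[ci]
        if len(own) == 1:
            continue  # singleton convention: s(i) = 0
        a = D[i, own].sum() / (len(own) - 1)
        b = min(D[i, members[c]].mean() for c in uniq if c != ci)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def davies_bouldin(emb: np.ndarray, labels) -> float:
    """Davies-Bouldin index (see module docstring)."""
    emb, labels, uniq = _check_labels(emb, labels)
    centroids = np.stack([emb[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array([
        np.linalg.norm(emb[labels == c] - centroids[k], axis=1).mean()
        for k, c in enumerate(uniq)
    ])
    K = len(uniq)
    M = pairwise_distances(centroids)
    off = ~np.eye(K, dtype=bool)
    if (M[off] == 0).any():
        raise ValueError("coincident centroids: Davies-Bouldin ratio undefined")
    R = (scatter[:, None] + scatter[None, :]) / np.where(off, M, np.inf)
    return float(R.max(axis=1).mean())


@dataclass
class ValidationTable:
    """Grid of SC / DBI values over (K, reduction method, clustering method)."""

    rows: list = field(default_factory=list)

    def add(self, K: int, reduction: str, clustering: str, sc: float, dbi: float):
        if any(r["K"] == K and r["reduction"] == reduction and r["clustering"] == clustering
               for r in self.rows):
            raise ValueError(f"duplicate row for K={K}, {reduction}, {clustering}")
        if not -1 - 1e-9 <= sc <= 1 + 1e-9:
            raise ValueError(f"silhouette {sc} outside [-1, 1]")
        if dbi < 0:
            raise ValueError(f"Davies-Bouldin {dbi} negative")
        self.rows.append({"K": int(K), "reduction": reduction,
                          "clustering": clustering, "sc": float(sc), "dbi": float(dbi)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["K", "reduction", "clustering", "sc", "dbi"])

    def to_wide(self) -> pd.DataFrame:
        """K x (reduction, clustering, index) grid shaped like a validation-index table."""
        df = self.to_frame()
        return df.pivot_table(index="K", columns=["clustering", "reduction"],
                              values=["sc", "dbi"], sort=False)


def scan_k(
    emb: np.ndarray,
    clustering_method: str = "hierarchical",
    k_range: Iterable[int] = range(2, 10),
    seed: int = 0,
    reduction: str = "unspecified",
    linkage: str = "ward",
    n_restarts: int = 10,
) -> ValidationTable:
    """Cluster at each K in ``k_range`` and record SC and DBI per K."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty K range")
    emb = np.asarray(emb, dtype=np.float64)
    if max(ks) > emb.shape[0]:
        raise ValueError(f"max K {max(ks)} exceeds sample count {emb.shape[0]}")
    table = ValidationTable()
    for K in ks:
        if clustering_method == "kmeans":
            res = kmeans(emb, K, n_restarts=n_restarts, seed=seed)
        elif clustering_method == "hierarchical":
            res = hierarchical(emb, K, linkage_method=linkage)
        else:
            raise ValueError(f"unknown clustering method {clustering_method!r}")
        table.add(K, reduction, clustering_method,
                  silhouette(emb, res.labels), davies_bouldin(emb, res.labels))
    return table


def select_k(table: ValidationTable, criterion: str = "sc_max") -> int:
    """Optimal K: argmax SC or argmin DBI, ties broken toward smaller K.

    When the two criteria disagree the choice follows ``criterion``; use
    :func:`selection_report` to surface the disagreement.
    """
    df = table.to_frame()
    if df.empty:
        raise ValueError("empty validation table")
    if criterion == "sc_max":
        agg = df.groupby("K")["sc"].mean()
        return int(agg[agg == agg.max()].index.min())
    if criterion == "dbi_min":
        agg = df.groupby("K")["dbi"].mean()
        return int(agg[agg == agg.min()].index.min())
    raise ValueError("criterion must be 'sc_max' or 'dbi_min'")


def selection_report(table: ValidationTable) -> dict:
    """Both selections plus a disagreement flag."""
    k_sc = select_k(table, "sc_max")
    k_dbi = select_k(table, "dbi_min")
    return {"k_sc": k_sc, "k_dbi": k_dbi, "agree": k_sc == k_dbi}
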