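"""Cross-tab assignment evaluation: confusion counts, optimal cluster-to-
subpopulation matching, and the percent-correct-assignment (%CA) statistic.

Clusters are matched to subpopulations by the injective map maximising the
total matched count (Hungarian assignment; for a 2x2 table this is simply
the better-trace orientation). %CA is 100 x matched / n, reported both
unrounded and rounded half-up to the nearest integer percent. Unmatched
clusters (when K != G) contribute zero correct assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["ConfusionTable", "cross_tab", "match_clusters", "percent_correct",
           "evaluate_assignment"]


@dataclass
class ConfusionTable:
    """K x G contingency table: rows = predicted clusters, columns = true
    subpopulations."""

    counts: np.ndarray
    cluster_ids: list
    subpop_ids: list
    matching: Optional[dict] = None          # cluster id -> subpop id
    percent_correct: Optional[float] = None  # rounded integer %CA
    percent_correct_exact: Optional[float] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.cluster_ids), len(self.subpop_ids)):
            raise ValueError("counts shape inconsistent with identifiers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cluster_ids, columns=self.subpop_ids)


def cross_tab(pred: Sequence, truth: Sequence) -> ConfusionTable:
    """Contingency counts of predicted cluster x true subpopulation."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape[0] != truth.shape[0]:
        raise ValueError("pred and truth must have equal length")
    if pred.shape[0] == 0:
        raise ValueError("empty input")
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain at least 2 distinct subpopulations")
    clusters = sorted(np.unique(pred).tolist())
    subpops = sorted(np.unique(truth).tolist())
    counts = np.zeros((len(clusters), len(subpops)), dtype=np.int64)
    ci = {c: i for i, c in enumerate(clusters)}
    gi = {g: i for i, g in enumerate(subpops)}
    for p, t in zip(pred, truth):
        counts[ci[p], gi[t]] += 1
    return ConfusionTable(counts, clusters, subpops)


def match_clusters(t: ConfusionTable) -> dict:
    """Injective cluster -> subpopulation map maximising the matched count.

    Solved as a linear assignment on the negated counts. If the
    identity-order mapping (cluster i -> subpopulation i) ties the optimum,
    it is preferred.
    """
    rows, cols = linear_sum_assignment(-t.counts)
    best_total = t.counts[rows, cols].sum()
    K, G = t.counts.shape
    if K <= G:
        ident = t.counts[np.arange(K), np.arange(K)].sum()
        if ident == best_total:
            rows, cols = np.arange(K), np.arange(K)
    matching = {t.cluster_ids[r]: t.subpop_ids[c] for r, c in zip(rows, cols)}
    t.matching = matching
    return matching


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def percent_correct(t: ConfusionTable) -> float:
    """%CA under the current (or freshly computed) matching, rounded half-up
    to an integer percent; the exact value is stored on the table."""
    if t.n == 0:
        raise ValueError("empty confusion table")
    if t.matching is None:
        match_clusters(t)
    gi = {g: i for i, g in enumerate(t.subpop_ids)}
    matched = sum(
        t.counts[t.cluster_ids.index(c), gi[g]] for c, g in t.matching.items()
    )
    t.percent_correct_exact = 100.0 * matched / t.n
    t.percent_correct = float(_round_half_up(t.percent_correct_exact))
    return t.percent_correct


def evaluate_assignment(pred: Sequence, truth: Sequence) -> ConfusionTable:
    """cross_tab + match_clusters + percent_correct in one call."""
    t = cross_tab(pred, truth)
    match_clusters(t)
    percent_correct(t)
    return t
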