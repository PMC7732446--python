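"""Two-dimensional views of the reduced data: t-SNE of the autoencoder
embedding and the first two principal components.

t-SNE is delegated to scikit-learn; the interface binds the parameter set
used throughout (perplexity 30, 1,000 iterations, learning rate 200) and
the output contract (finite n x 2 coordinates), not the internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["PlotFrame", "tsne_embed", "pca_scatter", "export_plot"]


@dataclass
class PlotFrame:
    """n x 2 coordinates with a label per point and axis names."""

    coordinates: np.ndarray
    labels: list
    axis_names: tuple = ("dim1", "dim2")

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be n x 2")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")
        if len(self.labels) != self.coordinates.shape[0]:
            raise ValueError("one label per point required")

    def to_frame(self, sample_ids: Optional[Sequence] = None):
        import pandas as pd

        idx = sample_ids if sample_ids is not None else range(len(self.labels))
        return pd.DataFrame(
            {self.axis_names[0]: self.coordinates[:, 0],
             self.axis_names[1]: self.coordinates[:, 1],
             "label": list(self.labels)}, index=idx,
        )


def tsne_embed(
    emb: np.ndarray,
    labels: Sequence,
    perplexity: float = 30.0,
    iterations: int = 1000,
    learning_rate: float = 200.0,
    seed: int = 0,
) -> PlotFrame:
    """2-D t-SNE of an embedding; requires perplexity < (n - 1) / 3."""
    from sklearn.manifold import TSNE

    emb = np.asarray(emb, dtype=np.float64)
    n = emb.shape[0]
    if n < 10:
        raise ValueError("t-SNE needs at least 10 samples")
    bound = (n - 1) / 3
    if perplexity >= bound:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}; need perplexity < {bound:.2f}"
        )
    ts = TSNE(
        n_components=2, perplexity=perplexity, max_iter=iterations,
        learning_rate=learning_rate, init="pca", random_state=seed,
    )
    coords = ts.fit_transform(emb)
    return PlotFrame(coords, list(labels), ("tsne1", "tsne2"))


def pca_scatter(emb: np.ndarray, labels: Sequence) -> PlotFrame:
    """First two columns of a PCA embedding as plot coordinates."""
    emb = np.asarray(emb, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[1] < 2:
        raise ValueError("need at least 2 principal components")
    return PlotFrame(emb[:, :2].copy(), list(labels), ("PC1", "PC2"))


def export_plot(frame: PlotFrame, path, format: str = "png") -> None:
    """Scatter the frame colored by label; writes PNG or SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if format not in ("png", "svg"):
        raise ValueError(f"unsupported format {format!r}; use png or svg")
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(frame.labels)
    for lab in dict.fromkeys(frame.labels):  # preserve first-appearance order
        sel = labels == lab
        ax.scatter(frame.coordinates[sel, 0], frame.coordinates[sel, 1],
                   s=18, label=str(lab))
    ax.set_xlabel(frame.axis_names[0])
    ax.set_ylabel(frame.axis_names[1])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, format=format, dpi=150)
    plt.close(fig)
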