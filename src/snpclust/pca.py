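"""PCA baseline for genotype dimensionality reduction.

Computed by SVD of the column-centered matrix. Component signs are fixed so
that each component's largest-magnitude loading is positive, making fits
bit-reproducible. The default input is the one-hot matrix (centered, not
scaled); label-encoded input works but imposes an artificial ordinality
A<T<G<C and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .encoding import EncodedMatrix, require_complete

__all__ = ["PCAModel", "pca_fit", "pca_transform"]


@dataclass
class PCAModel:
    """Fitted principal components.

    ``components`` has orthonormal rows (m x d); ``explained_variance`` is
    non-increasing, in the usual unbiased (n-1) normalisation.
    """

    column_means: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _as_array(data: Union[EncodedMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(data, EncodedMatrix):
        if data.scheme == "label":
            warnings.warn(
                "PCA on label-encoded data imposes an artificial ordinality "
                "A<T<G<C; one-hot input is recommended", stacklevel=3,
            )
        return require_complete(data)
    return np.asarray(data, dtype=np.float64)


def pca_fit(data: Union[EncodedMatrix, np.ndarray], n_components: int) -> PCAModel:
    """Fit PCA by SVD of the centered matrix, sign-fixed (see module doc)."""
    X = _as_array(data)
    n, d = X.shape
    max_comp = min(n - 1, d)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}] for shape {X.shape}")
    means = X.mean(axis=0)
    Xc = X - means
    if not Xc.any():
        raise ValueError("zero-variance data: all rows identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:n_components]
    # sign convention: largest-|loading| entry of each component is positive
    flip = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    var = (s[:n_components] ** 2) / (n - 1)
    return PCAModel(means, comps, var)


def pca_transform(model: PCAModel, data: Union[EncodedMatrix, np.ndarray]) -> np.ndarray:
    """Project ``data`` onto the fitted components; shape (n, m)."""
    X = _as_array(data)
    if X.shape[1] != model.components.shape[1]:
        raise ValueError(
            f"data width {X.shape[1]} != model width {model.components.shape[1]}"
        )
    return (X - model.column_means) @ model.components.T
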