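"""Numeric encodings of nucleotide calls.

Two schemes are supported, matching the two preprocessing baselines the
pipeline compares:

* one-hot — each call becomes a 4-vector in fixed channel order (A, T, G, C):
  A=[1,0,0,0], T=[0,1,0,0], G=[0,0,1,0], C=[0,0,0,1]. Missing calls encode as
  the all-zero block (only user data can contain these; the standard filter
  removes loci with any missing call).
* label — A:0, T:1, G:2, C:3; missing gets the reserved code -1, which
  downstream numeric stages must reject.

Channel order is (A, T, G, C), not alphabetical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, SNPMatrix

#: Fixed channel/label order.
CHANNELS = ("A", "T", "G", "C")
_CODE = {b: i for i, b in enumerate(CHANNELS)}
MISSING_CODE = -1


@dataclass
class EncodedMatrix:
    """Numeric design matrix with its encoding scheme.

    ``values`` is n x 4L for one-hot and n x L for label encoding;
    ``block_size`` is 4 or 1 accordingly. Column order is locus-major.
    """

    values: np.ndarray
    scheme: str  # "one_hot" | "label"
    locus_ids: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.scheme not in ("one_hot", "label"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != self.block_size * len(self.locus_ids):
            raise ValueError("column count inconsistent with locus_ids and scheme")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count inconsistent with sample_ids")

    @property
    def block_size(self) -> int:
        return 4 if self.scheme == "one_hot" else 1

    @property
    def column_names(self) -> list:
        if self.scheme == "one_hot":
            return [f"{lid}_{ch}" for lid in self.locus_ids for ch in CHANNELS]
        return list(self.locus_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_names)


def one_hot_encode(m: SNPMatrix) -> EncodedMatrix:
    """One-hot encode calls into an n x 4L float matrix (locus-major blocks)."""
    n, L = m.calls.shape
    out = np.zeros((n, 4 * L), dtype=np.float64)
    for ch, k in _CODE.items():
        rows, cols = np.nonzero(m.calls == ch)
        out[rows, 4 * cols + k] = 1.0
    return EncodedMatrix(out, "one_hot", list(m.locus_ids), list(m.sample_ids))


def label_encode(m: SNPMatrix) -> EncodedMatrix:
    """Label-encode calls into an n x L integer matrix (missing -> -1)."""
    codes = np.full(m.calls.shape, MISSING_CODE, dtype=np.int64)
    for ch, k in _CODE.items():
        codes[m.calls == ch] = k
    return EncodedMatrix(codes, "label", list(m.locus_ids), list(m.sample_ids))


def decode_one_hot(e: EncodedMatrix) -> SNPMatrix:
    """Argmax-decode 4-blocks back to nucleotides.

    Accepts indicator or probability blocks; the all-zero block decodes to
    missing; ties break toward the earlier channel in (A, T, G, C).
    """
    if e.scheme != "one_hot":
        raise ValueError("decode_one_hot requires a one_hot matrix")
    n, d = e.values.shape
    if d % 4:
        raise ValueError("one-hot width must be divisible by 4")
    blocks = e.values.reshape(n, d // 4, 4)
    best = np.argmax(blocks, axis=2)  # first-index tie-break = channel order
    calls = np.array(CHANNELS, dtype="<U1")[best]
    calls[blocks.sum(axis=2) == 0] = MISSING
    return SNPMatrix(list(e.sample_ids), list(e.locus_ids), calls)


def require_complete(e: EncodedMatrix) -> np.ndarray:
    """Return ``e.values`` as floats, rejecting missing-call codes.

    Clustering and validation stages operate on complete matrices only.
    """
    if e.scheme == "label" and (e.values == MISSING_CODE).any():
        raise ValueError("label-encoded matrix contains missing calls (-1)")
    return np.asarray(e.values, dtype=np.float64)
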