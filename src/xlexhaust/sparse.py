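"""Sparse non-negative spectrum vectors over integer m/z bins.

Both theoretical and experimental spectra occupy a tiny fraction of the m/z
bin range, so they are stored as parallel arrays of sorted unique bin indices
and intensities.  The dot product walks both index arrays with a single
two-pointer merge pass, so matching a theoretical spectrum with m occupied
bins against an experimental spectrum with h occupied bins costs O(m + h).
"""

from __future__ import annotations

import numpy as np


class SparseVector:
    """A sparse vector: sorted unique ``indices`` with parallel ``values``."""

    __slots__ = ("indices", "values")

    def __init__(self, indices: np.ndarray, values: np.ndarray):
        self.indices = np.asarray(indices, dtype=np.int64)
        self.values = np.asarray(values, dtype=np.float64)
        if self.indices.shape != self.values.shape:
            raise ValueError("indices and values must have equal length")

    def __len__(self) -> int:
        return len(self.indices)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        pairs = dict(zip(self.indices.tolist(), self.values.tolist()))
        return f"SparseVector({pairs})"


def from_bins(bin_indices, weights=None) -> SparseVector:
    """Build a SparseVector from (possibly repeated, unsorted) bin indices.

    Repeated bins have their weights summed; with ``weights=None`` each
    occurrence counts 1, so the value of a bin is its multiplicity.
    """
    idx = np.asarray(bin_indices, dtype=np.int64)
    if idx.size == 0:
        return SparseVector(np.empty(0, dtype=np.int64), np.empty(0))
    if weights is None:
        w = np.ones(idx.shape, dtype=np.float64)
    else:
        w = np.asarray(weights, dtype=np.float64)
    uniq, inverse = np.unique(idx, return_inverse=True)
    out = np.zeros(len(uniq), dtype=np.float64)
    np.add.at(out, inverse, w)
    return SparseVector(uniq, out)


def sparse_dot(a: SparseVector, b: SparseVector) -> float:
    """Dot product of two sparse vectors by a single two-pointer merge pass."""
    ia, va = a.indices, a.values
    ib, vb = b.indices, b.values
    na, nb = len(ia), len(ib)
    i = j = 0
    acc = 0.0
    while i < na and j < nb:
        da = ia[i]
        db = ib[j]
        if da == db:
            acc += va[i] * vb[j]
            i += 1
            j += 1
        elif da < db:
            i += 1
        else:
            j += 1
    return float(acc)


def sparse_add(a: SparseVector, b: SparseVector) -> SparseVector:
    """Element-wise sum of two sparse vectors."""
    idx = np.concatenate([a.indices, b.indices])
    val = np.concatenate([a.values, b.values])
    uniq, inverse = np.unique(idx, return_inverse=True)
    out = np.zeros(len(uniq), dtype=np.float64)
    np.add.at(out, inverse, val)
    return SparseVector(uniq, out)


def norm(a: SparseVector) -> float:
    """Euclidean norm."""
    return float(np.sqrt(np.dot(a.values, a.values)))


def scale(a: SparseVector, factor: float) -> SparseVector:
    return SparseVector(a.indices.copy(), a.values * factor)
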