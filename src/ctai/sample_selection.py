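"""Kennard–Stone calibration/test splitting.

The algorithm picks a representative, space-filling calibration set: it
seeds with the two most distant samples (Euclidean distance on the raw
absorbance spectra) and then repeatedly adds the sample whose minimum
distance to the already-selected set is largest.  Ties break toward the
lowest index so the split is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["SplitResult", "kennard_stone"]


@dataclass
class SplitResult:
    """Calibration indices in KS selection order plus their complement."""

    calibration_indices: np.ndarray
    test_indices: np.ndarray


def kennard_stone(X: np.ndarray, n_select: int) -> SplitResult:
    """Select ``n_select`` calibration samples by the Kennard–Stone rule."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select={n_select} outside [2, {n}]")

    D = squareform(pdist(X))
    # seed: the maximally distant pair, lowest indices on ties
    flat = np.argmax(D)
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    # min distance of every remaining sample to the selected set
    mindist = np.minimum(D[:, selected[0]], D[:, selected[1]])
    while len(selected) < n_select:
        cand = np.where(mask)[0]
        best = cand[np.argmax(mindist[cand])]  # argmax takes first on ties
        selected.append(int(best))
        mask[best] = False
        mindist = np.minimum(mindist, D[:, best])
    calibration = np.asarray(selected, dtype=int)
    test = np.setdiff1d(np.arange(n), calibration)
    return SplitResult(calibration_indices=calibration, test_indices=test)
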