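"""Column-wise norms used by the structured-sparsity penalties."""

from __future__ import annotations

import numpy as np


def column_norms(M: np.ndarray) -> np.ndarray:
    """l2 norm of each column of ``M`` (entry j = sqrt(sum_i M_ij^2))."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"expected a 2-d matrix, got ndim={M.ndim}")
    if not np.isfinite(M).all():
        raise ValueError("matrix contains non-finite entries")
    return np.sqrt((M * M).sum(axis=0))


def l21_norm(M: np.ndarray) -> float:
    """Column-wise l2,1 norm: the sum over columns of the column l2 norms.

    Penalizing this drives entire columns toward zero, which is what makes
    it a feature-selection (rather than entry-wise) sparsity penalty.
    """
    return float(column_norms(M).sum())
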