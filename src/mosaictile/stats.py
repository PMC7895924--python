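"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact"]


def fisher_exact(table) -> float:
    """Two-tailed Fisher's exact test p for a 2×2 contingency table.

    Uses the point-probability convention: the p value sums the hypergeometric
    probabilities (margins fixed) of every table at least as extreme as — i.e.
    with probability no greater than — the observed one. Degenerate tables
    (an empty row or column) are rejected.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: empty row or column")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)
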