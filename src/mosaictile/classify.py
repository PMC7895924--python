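"""Mosaic cell classification from reporter fluorescence.

Implements the intracellular pixel-fraction rule for calling lineage-traced
(EGFP+) cells on a rescaled [0, 1] channel: a cell is EGFP-positive when at
least 75% of its pixels exceed 0.08 and EGFP-negative when at least 75% fall
below 0.06. Cells meeting neither rule are left unclassified rather than
forced into a call. Neighbour relations come from dilated-mask overlap on the
label image, and cells are then partitioned into deleted (EGFP+), neighbour
(EGFP− touching ≥1 EGFP+ cell) and distant (EGFP− touching none).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "classify_egfp",
    "build_neighbour_graph",
    "assign_cell_classes",
    "EGFP_POS",
    "EGFP_NEG",
    "UNCLASSIFIED",
]

EGFP_POS = "EGFP_POS"
EGFP_NEG = "EGFP_NEG"
UNCLASSIFIED = "UNCLASSIFIED"


def classify_egfp(
    mask: np.ndarray,
    egfp: np.ndarray,
    hi: float = 0.08,
    lo: float = 0.06,
    frac: float = 0.75,
) -> pd.DataFrame:
    """Call each cell EGFP_POS / EGFP_NEG / UNCLASSIFIED.

    ``egfp`` must be rescaled to [0, 1] and share ``mask``'s shape. A cell is
    positive when >= ``frac`` of its pixels have intensity strictly above
    ``hi``; negative when >= ``frac`` are strictly below ``lo``. Intracellular
    pixels are all pixels of the label (no erosion). Returns columns
    (cell_id, call, frac_above_hi, frac_below_lo).
    """
    if mask.shape != egfp.shape:
        raise ValueError("mask and channel must share a shape")
    if egfp.min() < 0 or egfp.max() > 1:
        raise ValueError("channel must be rescaled to [0, 1]")
    labels = mask.ravel().astype(np.int64)
    vals = np.asarray(egfp, dtype=float).ravel()
    n = int(labels.max())
    if n == 0:
        raise ValueError("label image has no cells")
    counts = np.bincount(labels, minlength=n + 1)
    above = np.bincount(labels, weights=(vals > hi), minlength=n + 1)
    below = np.bincount(labels, weights=(vals < lo), minlength=n + 1)
    ids = np.flatnonzero(counts[1:]) + 1
    f_above = above[ids] / counts[ids]
    f_below = below[ids] / counts[ids]
    call = np.full(ids.shape, UNCLASSIFIED, dtype=object)
    call[f_above >= frac] = EGFP_POS
    call[(f_below >= frac) & (f_above < frac)] = EGFP_NEG
    return pd.DataFrame(
        {
            "cell_id": ids,
            "call": call,
            "frac_above_hi": f_above,
            "frac_below_lo": f_below,
        }
    )


def build_neighbour_graph(
    mask: np.ndarray, dilation_radius: int = 1, periodic: bool = False
) -> nx.Graph:
    """Neighbour graph by dilated-mask overlap.

    Two cells are neighbours when the mask of one overlaps the other's mask
    dilated ``dilation_radius`` times with a 3×3 square element — equivalently,
    when some pixel of one lies within Chebyshev distance ``dilation_radius``
    of a pixel of the other. Corner contacts count; background gaps narrower
    than the dilation are bridged. ``periodic`` wraps contacts across the
    image edges (toroidal masks).
    """
    if not (mask > 0).any():
        raise ValueError("label image has no cells")
    r = int(dilation_radius)
    g = nx.Graph()
    g.add_nodes_from(int(v) for v in np.unique(mask) if v > 0)
    pairs: set[tuple[int, int]] = set()
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di == 0 and dj == 0:
                continue
            if periodic:
                shifted = np.roll(mask, (di, dj), axis=(0, 1))
                a, b = mask, shifted
            else:
                h, w = mask.shape
                a = mask[max(di, 0) : h + min(di, 0), max(dj, 0) : w + min(dj, 0)]
                b = mask[max(-di, 0) : h + min(-di, 0), max(-dj, 0) : w + min(-dj, 0)]
            sel = (a > 0) & (b > 0) & (a != b)
            if sel.any():
                uv = np.unique(
                    np.stack([a[sel], b[sel]]).astype(np.int64), axis=1
                )
                pairs.update(
                    (int(min(x, y)), int(max(x, y))) for x, y in uv.T
                )
    g.add_edges_from(pairs)
    return g


def assign_cell_classes(graph: nx.Graph, calls: pd.DataFrame) -> pd.DataFrame:
    """Partition cells into deleted / neighbour / distant classes.

    EGFP_POS cells are ``deleted``; EGFP_NEG cells with at least one EGFP_POS
    graph neighbour are ``neighbour``; EGFP_NEG cells with none are
    ``distant``; UNCLASSIFIED cells stay ``unclassified`` (excluded from class
    counts downstream) but do not block classification of their neighbours.
    """
    call_map = dict(zip(calls["cell_id"].astype(int), calls["call"]))
    missing = [n for n in graph.nodes if n not in call_map]
    if missing:
        raise ValueError(f"graph nodes without an EGFP call: {sorted(missing)[:5]}")
    rows = []
    for node in sorted(graph.nodes):
        call = call_map[node]
        if call == EGFP_POS:
            cls = "deleted"
        elif call == UNCLASSIFIED:
            cls = "unclassified"
        elif any(call_map.get(nb) == EGFP_POS for nb in graph.neighbors(node)):
            cls = "neighbour"
        else:
            cls = "distant"
        rows.append({"cell_id": node, "cell_class": cls})
    return pd.DataFrame(rows)
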