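"""Cell-border intensity and apical cap/cortex pattern quantification.

Junctional stains (e.g. myosin heavy chain IIb) visualised on cell borders are
shared between adjacent cells, so intensity is read out per *border segment* —
the pixels of each cell whose dilated footprint overlaps the other, plus any
background pixels between them within the dilation radius. Segments are
grouped by the classes of their two cells (EGFP–neighbour, neighbour–neighbour,
distant–distant; every other pairing is OTHER and excluded from the three-way
comparison). Per-embryo normalisation to a reference class (reference = 100%)
makes staining comparable across embryos.

Within a cell, the stain either rings the junctional cortex or covers the
medio-apical cap: the cell mask is split into a cortical ring (cell minus an
erosion) and the cap (the erosion), and the cell is called CAP when the
cap/cortex mean-intensity ratio reaches a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import binary_dilation, binary_erosion

__all__ = [
    "BorderSegment",
    "CapCortexRecord",
    "extract_border_segments",
    "border_class_of",
    "border_intensity_summary",
    "cap_cortex_split",
    "pattern_proportions",
    "BORDER_CLASSES",
]

BORDER_CLASSES = ("EGFP_NEIGHBOUR", "NEIGHBOUR_NEIGHBOUR", "DISTANT_DISTANT", "OTHER")

_STRUCT = np.ones((3, 3), dtype=bool)


@dataclass
class BorderSegment:
    """Pixels attributed to one cell–cell border."""

    edge: tuple[int, int]
    pixels: np.ndarray  # (N, 2) row/col indices
    border_class: str = "OTHER"

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def extract_border_segments(
    mask: np.ndarray, graph: nx.Graph, radius: int = 1
) -> list[BorderSegment]:
    """One pixel set per graph edge.

    The segment of edge (a, b) contains the pixels of a within the dilation of
    b, the pixels of b within the dilation of a, and background pixels covered
    by both dilations. The graph must have been built from the same mask and
    radius; an edge with an empty overlap indicates an inconsistent graph.
    """
    from scipy.ndimage import find_objects

    objects = find_objects(mask)
    segments = []
    h, w = mask.shape
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        sl_a = objects[a - 1] if 0 < a <= len(objects) else None
        sl_b = objects[b - 1] if 0 < b <= len(objects) else None
        if sl_a is None or sl_b is None:
            raise ValueError(f"edge ({a}, {b}) references a label absent from the mask")
        r0 = max(min(sl_a[0].start, sl_b[0].start) - radius - 1, 0)
        r1 = min(max(sl_a[0].stop, sl_b[0].stop) + radius + 1, h)
        c0 = max(min(sl_a[1].start, sl_b[1].start) - radius - 1, 0)
        c1 = min(max(sl_a[1].stop, sl_b[1].stop) + radius + 1, w)
        win = mask[r0:r1, c0:c1]
        ma, mb = win == a, win == b
        da = binary_dilation(ma, _STRUCT, iterations=radius)
        db = binary_dilation(mb, _STRUCT, iterations=radius)
        seg = (ma & db) | (mb & da) | ((win == 0) & da & db)
        if not seg.any():
            raise ValueError(f"edge ({a}, {b}) has an empty border overlap")
        rr, cc = np.nonzero(seg)
        segments.append(BorderSegment(edge=(a, b), pixels=np.column_stack([rr + r0, cc + c0])))
    return segments


def border_class_of(edge: tuple[int, int], class_map: dict[int, str]) -> str:
    """Border class from the classes of the edge's two cells.

    deleted–neighbour → EGFP_NEIGHBOUR; neighbour–neighbour →
    NEIGHBOUR_NEIGHBOUR; distant–distant → DISTANT_DISTANT; any other pairing
    (including an unclassified endpoint) → OTHER.
    """
    a = class_map.get(edge[0], "unclassified")
    b = class_map.get(edge[1], "unclassified")
    pair = frozenset((a, b))
    if pair == frozenset(("deleted", "neighbour")):
        return "EGFP_NEIGHBOUR"
    if pair == frozenset(("neighbour",)):
        return "NEIGHBOUR_NEIGHBOUR"
    if pair == frozenset(("distant",)):
        return "DISTANT_DISTANT"
    return "OTHER"


def classify_segments(
    segments: list[BorderSegment], classes: pd.DataFrame
) -> list[BorderSegment]:
    """Assign each segment its border class (in place; returns the list)."""
    cmap = dict(zip(classes["cell_id"].astype(int), classes["cell_class"]))
    for seg in segments:
        seg.border_class = border_class_of(seg.edge, cmap)
    return segments


def segment_table(segments: list[BorderSegment], channel: np.ndarray) -> pd.DataFrame:
    """Tabulate segments with their mean channel intensity."""
    rows = []
    for seg in segments:
        vals = channel[seg.pixels[:, 0], seg.pixels[:, 1]]
        rows.append(
            {
                "id_a": seg.edge[0],
                "id_b": seg.edge[1],
                "border_class": seg.border_class,
                "n_pixels": seg.n_pixels,
                "mean_intensity": float(vals.mean()),
            }
        )
    return pd.DataFrame(rows)


def border_intensity_summary(
    segments: list[BorderSegment],
    channel: np.ndarray,
    embryo_id: int | str = 1,
    normalize_to: str | None = None,
) -> pd.DataFrame:
    """Mean border intensity per class for one embryo.

    With ``normalize_to`` set to a border class, all class means are rescaled
    so the reference class reads 100% (per-embryo normalisation); a missing
    reference class is an error.
    """
    table = segment_table(segments, channel)
    out = (
        table.groupby("border_class")["mean_intensity"]
        .agg(mean_intensity="mean", n_segments="count")
        .reset_index()
    )
    out.insert(0, "embryo_id", embryo_id)
    if normalize_to is not None:
        ref = out.loc[out["border_class"] == normalize_to, "mean_intensity"]
        if ref.empty or float(ref.iloc[0]) == 0:
            raise ValueError(f"reference class {normalize_to!r} absent or zero")
        out["intensity_pct"] = 100.0 * out["mean_intensity"] / float(ref.iloc[0])
    return out


@dataclass
class CapCortexRecord:
    """Cap/cortex decomposition of one cell's stain."""

    cell_id: int
    cap_mean: float
    cortex_mean: float
    n_cap_pixels: int
    n_cortex_pixels: int
    pattern: str | None  # "CAP" | "CORTICAL" | None when undefined
    flagged: bool


def cap_cortex_split(
    mask: np.ndarray,
    cell_id: int,
    channel: np.ndarray,
    erosion_r: int = 2,
    theta: float = 1.0,
) -> CapCortexRecord:
    """Split one cell into apical cap and cortical ring and classify its stain.

    The cap is the cell mask eroded ``erosion_r`` times (3×3 element); the
    cortex is the remaining ring. The two are a partition of the cell. Pattern
    is CAP when cap_mean / cortex_mean >= ``theta`` (uniform cells classify as
    CAP at the default theta = 1; boundary convention, configurable). A cell
    emptied by the erosion is flagged with an undefined pattern.
    """
    cell = mask == cell_id
    if not cell.any():
        raise ValueError(f"cell {cell_id} absent from mask")
    cap = binary_erosion(cell, _STRUCT, iterations=erosion_r)
    cortex = cell & ~cap
    if not cap.any() or not cortex.any():
        return CapCortexRecord(
            cell_id=cell_id,
            cap_mean=float("nan"),
            cortex_mean=float("nan"),
            n_cap_pixels=int(cap.sum()),
            n_cortex_pixels=int(cortex.sum()),
            pattern=None,
            flagged=True,
        )
    cap_mean = float(channel[cap].mean())
    cortex_mean = float(channel[cortex].mean())
    if cortex_mean == 0:
        pattern = "CAP" if cap_mean > 0 or theta <= 1 else "CORTICAL"
    else:
        ratio = cap_mean / cortex_mean
        # ulp tolerance so a uniform cell sits on the CAP side of theta = 1
        pattern = "CAP" if ratio >= theta or np.isclose(ratio, theta) else "CORTICAL"
    return CapCortexRecord(
        cell_id=cell_id,
        cap_mean=cap_mean,
        cortex_mean=cortex_mean,
        n_cap_pixels=int(cap.sum()),
        n_cortex_pixels=int(cortex.sum()),
        pattern=pattern,
        flagged=False,
    )


def pattern_proportions(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """CAP/CORTICAL proportions per cell class plus a chi-square comparison.

    ``records`` needs columns cell_class and pattern. Classes without records
    are excluded with a warning; at least two classes with records and both
    patterns overall are required for the test.
    """
    df = records.dropna(subset=["pattern"])
    counts = (
        df.groupby(["cell_class", "pattern"]).size().unstack(fill_value=0)
    )
    for col in ("CAP", "CORTICAL"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["CAP", "CORTICAL"]]
    if len(counts) < 2:
        raise ValueError("need >= 2 cell classes with records")
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"prop_{c.lower()}" for c in props.columns]
    table = counts.to_numpy()
    # drop an all-zero pattern column to keep expected counts positive
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        stat, p = 0.0, 1.0
    else:
        res = sps.chi2_contingency(table, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    out = counts.join(props).reset_index()
    return out, stat, p
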