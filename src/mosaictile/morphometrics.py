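"""Label-image post-processing and per-cell apical shape features.

Mirrors the standard post-segmentation workflow for apical surface images:
cells truncated by the field of view are removed by blanking a fixed-width
border strip, fluorescence channels are min–max rescaled to [0, 1], and each
retained cell gets area, perimeter, solidity, axis lengths and the orientation
of its apical long axis.

Axis convention: the image row axis is rostrocaudal (RC) and the column axis is
mediolateral (ML). Orientation is the acute angle between the apical long axis
and the RC axis, folded into [0, 90] degrees, so 90 means a mediolaterally
oriented cell. Images must be acquired or generated with RC along rows for
orientation statistics to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import regionprops_table

__all__ = [
    "exclude_border_cells",
    "rescale_unit_interval",
    "compute_cell_features",
    "orientation_histogram",
    "chi2_homogeneity",
    "OrientationHistogram",
]


def exclude_border_cells(
    img: np.ndarray, border_width: int = 30
) -> tuple[np.ndarray, list[int]]:
    """Blank a border strip and drop every cell it touches.

    Pixels within ``border_width`` of any image edge are set to background, and
    any label that lost at least one pixel is removed entirely (a truncated
    mask would bias area and perimeter). Returns the cleaned image and the
    sorted list of excluded ids. Idempotent at fixed ``border_width``.
    """
    h, w = img.shape
    if border_width < 0 or 2 * border_width >= min(h, w):
        raise ValueError("border strip must leave a non-empty interior")
    if border_width == 0:
        return img.copy(), []
    out = img.copy()
    interior = np.zeros_like(img, dtype=bool)
    interior[border_width : h - border_width, border_width : w - border_width] = True
    touched = np.unique(out[~interior])
    touched = touched[touched > 0]
    out[~interior] = 0
    out[np.isin(out, touched)] = 0
    return out, sorted(int(t) for t in touched)


def rescale_unit_interval(channel: np.ndarray) -> np.ndarray:
    """Linearly rescale an intensity image to span [0, 1].

    Raises on a constant image, for which intensity thresholding is undefined.
    """
    arr = np.asarray(channel, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("cannot rescale a constant image")
    return (arr - lo) / (hi - lo)


def compute_cell_features(img: np.ndarray, pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Per-cell shape features from the second central moments.

    One row per nonzero label with area (px²), perimeter (weighted contour
    length, px), solidity (area / convex-hull area), major/minor equivalent
    ellipse axes (px) and ``orientation_deg`` in [0, 90] (acute angle between
    the long axis and the row/RC axis). Cells whose moments are degenerate
    (single pixel or isotropic) carry ``orientation_deg = NaN`` and
    ``degenerate = True``.
    """
    if not (img > 0).any():
        raise ValueError("label image has no cells")
    props = regionprops_table(
        img,
        properties=(
            "label",
            "area",
            "perimeter",
            "solidity",
            "axis_major_length",
            "axis_minor_length",
            "orientation",
        ),
    )
    df = pd.DataFrame(props).rename(
        columns={
            "label": "cell_id",
            "area": "area_px2",
            "perimeter": "perimeter_px",
            "axis_major_length": "major_axis_px",
            "axis_minor_length": "minor_axis_px",
        }
    )
    # skimage orientation: angle between row axis and major axis in (-pi/2, pi/2]
    orient = np.abs(np.degrees(df.pop("orientation")))
    degenerate = (df["area_px2"] <= 1) | np.isclose(
        df["major_axis_px"], df["minor_axis_px"]
    )
    orient[degenerate] = np.nan
    df["orientation_deg"] = orient
    df["degenerate"] = degenerate
    df["pixel_size_um"] = pixel_size_um
    return df


@dataclass
class OrientationHistogram:
    """Binned apical long-axis orientations for one cell group."""

    bin_edges: np.ndarray
    counts: np.ndarray
    median_deg: float
    group: str = ""


def orientation_histogram(
    records: pd.DataFrame, bin_width_deg: float = 10.0, group: str = ""
) -> OrientationHistogram:
    """Histogram of orientations over [0, 90] with the sample median.

    Only oriented (non-degenerate) cells contribute. The median of an
    even-count sample is the midpoint of the central pair.
    """
    vals = records["orientation_deg"].dropna().to_numpy()
    if vals.size == 0:
        raise ValueError("no oriented cells")
    edges = np.arange(0.0, 90.0 + bin_width_deg / 2, bin_width_deg)
    if edges[-1] < 90.0:
        edges = np.append(edges, 90.0)
    counts, edges = np.histogram(vals, bins=edges)
    return OrientationHistogram(
        bin_edges=edges, counts=counts, median_deg=float(np.median(vals)), group=group
    )


def chi2_homogeneity(
    hist_a: OrientationHistogram, hist_b: OrientationHistogram, yates: bool = True
) -> tuple[float, float]:
    """Two-sample chi-square test of homogeneity over shared bins.

    Yates continuity correction is applied only when the contingency table is
    2×2 (the only case it is defined for). Bins empty in both samples carry no
    information and are dropped; if fewer than two informative bins remain, or
    an expected count is still zero, the test is undefined and a coarser
    binning is advised.
    """
    if not np.array_equal(hist_a.bin_edges, hist_b.bin_edges):
        raise ValueError("histograms must share bin edges")
    table = np.vstack([hist_a.counts, hist_b.counts])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than two informative bins; merge bins before testing")
    expected = sps.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValueError("zero expected count; merge bins before testing")
    correction = yates and table.shape == (2, 2)
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
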