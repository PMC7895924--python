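"""Lewis' law and non-autonomous amplification statistics.

In an epithelium the apical area of a cell correlates linearly with its number
of neighbours (Lewis' law) and the average cell has six apical neighbours. When
a fraction p of cells carries a mosaic deletion, each deleted cell contacts
several replete neighbours, amplifying a non-autonomous effect — but deleted
cells share neighbours, so the number of *unique* replete neighbours per
deleted cell falls as p rises. This module measures those quantities on
observed graphs and provides the closed-form lattice model used to validate
them:

    f(p) = 1 - sum_k q_k (1 - p)^k     (replete cell touches >= 1 deleted)
    u(p) = (1 - p) f(p) / p            (unique replete neighbours per deleted)

with q_k the neighbour-number distribution (degree-k-regular: q_k = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LewisFit",
    "AmplificationSummary",
    "lewis_law_fit",
    "neighbour_count_summary",
    "fraction_replete_neighbouring",
    "unique_neighbours_per_deleted",
    "analytic_neighbour_model",
    "pearson_correlate",
]


@dataclass
class LewisFit:
    """OLS fit of apical area against neighbour number."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_cells: int


def lewis_law_fit(
    features: pd.DataFrame,
    graph: nx.Graph,
    classes: pd.DataFrame | None = None,
    subset: str | None = None,
) -> LewisFit:
    """Regress apical area on neighbour number (Lewis' law).

    ``features`` needs columns cell_id and area_px2; degrees come from
    ``graph``. ``subset`` optionally restricts to one cell class (requires
    ``classes``). Raises with fewer than three cells or zero degree variance.
    """
    df = features[["cell_id", "area_px2"]].copy()
    if subset is not None:
        if classes is None:
            raise ValueError("subset filtering requires a classes table")
        keep = classes.loc[classes["cell_class"] == subset, "cell_id"]
        df = df[df["cell_id"].isin(keep)]
    df = df[df["cell_id"].isin(graph.nodes)]
    if len(df) < 3:
        raise ValueError("need >= 3 cells for a Lewis fit")
    deg = np.array([graph.degree(c) for c in df["cell_id"]], dtype=float)
    if np.var(deg) == 0:
        raise ValueError("degree variance is zero; fit undefined")
    area = df["area_px2"].to_numpy(dtype=float)
    res = sps.linregress(deg, area)
    return LewisFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_cells=len(df),
    )


@dataclass
class AmplificationSummary:
    """Deleted-cell-centric neighbour statistics for one image or embryo."""

    p_hat: float
    mean_total_neighbours_of_deleted: float
    mean_replete_neighbours_of_deleted: float
    fraction_replete_neighbouring: float
    unique_neighbours_per_deleted: float
    n_deleted: int
    n_replete: int


def _class_map(classes: pd.DataFrame) -> dict[int, str]:
    return dict(zip(classes["cell_id"].astype(int), classes["cell_class"]))


def neighbour_count_summary(graph: nx.Graph, classes: pd.DataFrame) -> AmplificationSummary:
    """All amplification statistics for one classified neighbour graph.

    Unclassified cells are excluded from every count and denominator but do
    not block edges between classified cells. Deleted-centric means are NaN
    (not an error) when no deleted cell exists, matching mosaic-free images.
    """
    cmap = _class_map(classes)
    deleted = [c for c, k in cmap.items() if k == "deleted"]
    neighbour = [c for c, k in cmap.items() if k == "neighbour"]
    distant = [c for c, k in cmap.items() if k == "distant"]
    n_replete = len(neighbour) + len(distant)
    n_classified = len(deleted) + n_replete
    p_hat = len(deleted) / n_classified if n_classified else float("nan")

    if deleted:
        totals = []
        repletes = []
        for c in deleted:
            nbrs = [n for n in graph.neighbors(c) if cmap.get(n, "unclassified") != "unclassified"]
            totals.append(len(nbrs))
            repletes.append(sum(1 for n in nbrs if cmap[n] != "deleted"))
        mean_total = float(np.mean(totals))
        mean_replete = float(np.mean(repletes))
        unique = len(neighbour) / len(deleted)
    else:
        mean_total = mean_replete = unique = float("nan")

    frac = len(neighbour) / n_replete if n_replete else float("nan")
    return AmplificationSummary(
        p_hat=p_hat,
        mean_total_neighbours_of_deleted=mean_total,
        mean_replete_neighbours_of_deleted=mean_replete,
        fraction_replete_neighbouring=frac,
        unique_neighbours_per_deleted=unique,
        n_deleted=len(deleted),
        n_replete=n_replete,
    )


def fraction_replete_neighbouring(classes: pd.DataFrame) -> float:
    """Fraction of EGFP-negative cells touching at least one EGFP+ cell."""
    counts = classes["cell_class"].value_counts()
    n_nbr = int(counts.get("neighbour", 0))
    n_dist = int(counts.get("distant", 0))
    if n_nbr + n_dist == 0:
        raise ValueError("no EGFP-negative cells")
    return n_nbr / (n_nbr + n_dist)


def unique_neighbours_per_deleted(graph: nx.Graph, classes: pd.DataFrame) -> float:
    """Distinct replete cells touching >= 1 deleted cell, per deleted cell.

    Equals |neighbour-class| / |deleted|: each replete neighbour counts once
    no matter how many deleted cells it touches.
    """
    counts = classes["cell_class"].value_counts()
    n_del = int(counts.get("deleted", 0))
    if n_del == 0:
        raise ValueError("no deleted cells")
    return int(counts.get("neighbour", 0)) / n_del


def analytic_neighbour_model(
    p: float | np.ndarray, k: int = 6, degree_distribution: dict[int, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form neighbour fraction f(p) and unique-neighbour ratio u(p).

    Under independent Bernoulli(p) labels, a replete cell with k neighbours
    escapes contact with probability (1-p)^k, so f(p) = 1 - sum_k q_k (1-p)^k.
    On a k-regular mosaic the expected number of neighbour-class cells is
    n (1-p) f(p) and of deleted cells n p, giving u(p) = (1-p) f(p) / p, with
    limits u(0+) = k and u(1) = 0. The degree-distribution form of f is exact
    under label independence; u uses the regular-lattice approximation.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if (p_arr < 0).any() or (p_arr > 1).any():
        raise ValueError("p must lie in [0, 1]")
    if degree_distribution is None:
        degree_distribution = {k: 1.0}
    q = 1.0 - p_arr
    f = 1.0 - sum(w * q**kk for kk, w in degree_distribution.items())
    mean_k = sum(kk * w for kk, w in degree_distribution.items())
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(p_arr > 0, q * f / np.where(p_arr > 0, p_arr, 1.0), mean_k)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(f[0]), float(u[0])
    return f, u


def pearson_correlate(
    table: pd.DataFrame, x_column: str, y_column: str
) -> tuple[float, float, int]:
    """Pearson r with its two-tailed p (t transform) between two columns."""
    x = table[x_column].to_numpy(dtype=float)
    y = table[y_column].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant column; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)
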