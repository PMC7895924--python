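"""Apical constriction kinetics and ablation retraction statistics.

Live-imaged neuroepithelial cells pulse asynchronously, so raw time series
cannot be averaged directly. Each cell's trace is aligned at T = 0 when it
reaches its largest observed apical area and expressed as a percentage of that
maximum: negative aligned times are the dilation phase, positive times the
constriction phase. Group comparisons aggregate cells to embryo means per
aligned timepoint and apply two-sample t-tests with Bonferroni correction
across timepoints — a conservative stand-in for a mixed model that keeps the
embryo as the unit of measure.

Ablation retraction (% area change immediately after annular laser ablation, a
proxy for pre-existing apical tension) is likewise averaged per embryo and
cell type before any test, so pseudo-replication across cells of one embryo
cannot inflate significance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "align_at_max",
    "align_traces",
    "group_mean_trace",
    "compare_groups_per_timepoint",
    "retraction_percent",
    "embryo_level_average",
    "sample_size_two_group",
]


def align_at_max(times: np.ndarray, areas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Align one trace at its maximum area.

    Returns (aligned_times, normalized_areas) where T = 0 at the first
    occurrence of the maximum and areas are percentages of that maximum (100
    at T = 0). The multiset of areas is preserved up to the common scale.
    """
    times = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(times) < 3:
        raise ValueError("need >= 3 timepoints")
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    peak = int(np.argmax(areas))  # ties -> earliest
    # divide before scaling so no normalized value can exceed 100 by rounding
    return times - times[peak], areas / areas[peak] * 100.0


def align_traces(
    traces: pd.DataFrame,
    time_col: str = "t_min",
    area_col: str = "area_px2",
    min_side: int = 5,
) -> pd.DataFrame:
    """Align every cell's trace at its maximum (long-format in and out).

    Adds ``aligned_t`` and ``area_pct`` columns; ``short_side`` flags cells
    with fewer than ``min_side`` timepoints on either side of the peak (kept,
    not dropped — the imaging window with a free peak time implies asymmetric
    coverage).
    """
    out = []
    for cid, sub in traces.groupby("cell_id", sort=False):
        sub = sub.sort_values(time_col)
        at, pct = align_at_max(sub[time_col].to_numpy(), sub[area_col].to_numpy())
        sub = sub.assign(
            aligned_t=at,
            area_pct=pct,
            short_side=(at < 0).sum() < min_side or (at > 0).sum() < min_side,
        )
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def group_mean_trace(aligned: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-aligned-timepoint mean ± SEM for one group.

    Timepoints represented by a single cell are flagged (``single_cell``);
    their SEM is NaN.
    """
    sub = aligned[aligned["group"] == group]
    if sub.empty:
        raise ValueError(f"no cells in group {group!r}")
    g = sub.groupby("aligned_t")["area_pct"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out["single_cell"] = out["n"] < 2
    out["group"] = group
    return out.drop(columns="sd")


def _ttest_embryo_means(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with warnings.catch_warnings():
        # near-identical embryo means (e.g. at the alignment origin) trip
        # scipy's catastrophic-cancellation warning; the p value is still valid
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(sps.ttest_ind(a, b).pvalue)


def compare_groups_per_timepoint(
    aligned: pd.DataFrame, group_a: str, group_b: str, min_cell_fraction: float = 0.5
) -> pd.DataFrame:
    """Embryo-level two-sample t-tests per aligned timepoint, Bonferroni-adjusted.

    At each aligned timepoint, cells are aggregated to embryo means; the
    timepoint is tested only when both groups contribute >= 2 embryos and at
    least ``min_cell_fraction`` of each group's cells. The cell-coverage floor
    matters because the extremes of the aligned window are populated by a
    biased subsample (only early- or late-peaking cells), where group
    comparisons conflate the biological effect with peak-time selection. Raw p
    values are multiplied by the number of tested timepoints (capped at 1).
    """
    frames = {}
    cell_counts = {}
    group_sizes = {}
    for grp in (group_a, group_b):
        sub = aligned[aligned["group"] == grp]
        if sub["embryo_id"].nunique() < 2:
            raise ValueError(f"group {grp!r} needs >= 2 embryos")
        frames[grp] = sub.groupby(["aligned_t", "embryo_id"])["area_pct"].mean()
        cell_counts[grp] = sub.groupby("aligned_t")["cell_id"].nunique()
        group_sizes[grp] = sub["cell_id"].nunique()

    rows = []
    times = sorted(
        set(frames[group_a].index.get_level_values(0))
        & set(frames[group_b].index.get_level_values(0))
    )
    for t in times:
        if any(
            cell_counts[g].get(t, 0) < min_cell_fraction * group_sizes[g]
            for g in (group_a, group_b)
        ):
            continue
        a = frames[group_a].loc[t].to_numpy()
        b = frames[group_b].loc[t].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        rows.append(
            {
                "aligned_t": t,
                "p_raw": _ttest_embryo_means(a, b),
                "n_embryos_a": len(a),
                "n_embryos_b": len(b),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
            }
        )
    if not rows:
        raise ValueError("no aligned timepoint has >= 2 embryos in both groups")
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


def retraction_percent(
    pre_area: float | np.ndarray, post_area: float | np.ndarray
) -> float | np.ndarray:
    """Percent apical-area change after ablation (negative = retraction).

    Scale-invariant: areas in px² or µm² give identical percentages.
    """
    pre = np.asarray(pre_area, dtype=float)
    if (pre <= 0).any() if pre.ndim else pre <= 0:
        raise ValueError("pre-ablation area must be positive")
    out = 100.0 * (np.asarray(post_area, dtype=float) - pre) / pre
    return float(out) if out.ndim == 0 else out


def embryo_level_average(records: pd.DataFrame) -> pd.DataFrame:
    """Average retraction per embryo × cell type (embryo = unit of measure).

    ``records`` needs columns embryo_id, cell_type, pre_area, post_area.
    Downstream tests must consume these means, never raw cells.
    """
    df = records.copy()
    df["retraction_pct"] = retraction_percent(
        df["pre_area"].to_numpy(), df["post_area"].to_numpy()
    )
    return (
        df.groupby(["embryo_id", "cell_type"])["retraction_pct"]
        .mean()
        .reset_index()
    )


def _two_sample_t_power(n: int, delta: float, sd: float, alpha: float) -> float:
    df = 2 * n - 2
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    ncp = delta / (sd * np.sqrt(2.0 / n))
    return float(1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_two_group(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Smallest per-group n for a two-sample t-test to reach the target power.

    Starts from the normal approximation n ≈ 2 (z_{1-α/2} + z_{1-β})² (sd/δ)²
    and refines with the noncentral-t power function. Minimum n is 2 (a
    t-test needs at least one degree of freedom per group).
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    za = sps.norm.ppf(1 - alpha / 2)
    zb = sps.norm.ppf(power)
    n = max(2, int(np.ceil(2 * (za + zb) ** 2 * (sd / delta) ** 2)))
    while n > 2 and _two_sample_t_power(n - 1, delta, sd, alpha) >= power:
        n -= 1
    while _two_sample_t_power(n, delta, sd, alpha) < power:
        n += 1
        if n > 10_000_000:
            raise ValueError("target power unattainable at any feasible n")
    return n
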