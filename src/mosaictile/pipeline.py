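"""End-to-end orchestration: simulate → classify → neighbours → kinetics → borders.

A :class:`PipelineConfig` (JSON-serialisable) names the stages to run and
their parameters; :func:`run_pipeline` executes them in dependency order on a
synthetic epithelium, writing per-stage CSV/TIFF outputs, a ``metrics.json``
with the headline quantities (mean neighbour degree, classification confusion,
amplification summary, Lewis fit, kinetics and border summaries) and a run log
carrying the seed and parameters. Identical config + seed give byte-identical
metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import borders as bd
from . import classify as cf
from . import kinetics as kn
from . import morphometrics as mm
from . import neighbours as nb
from . import synthetic as syn

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

log = logging.getLogger("mosaictile")


@dataclasses.dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full synthetic run."""

    seed: int = 0
    n_cells: int = 400
    domain_size: tuple[int, int] = (400, 400)
    periodic: bool = True
    lattice_mode: str = "voronoi"
    lloyd_iterations: int = 2
    p: float = 0.16
    border_width: int = 0  # periodic synthetic images have no boundary
    hi: float = 0.08
    lo: float = 0.06
    frac: float = 0.75
    dilation_radius: int = 1
    noise_sd: float = 0.0
    psf_sigma: float = 0.0
    run_kinetics: bool = True
    run_borders: bool = True
    n_trace_cells_per_class: int = 12
    n_trace_embryos: int = 3

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "domain_size" in data:
            data["domain_size"] = tuple(data["domain_size"])
        return cls(**data)


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> dict:
    """Run all enabled stages and return (and write) the metrics dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    metrics: dict = {"seed": config.seed, "parameters": dataclasses.asdict(config)}

    # --- simulate -----------------------------------------------------------
    log.info("simulating tessellation (%d cells)", config.n_cells)
    tess = syn.generate_tessellation(
        syn.TessellationSpec(
            n_cells=config.n_cells,
            domain_size=config.domain_size,
            periodic=config.periodic,
            lattice_mode=config.lattice_mode,
            lloyd_iterations=config.lloyd_iterations,
            seed=seeds[0],
        )
    )
    labels, truth = syn.rasterize_labels(tess)
    mosaic = syn.assign_mosaic(tess, config.p, seed=seeds[1])
    render = syn.render_channels(
        labels,
        mosaic,
        syn.RenderSpec(noise_sd=config.noise_sd, psf_sigma=config.psf_sigma, seed=seeds[2]),
        periodic=config.periodic,
    )
    tifffile.imwrite(out / "labels.tif", labels)
    tifffile.imwrite(out / "channels.tif", render)
    truth_classes = syn.true_cell_classes(tess, mosaic)
    truth.merge(truth_classes, on="cell_id").to_csv(out / "truth.csv", index=False)

    # --- features + classification -----------------------------------------
    mask, excluded = mm.exclude_border_cells(labels, config.border_width)
    features = mm.compute_cell_features(mask)
    features.to_csv(out / "features.csv", index=False)
    calls = cf.classify_egfp(mask, render[1], hi=config.hi, lo=config.lo, frac=config.frac)
    graph = cf.build_neighbour_graph(
        mask, dilation_radius=config.dilation_radius, periodic=config.periodic
    )
    classes = cf.assign_cell_classes(graph, calls)
    calls.to_csv(out / "egfp_calls.csv", index=False)
    classes.to_csv(out / "cell_classes.csv", index=False)
    pd.DataFrame(sorted(graph.edges), columns=["id_a", "id_b"]).to_csv(
        out / "edges.csv", index=False
    )

    retained = truth_classes[~truth_classes["cell_id"].isin(excluded)]
    merged = retained.merge(calls, on="cell_id")
    confusion = int(
        (
            merged["recombined"] != (merged["call"] == cf.EGFP_POS)
        ).sum()
    )
    degrees = [d for _, d in graph.degree]
    metrics["n_cells_retained"] = int(len(calls))
    metrics["n_border_excluded"] = len(excluded)
    metrics["mean_degree"] = float(np.mean(degrees))
    metrics["classification_confusion"] = confusion

    # --- neighbour amplification -------------------------------------------
    summary = nb.neighbour_count_summary(graph, classes)
    metrics["amplification"] = dataclasses.asdict(summary)
    try:
        fit = nb.lewis_law_fit(features, graph)
        metrics["lewis_fit"] = dataclasses.asdict(fit)
    except ValueError as exc:
        log.warning("Lewis fit skipped: %s", exc)
        metrics["lewis_fit"] = None

    # --- kinetics ------------------------------------------------------------
    if config.run_kinetics:
        cells = []
        k = 0
        for cls in syn.CELL_CLASSES:
            for i in range(config.n_trace_cells_per_class):
                cells.append(
                    {
                        "cell_id": k + 1,
                        "embryo_id": i % config.n_trace_embryos + 1,
                        "cell_class": cls,
                    }
                )
                k += 1
        traces = syn.simulate_area_traces(
            pd.DataFrame(cells), syn.DynamicsSpec(seed=seeds[3])
        )
        traces.to_csv(out / "traces.csv", index=False)
        aligned = kn.align_traces(traces)
        metrics["kinetics"] = {
            grp: {
                "n_cells": int(aligned.loc[aligned["group"] == grp, "cell_id"].nunique()),
                "max_pct": float(
                    kn.group_mean_trace(aligned, grp)["mean"].max()
                ),
            }
            for grp in syn.CELL_CLASSES
        }
        aligned.to_csv(out / "aligned_traces.csv", index=False)

    # --- borders --------------------------------------------------------------
    if config.run_borders:
        # border statistics are defined on bounded masks; analyse the mask with
        # a non-periodic graph restricted to interior contacts
        seg_graph = cf.build_neighbour_graph(
            mask, dilation_radius=config.dilation_radius, periodic=False
        )
        segments = bd.classify_segments(
            bd.extract_border_segments(mask, seg_graph, radius=config.dilation_radius),
            classes,
        )
        seg_summary = bd.border_intensity_summary(segments, render[0])
        seg_summary.to_csv(out / "border_summary.csv", index=False)
        metrics["borders"] = {
            row["border_class"]: row["mean_intensity"]
            for _, row in seg_summary.iterrows()
        }

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    (out / "run_log.txt").write_text(
        f"seed={config.seed}\nchild_seeds={seeds}\n"
        + json.dumps(dataclasses.asdict(config), indent=2)
        + "\n"
    )
    log.info("pipeline complete: %s", out / "metrics.json")
    return metrics


def write_report(metrics: dict) -> str:
    """Human-readable tabulation of a metrics dict."""
    if not metrics:
        raise ValueError("empty metrics")
    lines = ["mosaictile run report", "=" * 40]
    lines.append(f"seed: {metrics.get('seed')}")
    lines.append(f"cells retained: {metrics.get('n_cells_retained')}")
    lines.append(f"mean neighbour degree: {metrics.get('mean_degree'):.3f}")
    lines.append(f"classification confusion: {metrics.get('classification_confusion')}")
    amp = metrics.get("amplification")
    if amp:
        lines.append("amplification summary:")
        for key, val in amp.items():
            lines.append(f"  {key}: {val:.4g}" if isinstance(val, float) else f"  {key}: {val}")
    fit = metrics.get("lewis_fit")
    if fit:
        lines.append(
            "Lewis fit: slope={slope:.3f} px2/neighbour, r={pearson_r:.3f}, "
            "p={p_value:.3g}, n={n_cells}".format(**fit)
        )
    if "kinetics" in metrics:
        lines.append("kinetics groups: " + ", ".join(
            f"{g} (n={v['n_cells']})" for g, v in metrics["kinetics"].items()
        ))
    if "borders" in metrics:
        lines.append("border classes: " + ", ".join(
            f"{k}={v:.3f}" for k, v in metrics["borders"].items()
        ))
    return "\n".join(lines) + "\n"
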