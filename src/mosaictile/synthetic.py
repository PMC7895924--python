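"""Synthetic epithelium generator.

Produces ground-truthed apical tessellations, fluorescence renders, apical-area
time series, ablation cohorts and embryo cohorts with the statistical structure
the downstream analysis assumes:

* a near-trivalent apical tessellation (mean six neighbours per cell on a
  periodic domain, by Euler's formula);
* Bernoulli mosaic labelling of "recombined" (gene-deleted) cells at fraction p;
* membrane-localised two-channel fluorescence (a ubiquitous membrane reporter
  plus a membrane reporter restricted to recombined cells), with an optional
  myosin-like channel carrying border-class and cap/cortex patterns;
* class-dependent pulsatile apical-area dynamics (deleted cells dilate faster
  but constrict normally; replete neighbours of deleted cells dilate normally
  but fail to constrict; distant/control cells do both normally);
* class-dependent post-ablation retraction with embryo-level random effects;
* embryo cohorts in which neural-fold eversion tracks the fraction of
  neighbour-class cells.

All randomness flows from a single integer seed per spec object; child streams
are spawned deterministically via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from skimage.filters import gaussian

__all__ = [
    "TessellationSpec",
    "Tessellation",
    "MosaicAssignment",
    "RenderSpec",
    "DynamicsSpec",
    "AblationSpec",
    "CohortSpec",
    "generate_tessellation",
    "rasterize_labels",
    "assign_mosaic",
    "render_channels",
    "simulate_area_traces",
    "simulate_ablation_cohort",
    "simulate_embryo_cohort",
    "CELL_CLASSES",
]

#: canonical cell-class labels used across the package
CELL_CLASSES = ("control", "deleted", "neighbour", "distant")


class ConfigurationError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TessellationSpec:
    """Parameters of the apical tessellation.

    ``domain_size`` is (width, height) in pixels; ``periodic`` makes the domain
    toroidal (no boundary, exact mean degree 6 for trivalent tessellations).
    ``lattice_mode`` is ``"voronoi"`` (Lloyd-relaxed random points) or
    ``"hexagonal"`` (regular offset lattice; requires ``n_cells`` to factor
    into an integer grid with an even number of rows when periodic).
    """

    n_cells: int
    domain_size: tuple[int, int] = (512, 512)
    periodic: bool = True
    lloyd_iterations: int = 2
    lattice_mode: str = "voronoi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ConfigurationError("n_cells must be >= 3")
        if min(self.domain_size) < 32:
            raise ConfigurationError("domain_size components must be >= 32 px")
        if self.lloyd_iterations < 0:
            raise ConfigurationError("lloyd_iterations must be >= 0")
        if self.lattice_mode not in ("voronoi", "hexagonal"):
            raise ConfigurationError(f"unknown lattice_mode {self.lattice_mode!r}")


@dataclass
class Tessellation:
    """A realised apical tessellation with ground truth.

    ``points`` are the Voronoi generators (x, y in px); polygons are vertex
    arrays ordered counter-clockwise; ``adjacency`` maps 1-based cell id to the
    set of neighbouring cell ids. On a periodic trivalent tessellation the mean
    degree is exactly 6.
    """

    points: np.ndarray
    polygons: list[np.ndarray]
    centroids: np.ndarray
    adjacency: dict[int, set[int]]
    areas: np.ndarray
    degrees: np.ndarray
    domain_size: tuple[int, int]
    periodic: bool

    @property
    def n_cells(self) -> int:
        return len(self.points)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "true_area_px2": self.areas,
                "true_degree": self.degrees,
            }
        )


def _pad_points(points: np.ndarray, domain: tuple[int, int], periodic: bool) -> np.ndarray:
    """Surround ``points`` with copies so every central Voronoi region is finite.

    Periodic domains get 8 translated copies (torus unrolled); bounded domains
    get mirror images across each edge and corner, which clips boundary cells
    exactly at the domain rectangle.
    """
    w, h = float(domain[0]), float(domain[1])
    copies = [points]
    if periodic:
        for dx in (-w, 0.0, w):
            for dy in (-h, 0.0, h):
                if dx == 0.0 and dy == 0.0:
                    continue
                copies.append(points + [dx, dy])
    else:
        x, y = points[:, 0], points[:, 1]
        mirrors = [
            np.column_stack([-x, y]),
            np.column_stack([2 * w - x, y]),
            np.column_stack([x, -y]),
            np.column_stack([x, 2 * h - y]),
            np.column_stack([-x, -y]),
            np.column_stack([-x, 2 * h - y]),
            np.column_stack([2 * w - x, -y]),
            np.column_stack([2 * w - x, 2 * h - y]),
        ]
        copies.extend(mirrors)
    return np.vstack(copies)


def _voronoi_geometry(
    points: np.ndarray, domain: tuple[int, int], periodic: bool
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, dict[int, set[int]]]:
    """Polygons, centroids, areas and adjacency of the (padded) Voronoi diagram."""
    n = len(points)
    padded = _pad_points(points, domain, periodic)
    vor = Voronoi(padded)

    polygons: list[np.ndarray] = []
    centroids = np.empty((n, 2))
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - padding guarantees finite
            raise RuntimeError("unbounded Voronoi region despite padding")
        verts = vor.vertices[region]
        # order counter-clockwise around the generator
        ang = np.arctan2(verts[:, 1] - points[i, 1], verts[:, 0] - points[i, 0])
        verts = verts[np.argsort(ang)]
        polygons.append(verts)
        x, y = verts[:, 0], verts[:, 1]
        cross = x * np.roll(y, -1) - np.roll(x, -1) * y
        area = 0.5 * np.abs(cross.sum())
        areas[i] = area
        cx = np.abs(np.sum((x + np.roll(x, -1)) * cross)) / (6 * area)
        cy = np.abs(np.sum((y + np.roll(y, -1)) * cross)) / (6 * area)
        # signed centroid formula; use signed version for correctness
        s = cross.sum() / 2.0
        centroids[i] = [
            np.sum((x + np.roll(x, -1)) * cross) / (6 * s),
            np.sum((y + np.roll(y, -1)) * cross) / (6 * s),
        ]
        del cx, cy

    adjacency: dict[int, set[int]] = {i + 1: set() for i in range(n)}
    for p, q in vor.ridge_points:
        if periodic:
            if p >= n and q >= n:
                continue
            a, b = int(p % n), int(q % n)
        else:
            if p >= n or q >= n:
                continue
            a, b = int(p), int(q)
        if a != b:
            adjacency[a + 1].add(b + 1)
            adjacency[b + 1].add(a + 1)
    return polygons, centroids, areas, adjacency


def _hex_grid(spec: TessellationSpec) -> np.ndarray:
    """Offset-row lattice points whose Voronoi diagram is a hexagonal tiling."""
    w, h = spec.domain_size
    target = w / h * np.sqrt(3) / 2  # nx/ny giving near-regular hexagons
    best = None
    for ny in range(2, spec.n_cells + 1, 2):
        if spec.n_cells % ny:
            continue
        nx = spec.n_cells // ny
        score = abs(np.log((nx / ny) / target))
        if best is None or score < best[0]:
            best = (score, nx, ny)
    if spec.periodic and best is None:
        raise ConfigurationError(
            f"n_cells={spec.n_cells} cannot tile a periodic hexagonal domain "
            "(needs a factorisation with an even number of rows)"
        )
    if best is None:  # non-periodic fallback: allow odd rows
        for ny in range(1, spec.n_cells + 1):
            if spec.n_cells % ny:
                continue
            nx = spec.n_cells // ny
            score = abs(np.log((nx / ny) / target))
            if best is None or score < best[0]:
                best = (score, nx, ny)
    _, nx, ny = best
    dx, dy = w / nx, h / ny
    j, i = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = (i + 0.5 * (j % 2) + 0.25) % nx * dx
    y = (j + 0.5) * dy
    return np.column_stack([x.ravel(), y.ravel()])


def generate_tessellation(spec: TessellationSpec) -> Tessellation:
    """Generate an apical tessellation according to ``spec``.

    Voronoi mode seeds uniform random generators and applies the requested
    number of Lloyd relaxation iterations (each replaces generators by their
    cell centroids) before extracting polygons; hexagonal mode places a regular
    offset lattice. Periodic adjacency wraps across the domain edges.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.domain_size
    if spec.lattice_mode == "hexagonal":
        points = _hex_grid(spec)
        iterations = 0
    else:
        points = rng.uniform([0, 0], [w, h], size=(spec.n_cells, 2))
        iterations = spec.lloyd_iterations

    for _ in range(iterations):
        _, centroids, _, _ = _voronoi_geometry(points, spec.domain_size, spec.periodic)
        points = centroids
        if spec.periodic:
            points = np.mod(points, [w, h])
        else:
            points = np.clip(points, [1e-6, 1e-6], [w - 1e-6, h - 1e-6])

    polygons, centroids, areas, adjacency = _voronoi_geometry(
        points, spec.domain_size, spec.periodic
    )
    degrees = np.array([len(adjacency[i + 1]) for i in range(len(points))])
    return Tessellation(
        points=points,
        polygons=polygons,
        centroids=centroids,
        adjacency=adjacency,
        areas=areas,
        degrees=degrees,
        domain_size=spec.domain_size,
        periodic=spec.periodic,
    )


def rasterize_labels(tess: Tessellation) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a tessellation to a label image plus its truth table.

    Each pixel (centre convention) is assigned the id of the Voronoi cell that
    contains it, i.e. its nearest generator (with wrap-around on periodic
    domains). Label ids are consecutive positive integers matching the
    tessellation's cell ids; background 0 does not occur on a full partition.
    Cells too thin to own any pixel are dropped from the truth table with a
    warning.
    """
    w, h = tess.domain_size
    n = tess.n_cells
    if tess.periodic:
        ref = _pad_points(tess.points, tess.domain_size, periodic=True)
    else:
        ref = tess.points
    tree = cKDTree(ref)
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    gx, gy = np.meshgrid(xs, ys)  # rows = y, cols = x
    _, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), workers=-1)
    labels = (idx % n + 1).astype(np.uint16).reshape(h, w)

    truth = tess.truth_table()
    present = np.unique(labels)
    missing = np.setdiff1d(truth["cell_id"].to_numpy(), present)
    if missing.size:
        warnings.warn(
            f"{missing.size} cell(s) thinner than one pixel vanished during "
            "rasterization and were removed from the truth table",
            stacklevel=2,
        )
        truth = truth[~truth["cell_id"].isin(missing)].reset_index(drop=True)
    return labels, truth


# ---------------------------------------------------------------------------
# Mosaic labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicAssignment:
    """Bernoulli mosaic recombination flags, one per cell id (1-based)."""

    p: float
    recombined: np.ndarray  # boolean, index i -> cell id i+1
    seed: int

    def flags_for(self, cell_ids: np.ndarray) -> np.ndarray:
        return self.recombined[np.asarray(cell_ids) - 1]


def assign_mosaic(tess: Tessellation, p: float, seed: int = 0) -> MosaicAssignment:
    """Flag each cell as recombined with i.i.d. probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("recombination fraction p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = rng.random(tess.n_cells) < p
    return MosaicAssignment(p=p, recombined=flags, seed=seed)


def true_cell_classes(tess: Tessellation, mosaic: MosaicAssignment) -> pd.DataFrame:
    """Ground-truth deleted/neighbour/distant classes from the true adjacency."""
    flags = mosaic.recombined
    classes = []
    for i in range(tess.n_cells):
        if flags[i]:
            classes.append("deleted")
        elif any(flags[j - 1] for j in tess.adjacency[i + 1]):
            classes.append("neighbour")
        else:
            classes.append("distant")
    return pd.DataFrame(
        {"cell_id": tess.cell_ids, "recombined": flags, "cell_class": classes}
    )


# ---------------------------------------------------------------------------
# Fluorescence rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for the membrane-reporter channels.

    The red channel carries membrane signal on every cell; the green channel
    only on recombined cells. ``interior_fill`` adds diffuse cytoplasmic green
    signal (as a fraction of the membrane level) inside recombined cells, so
    that intracellular pixel-fraction thresholding behaves as it does on real
    reporter images. An optional myosin-like channel paints per-border-class
    mean intensities and per-cell cap/cortical patterns.
    """

    membrane_width: int = 2
    egfp_level: float = 0.8
    tdtom_level: float = 0.8
    interior_fill: float = 0.15
    noise_sd: float = 0.02
    psf_sigma: float = 1.0
    border_class_intensities: dict[str, float] | None = None
    cap_pattern_assignments: dict[int, str] | None = None
    myosin_level: float = 0.8
    cap_erosion_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("egfp_level", "tdtom_level", "interior_fill", "myosin_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _membrane_ring(labels: np.ndarray, width: int, periodic: bool) -> np.ndarray:
    """Boolean mask of each cell's inner boundary band of the given width."""
    from scipy.ndimage import maximum_filter, minimum_filter

    mode = "wrap" if periodic else "nearest"
    size = 2 * width + 1
    mx = maximum_filter(labels, size=size, mode=mode)
    mn = minimum_filter(labels, size=size, mode=mode)
    return (labels > 0) & ((mx != labels) | (mn != labels))


def render_channels(
    labels: np.ndarray,
    mosaic: MosaicAssignment,
    spec: RenderSpec,
    adjacency: dict[int, set[int]] | None = None,
    cell_classes: pd.DataFrame | None = None,
    periodic: bool = False,
) -> np.ndarray:
    """Render fluorescence channels for a label image.

    Returns a float32 array of shape (C, H, W) in [0, 1] with channel order
    (tdTomato, EGFP[, myosin]). The myosin channel is rendered only when
    ``spec.border_class_intensities`` or ``spec.cap_pattern_assignments`` is
    given; border-class painting needs ``adjacency`` and ``cell_classes``.
    """
    rng = np.random.default_rng(spec.seed)
    ring = _membrane_ring(labels, spec.membrane_width, periodic)
    recombined_cells = set(np.flatnonzero(mosaic.recombined) + 1)
    recomb_mask = np.isin(labels, list(recombined_cells)) if recombined_cells else np.zeros_like(labels, bool)

    tdtom = np.where(ring, spec.tdtom_level, 0.0)
    egfp = np.zeros_like(tdtom)
    egfp[recomb_mask & ring] = spec.egfp_level
    egfp[recomb_mask & ~ring] = spec.interior_fill * spec.egfp_level

    channels = [tdtom, egfp]

    want_myosin = spec.border_class_intensities or spec.cap_pattern_assignments
    if want_myosin:
        myo = np.zeros_like(tdtom)
        if spec.cap_pattern_assignments:
            interior = (labels > 0) & ~ring
            # cap = interior eroded further; cortical = the membrane ring
            for cid, pattern in spec.cap_pattern_assignments.items():
                cell = labels == cid
                if pattern == "cap":
                    myo[cell & interior] = spec.myosin_level
                    myo[cell & ring] = 0.3 * spec.myosin_level
                else:
                    myo[cell & ring] = spec.myosin_level
                    myo[cell & interior] = 0.3 * spec.myosin_level
        if spec.border_class_intensities:
            if adjacency is None or cell_classes is None:
                raise ConfigurationError(
                    "border_class_intensities needs adjacency and cell_classes"
                )
            from .borders import border_class_of  # local import avoids a cycle

            class_map = dict(
                zip(cell_classes["cell_id"], cell_classes["cell_class"])
            )
            r = spec.membrane_width
            from scipy.ndimage import binary_dilation

            struct = np.ones((3, 3), bool)
            edges = {
                (a, b) for a, nbrs in adjacency.items() for b in nbrs if a < b
            }
            for a, b in sorted(edges):
                cls = border_class_of((a, b), class_map)
                level = spec.border_class_intensities.get(cls)
                if level is None:
                    continue
                ma, mb = labels == a, labels == b
                da = binary_dilation(ma, struct, iterations=r)
                db = binary_dilation(mb, struct, iterations=r)
                seg = (ma & db) | (mb & da)
                myo[seg] = level
        channels.append(myo)

    img = np.stack(channels).astype(np.float32)
    if spec.psf_sigma > 0:
        for c in range(img.shape[0]):
            img[c] = gaussian(img[c], sigma=spec.psf_sigma, preserve_range=True)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Apical-area dynamics
# ---------------------------------------------------------------------------

def _default_rates(kind: str) -> dict[str, float]:
    if kind == "dilation":
        return {"control": 0.02, "distant": 0.02, "neighbour": 0.02, "deleted": 0.04}
    return {"control": 0.025, "distant": 0.025, "neighbour": 0.0, "deleted": 0.025}


@dataclass(frozen=True)
class DynamicsSpec:
    """Class-dependent single-pulse apical-area dynamics.

    Each cell dilates linearly up to a random peak time (uniform within the
    imaging window, jittered) and then constricts linearly; rates are per-class
    fractions of baseline per minute. The window defaults to 20 timepoints at
    1-minute sampling.

    Variability is hierarchical and multiplicative: embryos carry shared rate
    multipliers (``embryo_rate_sd``) so cells from one embryo are correlated,
    as in real cohorts; each cell then perturbs its own rates with coefficient
    of variation ``noise_sd`` and its baseline area lognormally
    (``baseline_cv``). ``frame_noise_sd`` adds i.i.d. multiplicative
    measurement noise per timepoint; it defaults to 0 because frame-level
    noise makes the maximum of a non-constricting (flat-tailed) trace
    unidentifiable, which distorts max-aligned averages — see the package
    methods note.
    """

    n_timepoints: int = 20
    baseline_area: float = 300.0
    dilation_rate: dict[str, float] = field(default_factory=lambda: _default_rates("dilation"))
    constriction_rate: dict[str, float] = field(default_factory=lambda: _default_rates("constriction"))
    pulse_period: float = 20.0
    phase_jitter: float = 2.0
    noise_sd: float = 0.05
    embryo_rate_sd: float = 0.1
    baseline_cv: float = 0.1
    frame_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3")
        if any(v < 0 for v in self.dilation_rate.values()) or any(
            v < 0 for v in self.constriction_rate.values()
        ):
            raise ConfigurationError("rates must be >= 0")
        if self.noise_sd < 0 or self.frame_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")


def simulate_area_traces(cells: pd.DataFrame, spec: DynamicsSpec) -> pd.DataFrame:
    """Simulate per-cell apical-area time series.

    ``cells`` needs columns ``cell_id`` and ``cell_class`` (one of
    control/deleted/neighbour/distant); an ``embryo_id`` column is carried
    through (default 1). Returns a long-format frame with columns
    (cell_id, embryo_id, group, t_min, area_px2).
    """
    missing = set(cells["cell_class"]) - set(CELL_CLASSES)
    if missing:
        raise ValueError(f"unknown cell classes: {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_timepoints, dtype=float)
    lo, hi = 2.0, spec.n_timepoints - 3.0
    records = []
    embryo = cells["embryo_id"] if "embryo_id" in cells else pd.Series(1, index=cells.index)
    multipliers = {
        eid: np.maximum(rng.normal(1.0, spec.embryo_rate_sd, size=2), 0.2)
        for eid in sorted(pd.unique(embryo))
    }
    for (_, row), eid in zip(cells.iterrows(), embryo):
        cls = row["cell_class"]
        md, mc = multipliers[eid]
        cell_d, cell_c = np.maximum(1.0 + rng.normal(0.0, spec.noise_sd, size=2), 0.1)
        d = spec.dilation_rate[cls] * md * cell_d
        c = spec.constriction_rate[cls] * mc * cell_c
        baseline = spec.baseline_area * float(np.exp(rng.normal(0.0, spec.baseline_cv)))
        # peaks on the 1-min sampling grid: the discrete trace then attains its
        # true maximum at tp for every class, constricting or not
        tp = rng.integers(int(lo), int(hi) + 1) + rng.normal(0.0, spec.phase_jitter)
        tp = float(np.clip(np.round(tp), 1, spec.n_timepoints - 2))
        area = np.where(
            t <= tp,
            baseline * (1.0 + d * (t - tp)),
            baseline * (1.0 - c * (t - tp)),
        )
        if spec.frame_noise_sd > 0:
            area = area * (1.0 + rng.normal(0.0, spec.frame_noise_sd, size=area.shape))
        area = np.maximum(area, 1e-3 * baseline)
        records.append(
            pd.DataFrame(
                {
                    "cell_id": row["cell_id"],
                    "embryo_id": eid,
                    "group": cls,
                    "t_min": t,
                    "area_px2": area,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Ablation cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationSpec:
    """Hierarchical generator of per-cell post-ablation retraction.

    ``class_means`` are mean percentage area changes (negative = retraction).
    Each embryo draws a shared random effect ~ N(0, sd_embryo) added to every
    cell's class mean; cells then draw ~ N(mean + effect, sd_cell).
    """

    class_means: dict[str, float] = field(
        default_factory=lambda: {"control": -20.0, "deleted": -20.0, "neighbour": -2.0, "distant": -20.0}
    )
    sd_embryo: float = 4.0
    sd_cell: float = 5.0
    n_embryos: int = 10
    cells_per_embryo: int = 3
    baseline_area: float = 600.0
    seed: int = 0


def simulate_ablation_cohort(spec: AblationSpec) -> pd.DataFrame:
    """Draw a cohort of ablation records (one row per cell).

    Returns columns (embryo_id, unit, cell_type, pre_area, post_area,
    true_retraction_pct); ``post = pre * (1 + retraction/100)`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for e in range(1, spec.n_embryos + 1):
        effect = rng.normal(0.0, spec.sd_embryo)
        for ctype, mean in spec.class_means.items():
            for _ in range(spec.cells_per_embryo):
                r = rng.normal(mean + effect, spec.sd_cell)
                pre = spec.baseline_area * float(np.exp(rng.normal(0.0, 0.1)))
                rows.append(
                    {
                        "embryo_id": e,
                        "unit": "cell",
                        "cell_type": ctype,
                        "pre_area": pre,
                        "post_area": pre * (1.0 + r / 100.0),
                        "true_retraction_pct": r,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Embryo cohorts (eversion vs neighbour fraction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort of embryos with varying recombination and correlated eversion.

    Eversion is modelled as elevation (µm) = intercept + slope × neighbour
    fraction + noise; a negative value means the neural folds are everted.
    """

    n_embryos: int = 12
    p_range: tuple[float, float] = (0.05, 0.4)
    eversion_intercept: float = 80.0
    eversion_slope_vs_neighbour_fraction: float = -400.0
    eversion_noise_sd: float = 15.0
    lattice_cells: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.p_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("p_range must lie within [0, 1]")
        if self.n_embryos < 3:
            raise ConfigurationError("n_embryos must be >= 3")


def simulate_embryo_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate per-embryo summaries linking mosaicism to fold eversion.

    Each embryo draws p ~ Uniform(p_range), receives a Bernoulli mosaic on a
    periodic hexagonal lattice, and its neighbour fraction (share of
    non-recombined cells touching >= 1 recombined cell) is measured on the true
    adjacency; elevation then follows the linear model in :class:`CohortSpec`.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_embryos + 1)
    rng = np.random.default_rng(children[0])
    tess = generate_tessellation(
        TessellationSpec(
            n_cells=spec.lattice_cells,
            domain_size=(512, 512),
            periodic=True,
            lattice_mode="hexagonal",
            seed=spec.seed,
        )
    )
    rows = []
    for e in range(1, spec.n_embryos + 1):
        p = rng.uniform(*spec.p_range)
        child = np.random.default_rng(children[e])
        mosaic = MosaicAssignment(
            p=p, recombined=child.random(tess.n_cells) < p, seed=-1
        )
        classes = true_cell_classes(tess, mosaic)
        counts = classes["cell_class"].value_counts()
        n_neg = counts.get("neighbour", 0) + counts.get("distant", 0)
        frac = counts.get("neighbour", 0) / n_neg if n_neg else np.nan
        p_hat = counts.get("deleted", 0) / len(classes)
        elevation = (
            spec.eversion_intercept
            + spec.eversion_slope_vs_neighbour_fraction * frac
            + rng.normal(0.0, spec.eversion_noise_sd)
        )
        rows.append(
            {
                "embryo_id": e,
                "p": p,
                "p_hat": p_hat,
                "neighbour_fraction": frac,
                "elevation_um": elevation,
            }
        )
    return pd.DataFrame(rows)
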