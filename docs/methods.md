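# Methods

`mosaictile` quantifies the consequences of mosaic gene deletion in a
pseudostratified epithelium from 2-D apical segmentations. This note records
the models, the parameter choices that matter, and the limits of what the
synthetic validation shows.

## Image post-processing and morphometrics

Label images (integer rasters, background 0) are assumed to come from an
apical-surface segmentation. Cells touching a border strip of configurable
width (default 30 px) are removed entirely: partial masks would bias area and
perimeter, so beyond the literal pixel replacement the whole cell is excluded
from per-cell statistics. The operation is idempotent at fixed width.

Per-cell features use the equivalent-ellipse convention (second central
moments of the pixel set): area A (px²), perimeter P (weighted boundary
contour length, the scikit-image convention — perimeter is inherently
convention-dependent on a pixel grid, so the convention is fixed here),
solidity A / convex-hull area, and major/minor axis lengths. Orientation is
reported as the acute angle between the apical long axis and the image row
axis, folded into [0, 90]°. The row axis must be the rostrocaudal (RC) axis of
the tissue; 90° then means a mediolaterally (ML) oriented cell. Whether
orientations should be folded to [0, 90] or kept in [0, 180) is a genuine
choice; the folded convention treats rostral-leaning and caudal-leaning tilts
as equivalent, which matches how planar polarity of an axis (not a vector) is
usually summarised. Single-pixel or isotropic cells have no defined long axis
and are flagged instead of silently dropped. Orientation histograms default
to 10° bins (configurable); the median of an even-count sample is the
midpoint of the central pair. Histogram pairs are compared with a chi-square
test of homogeneity; Yates continuity correction applies only to 2×2 tables.

## Mosaic classification

Fluorescence channels from microscope images are min–max rescaled to [0, 1]
per image (a constant channel is an error — thresholding would be undefined).
A cell is called reporter-positive (lineage-traced, gene-deleted) when at
least 75% of its intracellular pixels exceed 0.08, and reporter-negative when
at least 75% fall below 0.06; both inequalities are strict. "Intracellular"
means every pixel of the label, with no erosion. The two one-sided rules
leave a gap: cells with intermediate or mixed intensity meet neither rule and
are kept as *unclassified* rather than forced into a call. Unclassified cells
are excluded from all class counts and denominators, but they do not block an
edge between two classified cells.

Neighbour relations are defined by dilated-mask overlap: cells a and b are
adjacent when the mask of one overlaps the other's mask dilated with a 3×3
square element. The dilation radius is not fixed by the original protocol;
the default of 1 px is the minimal dilation that bridges a one-pixel
watershed/membrane line, and corner contacts count (8-connectivity). The
implementation compares the label image against itself shifted by every
offset with Chebyshev norm ≤ radius, which is mathematically identical to
per-cell dilation and overlap but runs in a handful of vectorised passes; a
periodic mode wraps the shifts for toroidal synthetic masks. The graph is
built after border exclusion, so excluded cells can neither be nodes nor
confer neighbour status.

Classes follow the lineage-tracing logic: reporter-positive cells are
*deleted*; reporter-negative cells touching at least one positive cell are
*neighbours*; reporter-negative cells touching none are *distant*.

## Lewis' law and neighbour-sharing amplification

Lewis' law predicts a linear relation between a cell's apical area and its
neighbour number, with a mean of six neighbours in a planar epithelium; on a
periodic (toroidal) trivalent tessellation the mean is exactly six by Euler's
formula, which is why the periodic domain is the default for statistical
validation (bounded fields of view have boundary effects the closed forms do
not model). The fit is ordinary least squares of A on degree with Pearson's r.

For a mosaic in which each cell is independently deleted with probability p
on a k-regular tessellation:

    f(p) = 1 − (1 − p)^k              (a replete cell touches ≥ 1 deleted cell)
    u(p) = (1 − p) f(p) / p           (unique replete neighbours per deleted cell)

with limits u(0⁺) = k and u(1) = 0, and the degree-distribution
generalisation f(p) = 1 − Σ_k q_k (1 − p)^k, which is exact under label
independence; the u formula additionally assumes degree regularity and is an
approximation for Voronoi degree heterogeneity. f is strictly increasing and
u strictly decreasing in p: more recombination reaches more neighbours in
total, but deleted cells increasingly share them, so the per-cell
amplification of a non-autonomous effect shrinks. The observed counterparts
are: f̂ = |neighbour| / (|neighbour| + |distant|) and
û = |neighbour| / |deleted| (each replete neighbour counted once however many
deleted cells it touches — the reading of "unique neighbours per deleted
cell" consistent with neighbour sharing reducing the ratio). Per-embryo
computation (then pooling embryos) is the default; pooled-over-cells mode is
available.

## Constriction kinetics

Cells pulse asynchronously, so each trace is aligned at T = 0 where it
attains its largest observed apical area (ties to the earliest timepoint) and
expressed as a percentage of that maximum. Group curves are per-timepoint
means ± SEM over cells. Group comparisons aggregate cells to embryo means at
each aligned timepoint and apply two-sample t-tests across embryos with
Bonferroni correction over tested timepoints — a deliberately conservative
replacement for a mixed model whose random-effects structure is not pinned
down; the embryo remains the unit of measure throughout. Timepoints are
tested only when both groups contribute ≥ 2 embryos and ≥ 50% of their cells:
the extremes of the aligned window are populated only by unusually early- or
late-peaking cells, so comparisons there conflate the group effect with
peak-time selection. Traces with fewer than 5 timepoints on either side of
the peak are flagged but retained.

Post-ablation retraction is the percent apical-area change immediately after
annular laser ablation (negative = retraction; scale-invariant in the area
unit). Retractions are averaged per embryo × cell type before any test, which
holds the type-I error at its nominal level under embryo-level random effects
where cell-level pooling inflates it.

The pilot sample-size calculation uses the smallest per-group n at which a
two-sample t-test reaches the target power, starting from the normal
approximation n ≈ 2 (z₁₋α/₂ + z₁₋β)² (sd/δ)² and refining with the
noncentral-t power function (minimum n = 2). The standard deviation behind
the original pilot's n = 24 for a 20% difference is not recorded anywhere, so
that exact n cannot be recomputed; sd is an explicit input.

## Border intensity and cap/cortex patterns

Junctional stain intensity is read per border segment: for each graph edge,
the pixels of either cell within the dilation of the other plus background
pixels covered by both dilations. Segments are classed by their endpoints —
deleted–neighbour, neighbour–neighbour, distant–distant — and every other
pairing (including unclassified endpoints) is OTHER and excluded from the
three-way comparison, since pooling mixed pairs would dilute the contrast.
Per-embryo normalisation sets a reference class to 100%.

Within a cell, the stain is split into an apical cap (the mask eroded r
times, default r = 2) and the cortical ring (the remainder); the two
partition the cell. A cell is CAP when cap/cortex mean ratio ≥ θ (default
θ = 1, so a uniform cell is CAP; the boundary is a convention and both θ and
r are exposed — the original classification was visual, so these defaults are
this package's construction and should be calibrated before quantitative use
on real images).

Border statistics are defined on bounded masks; periodic synthetic
rasterizations are analysed with a non-periodic graph there.

## Fisher's exact test

The 2×2 genotype-by-outcome comparison uses the two-tailed exact test under
the point-probability convention: p sums the hypergeometric probabilities
(margins fixed) of every table with probability no greater than the observed
one. Alternatives (doubling one tail) exist; this is the convention
implemented, and the test suite checks it against a full enumeration oracle.

## The synthetic epithelium

The generator is first-class code, not a fixture: it defines the conditions
every statistical claim in the test suite is made under.

**Geometry.** Voronoi tessellations of uniform random points with Lloyd
relaxation (default 2 iterations) on a periodic or bounded rectangle;
hexagonal lattices as the regular special case. Periodic diagrams are built
by tiling the generators 3×3 (mirroring for bounded domains), so every
central region is finite and adjacency wraps exactly. Rasterization assigns
each pixel to its nearest generator — identical to polygon membership for a
Voronoi diagram — and cells too thin to own a pixel are dropped from the
truth table with a warning.

**Mosaic and rendering.** Recombination is i.i.d. Bernoulli(p). The render
puts membrane signal (an inner boundary band, default 2 px) on every cell in
the red channel and only on recombined cells in the green channel, plus a
diffuse cytoplasmic fill inside recombined cells (default 0.15 of the
membrane level) — without some interior signal an intracellular
pixel-fraction threshold could never call a purely membrane-localised
reporter, whereas real recombined cells carry diffuse signal. Optional
myosin-like channel paints per-border-class intensities and per-cell
cap/cortical patterns. Gaussian PSF blur and additive Gaussian noise are
applied last, clipped to [0, 1].

**Area dynamics.** One dilation→constriction ramp per cell with the peak at a
random timepoint: the analysis aligns at a single maximum within a 20-minute
window sampled once per minute, so a single peak per window suffices. Default
rates: dilation 0.02/min (control, distant, neighbour) and 0.04/min
(deleted); constriction 0.025/min for all classes except neighbours, which do
not constrict (rate 0). The magnitude of the deleted cells' faster dilation
is not quantified anywhere; the 2× default is a free parameter and only the
ordering claims depend on it. Variability is hierarchical: per-embryo shared
rate multipliers (CV 0.1 — without them, embryo-level tests would face a
degenerate between-embryo variance no real cohort has), per-cell rate
multipliers (CV `noise_sd`, default 0.05) and lognormal per-cell baselines
(CV 0.1). Peak times are drawn on the 1-minute sampling grid.

Frame-level measurement noise is deliberately **not** part of the default
conditions and is exposed separately as `frame_noise_sd`. The reason is a
genuine property of max-alignment worth knowing about: for a cell that does
not constrict, the post-peak trace is flat, so under any i.i.d. per-frame
noise the flat values and the true peak are exchangeable and the observed
argmax lands uniformly across the tail — no matter how small the noise. The
aligned "dilation phase" of such cells then mixes in plateau samples and is
systematically compressed, creating spurious pre-peak differences against
constricting groups. Analyses of genuinely non-constricting cells aligned at
a noisy observed maximum inherit this artifact; simulations with
`frame_noise_sd > 0` reproduce it.

**Ablation and cohorts.** Retraction cohorts are hierarchical normal draws:
embryo effect ~ N(0, σ_embryo), cell ~ N(class mean + effect, σ_cell), with
pre/post areas consistent with the drawn percentage by construction. Embryo
cohorts draw p ~ Uniform(p_range) per embryo, measure the neighbour fraction
on a periodic hexagonal lattice (900 cells), and set neural-fold elevation =
intercept + slope × neighbour fraction + noise (defaults +80 µm, −400 µm per
unit fraction, σ = 15 µm — chosen so cohorts spanning the achievable
recombination range cross from elevated folds to eversion, i.e. negative
elevation). All randomness descends from one integer seed per spec through
spawned child streams.

**What the synthetic validation does not show.** The generator has convex,
simply-connected cells, no segmentation errors, no neighbour exchange or
division during traces, no 3-D pseudostratified geometry, no photobleaching
or drift, and independent (non-clustered) recombination. Passing tests
demonstrate that the statistics are implemented correctly and behave as
derived under these conditions — not that the biological effect sizes in any
real tissue are recoverable at these n's.

## Numerical choices

- Degenerate moments (single-pixel / isotropic cells): orientation NaN +
  flag. Constant images: error on rescale. Ties at the trace maximum:
  earliest timepoint. Normalized traces divide before scaling by 100 so the
  maximum is exactly 100.
- Cap/cortex ratio uses an ulp tolerance at the θ boundary so uniform cells
  classify as CAP deterministically.
- Chi-square homogeneity drops bins empty in both samples; fewer than two
  informative bins, or a zero expected count, is an error advising a coarser
  binning.
- Zero-variance group comparisons return p = 1 when the means agree (0
  otherwise) instead of NaN.
- Graph/segment extraction works on bounding boxes padded by the dilation
  radius; periodic modes pad with wrapped copies.

## Problem sizes used in validation

The shipped tests and the acceptance script use 1,000-cell periodic Voronoi
tessellations at 800×800 px for degree recovery, 10⁴-cell hexagonal lattices
for the closed-form/simulation agreement, 196-cell renders for the
classification round trip, 36 cells per class over 5 embryos per group for
kinetics (20 replicate seeds), and 1,000 replicate null cohorts for the
type-I error calibration. These sizes give Monte-Carlo standard errors
comfortably below the tolerances being checked.
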