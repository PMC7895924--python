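# mosaictile

Quantitative analysis of **mosaic gene deletion in epithelia** from apical
cell segmentations — built for the planar-cell-polarity / neural-tube-closure
setting, where a fraction *p* of neuroepithelial cells loses a gene (e.g.
*Vangl2*), is lineage-traced by a membrane reporter switch (tdTomato → EGFP),
and disrupts the apical constriction of its *wild-type neighbours*
non-autonomously.

The package is aimed at developmental biologists and image analysts who have
2-D label masks of the apical surface (e.g. from Cellpose) plus co-registered
fluorescence channels, per-cell apical-area time series from live imaging,
and pre/post laser-ablation areas. It provides:

- **morphometrics** — border-cell exclusion, [0, 1] intensity rescaling,
  per-cell area/perimeter/solidity/axes, and apical long-axis orientation
  (acute angle to the rostrocaudal axis in [0, 90]°, 90° = mediolateral) with
  histogram comparison by chi-square;
- **mosaic classification** — the intracellular pixel-fraction rule
  (EGFP⁺ if ≥ 75% of pixels > 0.08; EGFP⁻ if ≥ 75% < 0.06; otherwise
  unclassified), dilated-mask neighbour graphs, and the
  deleted / neighbour / distant class partition;
- **neighbour amplification** — Lewis'-law fits (apical area *A* vs neighbour
  number *N*; mean *N* = 6 on a periodic trivalent tessellation) and the
  neighbour-sharing model

  ```
  f(p) = 1 − (1 − p)^k            fraction of replete cells touching ≥1 deleted cell
  u(p) = (1 − p) · f(p) / p       unique replete neighbours per deleted cell
  ```

  which shows non-autonomous amplification is largest at low recombination;
- **constriction kinetics** — trace alignment at the largest observed apical
  area (T = 0, 100%), group means ± SEM, embryo-level per-timepoint t-tests
  with Bonferroni correction, ablation retraction (% area change) with the
  embryo as the unit of measure, and noncentral-t sample-size calculations;
- **border intensity** — per-border-segment stain readout by border class
  (EGFP–neighbour / neighbour–neighbour / distant–distant), per-embryo
  normalisation, and apical-cap vs cortical pattern classification;
- **synthetic epithelium** — a ground-truthed generator (Voronoi/hexagonal
  tessellations with exact adjacency, mosaic labelling, membrane renders,
  class-dependent area dynamics, hierarchical ablation cohorts, embryo
  cohorts) that exercises the entire pipeline with no external data.

See `docs/methods.md` for models, conventions, defaults and limitations.

## Worked example

Run the full synthetic pipeline (simulate → classify → neighbour statistics →
kinetics → borders) from Python:

```python
from mosaictile import pipeline as pl

metrics = pl.run_pipeline(pl.PipelineConfig(seed=1, n_cells=400,
                                            domain_size=(400, 400)), "demo")
print(pl.write_report(metrics))
```

or from the shell: `mosaictile run --seed 1 --out demo`. Output:

```
mosaictile run report
========================================
seed: 1
cells retained: 400
mean neighbour degree: 6.045
classification confusion: 0
amplification summary:
  p_hat: 0.18
  mean_total_neighbours_of_deleted: 6.153
  mean_replete_neighbours_of_deleted: 5.097
  fraction_replete_neighbouring: 0.7165
  unique_neighbours_per_deleted: 3.264
  n_deleted: 72
  n_replete: 328
Lewis fit: slope=54.467 px2/neighbour, r=0.421, p=1.38e-18, n=400
kinetics groups: control (n=12), deleted (n=12), neighbour (n=12), distant (n=12)
```

Reading the numbers: the neighbour graph rebuilt from the rasterized mask
recovers the Lewis mean of ~6 neighbours per cell; classification from the
rendered EGFP channel reproduces the ground-truth mosaic with zero confusion;
18% of cells are deleted, each touching ~5.1 replete neighbours on average,
and 72% of replete cells touch at least one deleted cell — but sharing leaves
only ~3.3 *unique* replete neighbours per deleted cell
(u(0.18) = 0.82 · (1 − 0.82⁶)/0.18 ≈ 3.1); apical area correlates positively
with neighbour number (Lewis' law) even on a relaxed random tessellation.

Each stage is also available on its own (`mosaictile simulate|features|
classify|neighbours|kinetics|power`) and as plain functions
(`mosaictile.classify_egfp`, `mosaictile.lewis_law_fit`,
`mosaictile.align_at_max`, `mosaictile.sample_size_two_group`, ...), reading
and writing TIFF masks/channels and CSV tables.

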