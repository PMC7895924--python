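"""Tests of the synthetic epithelium generator against ground truth."""

import numpy as np
import pandas as pd
import pytest

from mosaictile import classify as cf
from mosaictile import kinetics as kn
from mosaictile import synthetic as syn


def _manual_tessellation(points, domain, adjacency):
    """Hand-built tessellation for rasterization edge cases."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    return syn.Tessellation(
        points=points,
        polygons=[np.zeros((0, 2))] * n,
        centroids=points.copy(),
        adjacency=adjacency,
        areas=np.full(n, np.nan),
        degrees=np.array([len(adjacency[i + 1]) for i in range(n)]),
        domain_size=domain,
        periodic=False,
    )


class TestTessellation:
    def test_hexagonal_periodic_all_degree_six(self, hex_tess):
        assert set(hex_tess.degrees) == {6}

    def test_periodic_voronoi_mean_degree_exactly_six(self, voronoi_tess):
        # Euler's formula for a trivalent partition of the torus: E = 3N
        n_edges = sum(len(v) for v in voronoi_tess.adjacency.values()) // 2
        assert n_edges == 3 * voronoi_tess.n_cells
        assert voronoi_tess.degrees.mean() == pytest.approx(6.0)

    def test_nonperiodic_boundary_cells_have_lower_degree(self):
        tess = syn.generate_tessellation(
            syn.TessellationSpec(n_cells=200, domain_size=(300, 300), periodic=False, seed=3)
        )
        assert tess.degrees.mean() < 6
        # cells touching the boundary have fewer neighbours than interior mean
        w, h = tess.domain_size
        margin = 30
        on_edge = (
            (tess.points[:, 0] < margin) | (tess.points[:, 0] > w - margin)
            | (tess.points[:, 1] < margin) | (tess.points[:, 1] > h - margin)
        )
        assert tess.degrees[on_edge].mean() < tess.degrees[~on_edge].mean()

    def test_adjacency_symmetric_no_self_edges(self, voronoi_tess):
        for a, nbrs in voronoi_tess.adjacency.items():
            assert a not in nbrs
            for b in nbrs:
                assert a in voronoi_tess.adjacency[b]

    def test_polygon_areas_partition_domain(self, voronoi_tess):
        w, h = voronoi_tess.domain_size
        assert voronoi_tess.areas.sum() == pytest.approx(w * h, rel=1e-9)

    def test_hexagonal_incompatible_count_raises(self):
        with pytest.raises(ValueError):
            syn.generate_tessellation(
                syn.TessellationSpec(
                    n_cells=7, domain_size=(64, 64), periodic=True, lattice_mode="hexagonal"
                )
            )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            syn.TessellationSpec(n_cells=2)
        with pytest.raises(ValueError):
            syn.TessellationSpec(n_cells=10, domain_size=(16, 64))


class TestRasterize:
    def test_single_cell_covers_domain(self):
        tess = _manual_tessellation([[32, 32]], (64, 64), {1: set()})
        labels, truth = syn.rasterize_labels(tess)
        assert (labels == 1).all()
        assert list(truth["cell_id"]) == [1]

    def test_two_half_domains(self):
        tess = _manual_tessellation(
            [[16, 32], [48, 32]], (64, 64), {1: {2}, 2: {1}}
        )
        labels, truth = syn.rasterize_labels(tess)
        assert set(np.unique(labels)) == {1, 2}
        assert (labels[:, :32] == 1).all() and (labels[:, 32:] == 2).all()
        assert truth["true_degree"].tolist() == [1, 1]

    def test_rasterized_area_within_5pct_of_polygon_area(self, voronoi_tess):
        labels, truth = syn.rasterize_labels(voronoi_tess)
        counts = np.bincount(labels.ravel(), minlength=voronoi_tess.n_cells + 1)
        mean_diam = np.sqrt(voronoi_tess.areas.mean())
        assert mean_diam >= 15
        rel = np.abs(counts[1:] - voronoi_tess.areas) / voronoi_tess.areas
        assert (rel < 0.05).all()


class TestMosaic:
    def test_p_zero_and_one(self, hex_tess):
        assert not syn.assign_mosaic(hex_tess, 0.0, seed=1).recombined.any()
        assert syn.assign_mosaic(hex_tess, 1.0, seed=1).recombined.all()

    def test_bernoulli_fraction(self):
        tess = syn.generate_tessellation(
            syn.TessellationSpec(
                n_cells=10000, domain_size=(1024, 1024), periodic=True,
                lattice_mode="hexagonal", seed=0,
            )
        )
        frac = syn.assign_mosaic(tess, 0.16, seed=5).recombined.mean()
        # binomial SE = sqrt(.16*.84/1e4) ~ 0.0037
        assert frac == pytest.approx(0.16, abs=0.011)

    def test_reproducible_bit_exact(self, hex_tess):
        a = syn.assign_mosaic(hex_tess, 0.3, seed=9)
        b = syn.assign_mosaic(hex_tess, 0.3, seed=9)
        assert np.array_equal(a.recombined, b.recombined)


class TestRender:
    def test_noise_free_channels(self, hex_tess, hex_raster):
        labels, _ = hex_raster
        mosaic = syn.assign_mosaic(hex_tess, 0.2, seed=2)
        img = syn.render_channels(
            labels, mosaic, syn.RenderSpec(noise_sd=0.0, psf_sigma=0.0), periodic=True
        )
        neg = ~np.isin(labels, np.flatnonzero(mosaic.recombined) + 1)
        assert (img[1][neg] == 0).all()  # EGFP dark outside recombined cells
        pos_ids = np.flatnonzero(mosaic.recombined) + 1
        pos = np.isin(labels, pos_ids)
        ring = syn._membrane_ring(labels, 2, periodic=True)
        spec = syn.RenderSpec()
        assert img[1][pos & ring].max() == pytest.approx(spec.egfp_level)
        interior = pos & ~ring
        assert img[1][interior].max() == pytest.approx(spec.interior_fill * spec.egfp_level)
        assert (img[0][ring] > 0).all()  # membrane reporter on every boundary

    def test_classification_round_trip_zero_confusion(self, hex_tess, hex_raster):
        labels, _ = hex_raster
        mosaic = syn.assign_mosaic(hex_tess, 0.16, seed=7)
        img = syn.render_channels(
            labels, mosaic, syn.RenderSpec(noise_sd=0.0, psf_sigma=0.0), periodic=True
        )
        calls = cf.classify_egfp(labels, img[1])
        called_pos = set(calls.loc[calls["call"] == cf.EGFP_POS, "cell_id"])
        true_pos = set(np.flatnonzero(mosaic.recombined) + 1)
        assert called_pos == true_pos
        assert set(calls["call"]) <= {cf.EGFP_POS, cf.EGFP_NEG}


class TestDynamics:
    def test_neighbour_flat_after_peak_without_noise(self):
        cells = pd.DataFrame({"cell_id": [1], "cell_class": ["neighbour"]})
        spec = syn.DynamicsSpec(seed=0, noise_sd=0.0, embryo_rate_sd=0.0, baseline_cv=0.0)
        tr = syn.simulate_area_traces(cells, spec)
        areas = tr["area_px2"].to_numpy()
        peak = int(np.argmax(areas))
        assert np.allclose(areas[peak:], areas[peak])

    def test_deleted_dilation_twice_distant_slope_ratio(self):
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "embryo_id": [1, 1], "cell_class": ["deleted", "distant"]}
        )
        spec = syn.DynamicsSpec(seed=3, noise_sd=0.0, baseline_cv=0.0)
        tr = syn.simulate_area_traces(cells, spec)
        slopes = {}
        for cid, sub in tr.groupby("cell_id"):
            at, pct = kn.align_at_max(sub["t_min"].to_numpy(), sub["area_px2"].to_numpy())
            pre = at < 0
            slopes[cid] = np.polyfit(at[pre], pct[pre], 1)[0]
        # same embryo -> shared rate multiplier cancels in the ratio
        assert slopes[1] / slopes[2] == pytest.approx(2.0, rel=1e-6)

    def test_group_trace_recovery_with_noise(self):
        cells = []
        k = 0
        for cls in ("distant", "deleted", "neighbour"):
            for i in range(36):
                cells.append({"cell_id": k + 1, "embryo_id": i % 5 + 1, "cell_class": cls})
                k += 1
        tr = syn.simulate_area_traces(pd.DataFrame(cells), syn.DynamicsSpec(seed=21))
        al = kn.align_traces(tr)
        pre = al[al["aligned_t"].between(-8, -1)]
        slopes = {
            g: np.polyfit(s["aligned_t"], s["area_pct"], 1)[0]
            for g, s in pre.groupby("group")
        }
        assert slopes["deleted"] > slopes["distant"] * 1.3
        post = al[(al["group"] == "neighbour") & al["aligned_t"].between(1, 8)]
        post_slope = np.polyfit(post["aligned_t"], post["area_pct"], 1)[0]
        assert abs(post_slope) < 0.5  # %/min, flat within noise


class TestAblation:
    def test_zero_variance_gives_exact_class_means(self):
        spec = syn.AblationSpec(sd_embryo=0.0, sd_cell=0.0, n_embryos=3, seed=1)
        rec = syn.simulate_ablation_cohort(spec)
        for ctype, mean in spec.class_means.items():
            got = rec.loc[rec["cell_type"] == ctype, "true_retraction_pct"]
            assert np.allclose(got, mean)

    def test_pre_post_consistent_with_drawn_retraction(self):
        rec = syn.simulate_ablation_cohort(syn.AblationSpec(seed=4))
        pct = 100 * (rec["post_area"] - rec["pre_area"]) / rec["pre_area"]
        assert np.allclose(pct, rec["true_retraction_pct"])

    def test_neighbour_vs_distant_detected_via_embryo_anova(self):
        from scipy import stats as sps

        spec = syn.AblationSpec(
            class_means={"deleted": -20.0, "neighbour": -2.0, "distant": -20.0},
            n_embryos=10, seed=8,
        )
        em = kn.embryo_level_average(syn.simulate_ablation_cohort(spec))
        groups = [g["retraction_pct"].to_numpy() for _, g in em.groupby("cell_type")]
        assert sps.f_oneway(*groups).pvalue < 0.01
        nei = em[em.cell_type == "neighbour"]["retraction_pct"]
        dist = em[em.cell_type == "distant"]["retraction_pct"]
        assert sps.ttest_ind(nei, dist).pvalue < 0.01


class TestCohort:
    def test_noiseless_cohort_perfectly_anticorrelated(self):
        spec = syn.CohortSpec(n_embryos=8, eversion_noise_sd=0.0, lattice_cells=400, seed=2)
        df = syn.simulate_embryo_cohort(spec)
        r = np.corrcoef(df["neighbour_fraction"], df["elevation_um"])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_zero_slope_uncorrelated(self):
        from mosaictile.neighbours import pearson_correlate

        spec = syn.CohortSpec(
            n_embryos=12, eversion_slope_vs_neighbour_fraction=0.0,
            lattice_cells=400, seed=5,
        )
        df = syn.simulate_embryo_cohort(spec)
        _, p, n = pearson_correlate(df, "neighbour_fraction", "elevation_um")
        assert n == 12 and p > 0.05

    def test_neighbour_fraction_increases_with_p_in_expectation(self):
        from mosaictile.neighbours import analytic_neighbour_model

        ps = np.linspace(0.02, 0.6, 15)
        f, _ = analytic_neighbour_model(ps, k=6)
        assert (np.diff(f) > 0).all()

    def test_eversion_sign_matches_slope_sign_across_replicates(self):
        hits = 0
        for seed in range(20):
            df = syn.simulate_embryo_cohort(
                syn.CohortSpec(n_embryos=10, lattice_cells=400, seed=seed)
            )
            r = np.corrcoef(df["neighbour_fraction"], df["elevation_um"])[0, 1]
            hits += r < 0
        assert hits >= 19  # slope negative, noise_sd well below |slope|/4
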