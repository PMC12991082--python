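"""Generator contracts: geometry truth, determinism, self-consistency."""

import numpy as np
import pandas as pd
import pytest

from vasotrace import synthgen as sg
from vasotrace.exceptions import InvalidSpecError


def discrete_tube_count(shape, p0, p1, radius):
    """Brute-force oracle: voxels whose center is within radius of segment."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    L2 = d @ d
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                    axis=-1).reshape(-1, 3).astype(float)
    t = np.clip((grid - p0) @ d / L2, 0, 1)
    dist = np.linalg.norm(grid - (p0 + t[:, None] * d), axis=1)
    return int(np.count_nonzero(dist <= radius))


class TestVascularPhantom:
    def test_straight_branch_truth(self, straight_tube):
        spec, (intensity, mask, truth) = straight_tube
        assert truth["branches"][0]["tortuosity"] == pytest.approx(1.0, abs=1e-12)
        expect = discrete_tube_count((64, 16, 64), (2, 8, 32), (61, 8, 32), 2.0)
        assert int(mask.sum()) == expect

    def test_y_phantom_nodes(self, y_phantom):
        _, (_, _, truth) = y_phantom
        assert truth["n_junctions"] == 1
        assert truth["n_endpoints"] == 3

    def test_semicircle_truth_tortuosity(self, semicircle_phantom):
        _, (_, _, truth) = semicircle_phantom
        tau = truth["branches"][0]["tortuosity"]
        assert tau == pytest.approx(np.pi / 2, rel=0.01)

    def test_truth_self_consistency(self):
        """Stored tortuosity equals arc/chord recomputed from the centerline."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = tuple(map(tuple, np.sort(rng.uniform(5, 55, (4, 3)), axis=0)))
            spec = sg.VascularPhantomSpec((60, 60, 60),
                                          (sg.Branch(pts, 2.0),), seed=seed)
            _, _, truth = sg.generate_vascular_volume(spec)
            rec = truth["branches"][0]
            c = np.asarray(rec["centerline"])
            arc = np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))
            chord = np.linalg.norm(c[-1] - c[0])
            assert rec["tortuosity"] == pytest.approx(arc / chord, abs=1e-9)

    def test_too_few_control_points_rejected(self):
        with pytest.raises(InvalidSpecError):
            sg.VascularPhantomSpec((32, 32, 32),
                                   (sg.Branch(((5, 5, 5),), 2.0),))

    def test_deterministic(self):
        spec = sg.VascularPhantomSpec(
            (32, 16, 32), (sg.Branch(((2, 8, 8), (30, 8, 24)), 2.0),),
            noise_sd=0.1, psf_sigma_vox=1.0, seed=7)
        a = sg.generate_vascular_volume(spec)[0]
        b = sg.generate_vascular_volume(spec)[0]
        np.testing.assert_array_equal(a, b)


class TestKymograph:
    def test_stationary_cells_vertical_streaks(self):
        spec = sg.KymographSpec(duration_ms=100, true_velocity_um_s=0.0, seed=0)
        img, truth = sg.generate_kymograph(spec)
        assert truth["slope_px_per_line"] == 0.0
        # every line identical: streaks run parallel to the time axis
        assert np.ptp(img, axis=0).max() < 1e-12

    def test_unit_slope_velocity_from_acquisition_constants(self):
        v = 0.37 * 833.34  # one pixel per line at the default constants
        spec = sg.KymographSpec(duration_ms=100, true_velocity_um_s=v)
        assert spec.slope_px_per_line == pytest.approx(1.0, abs=1e-12)
        assert v == pytest.approx(308.3358, abs=1e-3)

    def test_streak_centroid_slope_recovery(self):
        """Linear fit to one streak's centroids recovers the stored slope."""
        spec = sg.KymographSpec(duration_ms=120, true_velocity_um_s=80.0,
                                streak_spacing_px=40.0, seed=3)
        img, truth = sg.generate_kymograph(spec)
        dark = 1.0 - img
        r0, c0 = np.unravel_index(np.argmax(dark), dark.shape)
        rows = range(max(r0 - 15, 0), min(r0 + 15, img.shape[0]))
        cents, rr = [], []
        for r in rows:
            w = dark[r]
            sel = slice(max(c0 - 12, 0), min(c0 + 12, img.shape[1]))
            ww = w[sel]
            if ww.sum() > 0.3:
                cents.append((np.arange(*sel.indices(img.shape[1])[:2]) * ww).sum() / ww.sum())
                rr.append(r)
        slope = np.polyfit(rr, cents, 1)[0]
        assert slope == pytest.approx(truth["slope_px_per_line"], abs=0.02)

    def test_zero_pitch_rejected(self):
        with pytest.raises(InvalidSpecError):
            sg.KymographSpec(duration_ms=100, true_velocity_um_s=100.0,
                             pixel_pitch_um=0.0)

    def test_deterministic(self):
        spec = sg.KymographSpec(duration_ms=100, true_velocity_um_s=500.0,
                                noise_sd=0.05, seed=11)
        a, _ = sg.generate_kymograph(spec)
        b, _ = sg.generate_kymograph(spec)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def base():
    return sg.VascularPhantomSpec(
        (20, 48, 48), (sg.Branch(((10, 5, 5), (10, 42, 42)), 2.5),))


class TestAmyloidPhantom:
    def test_background_only_without_deposits(self, base):
        spec = sg.AmyloidPhantomSpec(phantom=base, background_level=0.05)
        vol, _, truth = sg.generate_amyloid_volume(spec)
        np.testing.assert_allclose(vol, 0.05)
        assert truth["caa"] == [] and truth["plaques"] == []

    def test_plaque_ball_count_matches_enumeration(self, base):
        spec = sg.AmyloidPhantomSpec(phantom=base,
                                     plaques=(((8, 40, 8), 3.0, 1.0),))
        _, _, truth = sg.generate_amyloid_volume(spec)
        expect = sum(1 for z in range(-4, 5) for y in range(-4, 5)
                     for x in range(-4, 5) if z * z + y * y + x * x <= 9)
        assert truth["plaques"][0]["n_voxels"] == expect

    def test_half_coverage_by_construction(self, base):
        spec = sg.AmyloidPhantomSpec(phantom=base,
                                     caa_segments=((0, 0.5, 0.9),))
        _, rois, truth = sg.generate_amyloid_volume(spec)
        rec = truth["caa"][0]
        assert rec["coverage_pct"] == pytest.approx(50.0, abs=100.0 / rec["n_footprint_px"])
        assert rec["n_covered_px"] == round(0.5 * rec["n_footprint_px"])

    def test_vessel_overlap_warning(self, base):
        spec = sg.AmyloidPhantomSpec(phantom=base,
                                     plaques=(((10, 20, 20), 3.0, 1.0),))
        _, _, truth = sg.generate_amyloid_volume(spec)
        assert truth["plaques"][0]["overlaps_vessel"]
        assert truth["warnings"]


class TestCohort:
    def test_parallel_lines_without_interaction(self):
        spec = sg.CohortSimSpec(age_slope=0.05, group_effect=0.2,
                                interaction_coef=0.0, noise_sd=0.0)
        tab = sg.simulate_cohort(spec)
        slopes = [np.polyfit(g["age"], g["outcome"], 1)[0]
                  for _, g in tab.groupby("group")]
        assert slopes[0] == pytest.approx(slopes[1], abs=1e-12)

    def test_sigmoid_midpoint_at_inflection(self):
        spec = sg.CohortSimSpec(age_grid_months=(3.0, 12.04, 18.0),
                                sigmoid_params=(0.0, 30.0, 0.8, 12.04),
                                noise_sd=0.0)
        tab = sg.simulate_cohort(spec)
        ad = tab[(tab.group == 1) & (tab.age == 12.04)]
        np.testing.assert_allclose(ad["amyloid"], 15.0, atol=1e-12)

    def test_deterministic(self):
        spec = sg.CohortSimSpec(noise_sd=0.3, seed=5)
        pd.testing.assert_frame_equal(sg.simulate_cohort(spec),
                                      sg.simulate_cohort(spec))

    def test_empty_age_grid_rejected(self):
        with pytest.raises(InvalidSpecError):
            sg.CohortSimSpec(age_grid_months=())


class TestOmicsSim:
    def test_all_null_yields_no_detections(self):
        spec = sg.OmicsSimSpec(gene_universe_size=300,
                               deg_effects={f"g{i:05d}": (1.0, True)
                                            for i in range(50)}, seed=2)
        deg, _, truth = sg.simulate_omics_tables(spec)
        assert (deg["fdr"] >= 0.05).all()
        assert truth["detected_degs"] == []

    def test_placed_degs_overlap_truth(self):
        markers = {"vsmc": {f"g{i:05d}" for i in range(10)}}
        spec = sg.OmicsSimSpec(gene_universe_size=100, marker_sets=markers,
                               deg_effects={f"g{i:05d}": (-1.0, False)
                                            for i in range(10)}, seed=3)
        _, _, truth = sg.simulate_omics_tables(spec)
        assert truth["overlap_counts"]["vsmc"] == 10

    def test_disjoint_marker_sets_zero_overlap(self):
        markers = {"a": {"g00001", "g00002"}, "b": {"g00010", "g00011"}}
        spec = sg.OmicsSimSpec(gene_universe_size=50, marker_sets=markers,
                               deg_effects={"g00030": (2.0, False)}, seed=4)
        _, _, truth = sg.simulate_omics_tables(spec)
        assert truth["overlap_counts"] == {"a": 0, "b": 0}

    def test_marker_outside_universe_rejected(self):
        with pytest.raises(InvalidSpecError):
            sg.OmicsSimSpec(gene_universe_size=10,
                            marker_sets={"a": {"g99999"}})

    def test_deterministic(self):
        spec = sg.OmicsSimSpec(gene_universe_size=100,
                               deg_effects={"g00001": (1.0, False)}, seed=8)
        a, _, _ = sg.simulate_omics_tables(spec)
        b, _, _ = sg.simulate_omics_tables(spec)
        pd.testing.assert_frame_equal(a, b)
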