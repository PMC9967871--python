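"""Cluster segmentation, density, fractional area and neighbour distances."""

import numpy as np
import pytest

import cardioflux as cf
from cardioflux.errors import AnalysisError, ValidationError

FIXED = cf.SegmentationConfig(threshold_method="fixed", threshold_value=0.5)


def _img(px, nm=50.0, **kw):
    return cf.LabelImage(pixels=np.asarray(px, dtype=float), pixel_size_nm=nm, **kw)


def _points_set(pts, frame=15.0):
    clusters = [
        cf.Cluster(i, 0.01, (float(x), float(y)), 10, False) for i, (x, y) in enumerate(pts)
    ]
    return cf.ClusterSet(
        clusters=clusters, channel_label="TOM20", pixel_size_nm=15.0,
        frame_um=(frame, frame), threshold_used=0.5, min_size_used=4,
    )


class TestSegmentClusters:
    def test_blank_image_is_empty_not_error(self):
        cs = cf.segment_clusters(_img(np.zeros((64, 64))))
        assert len(cs) == 0

    def test_threshold_above_max_warns_empty(self):
        cfg = cf.SegmentationConfig(threshold_method="fixed", threshold_value=10.0)
        with pytest.warns(UserWarning, match="threshold"):
            cs = cf.segment_clusters(_img(np.random.default_rng(0).uniform(0, 1, (32, 32))), cfg)
        assert len(cs) == 0

    def test_single_disk_area(self):
        # disk of radius 100 nm rendered at 15 nm/px: area ~ pi * 0.1^2 um^2
        img, _ = cf.gen_cluster_image(
            cf.ClusterImageGenSpec(
                seed=0, n_spots=1, frame_um=2.0, mean_area_um2=np.pi * 0.01,
                area_sigma=1e-9, margin_um=0.5, noise_sd=0.0,
            )
        )
        cs = cf.segment_clusters(img, FIXED)
        assert len(cs) == 1
        assert cs.clusters[0].area_um2 == pytest.approx(np.pi * 0.01, rel=0.15)
        assert cs.clusters[0].area_um2 == cs.clusters[0].n_pixels * 0.015**2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_well_separated_count_exact(self, seed):
        spec = cf.ClusterImageGenSpec(
            seed=seed, n_spots=30, frame_um=10.0, mean_area_um2=0.03,
            min_sep_factor=3.0, margin_um=0.4,
        )
        img, truth = cf.gen_cluster_image(spec)
        assert len(cf.segment_clusters(img)) == truth["n_spots"]

    def test_translation_invariance(self):
        spec = cf.ClusterImageGenSpec(
            seed=3, n_spots=12, frame_um=6.0, min_sep_factor=2.0, margin_um=1.2, noise_sd=0.0
        )
        img, _ = cf.gen_cluster_image(spec)
        rolled = cf.LabelImage(
            pixels=np.roll(img.pixels, (7, -9), axis=(0, 1)), pixel_size_nm=img.pixel_size_nm
        )
        cs0 = cf.segment_clusters(img, FIXED)
        cs1 = cf.segment_clusters(rolled, FIXED)
        assert len(cs0) == len(cs1)
        np.testing.assert_allclose(
            np.sort(cs0.areas_um2), np.sort(cs1.areas_um2), rtol=1e-12
        )
        d0 = np.sort(cf.nearest_neighbour_distances(cs0, cs0))
        d1 = np.sort(cf.nearest_neighbour_distances(cs1, cs1))
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_area_conservation_at_min_size_one(self):
        spec = cf.ClusterImageGenSpec(seed=4, n_spots=10, frame_um=6.0, margin_um=0.5)
        img, _ = cf.gen_cluster_image(spec)
        cfg = cf.SegmentationConfig(threshold_method="fixed", threshold_value=0.5, min_size_px=1)
        cs = cf.segment_clusters(img, cfg)
        mask_px = int((img.pixels > 0.5).sum())
        assert sum(c.n_pixels for c in cs.clusters) == mask_px
        # with a size floor, total cluster area can only shrink
        cs4 = cf.segment_clusters(img, FIXED)
        assert sum(c.n_pixels for c in cs4.clusters) <= mask_px


class TestDensity:
    def test_uniform_grid_is_one_per_um2(self):
        xs = np.arange(0.5, 15.0, 1.0)
        pts = [(x, y) for x in xs for y in xs]  # 225 clusters on a 15x15 um frame
        dm = cf.cluster_density(_points_set(pts))
        assert dm.mean_per_tile == pytest.approx(1.0)
        assert dm.counts.sum() == dm.n_assigned == 225

    def test_assignment_conserves_count(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 15, (300, 2))
        dm = cf.cluster_density(_points_set(pts))
        assert dm.counts.sum() == dm.n_assigned == 300

    def test_tile_larger_than_frame(self):
        with pytest.raises(ValidationError, match="tile"):
            cf.cluster_density(_points_set([(1, 1)]), tile_um2=400.0)


class TestFractionalArea:
    def test_half_filled_frame(self):
        px = np.zeros((200, 200))
        px[:100] = 1.0
        assert cf.fractional_area(_img(px), config=FIXED) == pytest.approx(50.0)

    def test_complement_image(self):
        rng = np.random.default_rng(2)
        px = (rng.uniform(size=(300, 300)) < 0.597).astype(float)
        f = cf.fractional_area(_img(px), config=FIXED)
        fc = cf.fractional_area(_img(1.0 - px), config=FIXED)
        assert f == pytest.approx(59.7, abs=2.0)
        assert f + fc == pytest.approx(100.0)

    def test_raising_threshold_never_increases(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 1, (128, 128))
        img = _img(px)
        fracs = [
            cf.fractional_area(
                img, config=cf.SegmentationConfig(threshold_method="fixed", threshold_value=v)
            )
            for v in np.linspace(0.1, 0.9, 9)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_polygon_roi(self):
        px = np.zeros((100, 100))
        px[:, :50] = 1.0  # left half bright; pixels are 50 nm -> frame 5 um
        roi = np.array([(0.0, 0.0), (2.5, 0.0), (2.5, 5.0), (0.0, 5.0)])  # left half
        assert cf.fractional_area(_img(px), roi_um=roi, config=FIXED) == pytest.approx(
            100.0, abs=2.0
        )

    def test_degenerate_roi(self):
        with pytest.raises(ValidationError):
            cf.fractional_area(_img(np.ones((10, 10))), roi_um=np.zeros((2, 2)), config=FIXED)


class TestNearestNeighbours:
    def test_two_clusters_half_micron_apart(self):
        cs = _points_set([(1.0, 1.0), (1.0, 1.5)])
        np.testing.assert_allclose(cf.nearest_neighbour_distances(cs, cs), [0.5, 0.5])

    def test_single_cluster_self_has_no_neighbour(self):
        cs = _points_set([(1.0, 1.0)])
        with pytest.raises(AnalysisError, match=">= 2"):
            cf.nearest_neighbour_distances(cs, cs)

    def test_empty_reference_set(self):
        with pytest.raises(AnalysisError, match="empty"):
            cf.nearest_neighbour_distances(_points_set([(1, 1)]), _points_set([]))

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(4)
        a_pts = rng.uniform(0, 15, (100, 2))
        b_pts = rng.uniform(0, 15, (80, 2))
        a, b = _points_set(a_pts), _points_set(b_pts)
        d = cf.nearest_neighbour_distances(a, b)
        brute = np.sqrt(((a_pts[:, None, :] - b_pts[None, :, :]) ** 2).sum(-1)).min(1)
        np.testing.assert_array_equal(d, brute)
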