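import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.morphology import disk

from cnvquant.imaging import EnFaceAngiogram, ImageSpec, rasterize_tree
from cnvquant.quantify import (
    BinarizeOptions,
    BinaryFlowMask,
    SkeletonMask,
    binarize_flow,
    box_count_multi_origin,
    delineate_lesion,
    estimate_fractal_dimension,
    estimate_lacunarity,
    quantify_lesion,
    skeletonize_mask,
    surface_area,
    vessel_density,
)
from cnvquant.vessels import generate_vessel_tree, prune_tree

from conftest import brute_force_box_counts

PITCH = 4.5 / 320


def _img(arr: np.ndarray) -> EnFaceAngiogram:
    return EnFaceAngiogram(pixels=arr.astype(np.uint8), pixel_pitch_mm=PITCH)


class TestBinarize:
    def test_all_zero_image_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = binarize_flow(_img(np.zeros((64, 64))))
        assert not mask.mask.any()

    def test_inversion_flag_recovers_same_mask(self, trunk_image):
        direct = binarize_flow(trunk_image)
        inverted = EnFaceAngiogram(
            pixels=(255 - trunk_image.pixels).astype(np.uint8),
            pixel_pitch_mm=trunk_image.pixel_pitch_mm,
        )
        via_flag = binarize_flow(inverted, BinarizeOptions(invert=True))
        assert np.array_equal(direct.mask, via_flag.mask)

    def test_noise_free_trunk_mask_matches_stroke_within_one_pixel(self, trunk_image):
        mask = binarize_flow(trunk_image).mask
        # ground truth: pixels whose coverage is at least half in the raster
        truth = trunk_image.pixels >= round(0.1 * 255) + 0.5 * (255 - round(0.1 * 255))
        from scipy.ndimage import binary_dilation

        assert mask.any()
        assert not (mask & ~binary_dilation(truth, iterations=1)).any()
        assert not (truth & ~binary_dilation(mask, iterations=1)).any()


class TestDelineate:
    def test_single_component_hull(self):
        m = np.zeros((64, 64), bool)
        m[20:30, 20:30] = True
        flow = BinaryFlowMask(m, PITCH)
        kept, hull = delineate_lesion(flow)
        assert np.array_equal(kept.mask, m)
        assert hull.mask.sum() >= m.sum()

    def test_distant_speck_removed(self):
        m = np.zeros((128, 128), bool)
        m[30:60, 30:60] = True
        m[110:112, 110:114] = True  # distant speck
        kept, _ = delineate_lesion(BinaryFlowMask(m, PITCH))
        assert kept.mask[40, 40] and not kept.mask[110, 110]

    def test_touching_lobes_both_retained_one_hull(self):
        m = np.zeros((128, 128), bool)
        m[40:60, 30:60] = True
        m[55:80, 58:90] = True  # overlapping lobe
        kept, hull = delineate_lesion(BinaryFlowMask(m, PITCH))
        assert kept.mask.sum() == m.sum()
        from skimage.measure import label

        assert label(hull.mask, connectivity=2).max() == 1

    def test_empty_mask_gives_empty_lesion(self):
        kept, hull = delineate_lesion(BinaryFlowMask(np.zeros((64, 64), bool), PITCH))
        assert not kept.mask.any() and not hull.mask.any()


class TestSkeletonize:
    def test_bar_becomes_single_line(self):
        m = np.zeros((30, 30), bool)
        m[5:8, 5:25] = True
        skel = skeletonize_mask(BinaryFlowMask(m, PITCH))
        assert 15 <= skel.mask.sum() <= 21
        assert (skel.mask & ~m).sum() == 0

    def test_disk_collapses_to_center(self):
        m = np.zeros((30, 30), bool)
        m[5:26, 5:26] = disk(10).astype(bool)
        skel = skeletonize_mask(BinaryFlowMask(m, PITCH))
        assert skel.mask.sum() <= 5

    def test_component_count_preserved(self):
        from skimage.measure import label

        m = np.zeros((64, 64), bool)
        m[10:20, 10:40] = True
        m[40:45, 45:60] = True
        skel = skeletonize_mask(BinaryFlowMask(m, PITCH))
        assert label(skel.mask, connectivity=2).max() == label(m, connectivity=2).max() == 2


class TestBoxCounting:
    def test_single_pixel_counts_one_everywhere(self):
        m = np.zeros((64, 64), bool)
        m[31, 17] = True
        curve = box_count_multi_origin(SkeletonMask(m, PITCH))
        assert (curve.counts == 1).all()

    def test_full_row_closed_form_at_aligned_origin(self):
        m = np.zeros((64, 64), bool)
        m[10, :] = True
        curve = box_count_multi_origin(SkeletonMask(m, PITCH))
        for i, r in enumerate(curve.box_sizes):
            assert curve.counts[i, 0] == int(np.ceil(64 / r))

    def test_hand_fixture_matches_enumeration(self):
        rng = np.random.default_rng(0)
        m = np.zeros((16, 16), bool)
        pts = [(0, 0), (3, 7), (5, 5), (8, 2), (12, 12), (15, 3), (9, 14)]
        for y, x in pts:
            m[y, x] = True
        curve = box_count_multi_origin(SkeletonMask(m, PITCH))
        for i, r in enumerate(curve.box_sizes):
            for j, (a, b) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
                n, _ = brute_force_box_counts(m, int(r), a * r // 2, b * r // 2)
                assert curve.counts[i, j] == n

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_counts_match_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((32, 32)) < 0.2
        if not m.any():
            m[0, 0] = True
        curve = box_count_multi_origin(SkeletonMask(m, PITCH))
        for i, r in enumerate(curve.box_sizes):
            for j, (a, b) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
                n, masses = brute_force_box_counts(m, int(r), a * r // 2, b * r // 2)
                assert curve.counts[i, j] == n
                assert curve.mass_mean_occ[i, j] == pytest.approx(np.mean(masses))

    def test_counts_non_increasing_in_size_at_aligned_origin(self):
        rng = np.random.default_rng(3)
        m = rng.random((64, 64)) < 0.1
        curve = box_count_multi_origin(SkeletonMask(m, PITCH))
        assert (np.diff(curve.counts[:, 0]) <= 0).all()

    def test_subset_monotonicity(self):
        rng = np.random.default_rng(5)
        b = rng.random((64, 64)) < 0.15
        a = b & (rng.random((64, 64)) < 0.5)
        if not a.any():
            a[np.nonzero(b)[0][0], np.nonzero(b)[1][0]] = True
        ca = box_count_multi_origin(SkeletonMask(a, PITCH))
        cb = box_count_multi_origin(SkeletonMask(b, PITCH))
        assert (ca.counts <= cb.counts).all()
        assert surface_area(BinaryFlowMask(a, PITCH)) <= surface_area(BinaryFlowMask(b, PITCH))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            box_count_multi_origin(SkeletonMask(np.zeros((64, 64), bool), PITCH))


class TestFractalDimension:
    def test_straight_line(self):
        m = np.zeros((512, 512), bool)
        m[256, :] = True
        fd, n0, diag = estimate_fractal_dimension(box_count_multi_origin(SkeletonMask(m, PITCH)))
        assert fd == pytest.approx(1.0, abs=0.05)
        assert diag["r2"] > 0.99

    def test_too_few_sizes_rejected(self):
        m = np.zeros((8, 8), bool)
        m[2, 3] = True
        curve = box_count_multi_origin(SkeletonMask(m, PITCH))
        with pytest.raises(ValueError):
            estimate_fractal_dimension(curve)

    def test_filled_square_as_mask_is_two_dimensional(self):
        m = np.ones((256, 256), bool)
        fd, _, _ = estimate_fractal_dimension(box_count_multi_origin(BinaryFlowMask(m, PITCH)))
        assert fd == pytest.approx(2.0, abs=0.05)


class TestLacunarity:
    def test_fully_occupied_grid_is_zero(self):
        m = np.ones((64, 64), bool)
        curve = box_count_multi_origin(BinaryFlowMask(m, PITCH))
        assert estimate_lacunarity(curve) == 0.0
        assert estimate_lacunarity(curve, include_empty=True) == 0.0

    def test_four_by_four_hand_fixture(self):
        m = np.zeros((4, 4), bool)
        for y, x in [(0, 0), (0, 1), (1, 0), (0, 3), (3, 0), (2, 1)]:
            m[y, x] = True
        curve = box_count_multi_origin(SkeletonMask(m, PITCH), n_origins=1)
        # box masses at R=2: [3, 1, 2, 0]
        assert estimate_lacunarity(curve) == pytest.approx((2 / 3) / 4, abs=1e-12)
        assert estimate_lacunarity(curve, include_empty=True) == pytest.approx(
            1.25 / 1.5**2, abs=1e-12
        )

    def test_clustering_raises_empty_box_lacunarity(self):
        spread = np.zeros((4, 4), bool)
        spread[0, 0] = spread[0, 2] = spread[2, 0] = spread[2, 2] = True
        clustered = np.zeros((4, 4), bool)
        clustered[0, 0] = clustered[0, 1] = clustered[1, 0] = clustered[1, 1] = True
        # pin the bounding box so both patterns cover the same analysis area
        spread[3, 3] = clustered[3, 3] = True
        ls = estimate_lacunarity(
            box_count_multi_origin(SkeletonMask(spread, PITCH), n_origins=1), include_empty=True
        )
        lc = estimate_lacunarity(
            box_count_multi_origin(SkeletonMask(clustered, PITCH), n_origins=1),
            include_empty=True,
        )
        assert lc > ls


class TestAreaDensity:
    def test_surface_area_hand_arithmetic(self):
        m = np.zeros((320, 320), bool)
        m.ravel()[:1024] = True
        assert surface_area(BinaryFlowMask(m, 4.5 / 320)) == pytest.approx(0.2025, abs=1e-12)

    def test_surface_area_additive_and_empty(self):
        a = np.zeros((64, 64), bool)
        b = np.zeros((64, 64), bool)
        a[:10, :10] = True
        b[40:50, 40:55] = True
        sa = surface_area(BinaryFlowMask(a, PITCH))
        sb = surface_area(BinaryFlowMask(b, PITCH))
        sab = surface_area(BinaryFlowMask(a | b, PITCH))
        assert sab == pytest.approx(sa + sb)
        assert surface_area(BinaryFlowMask(np.zeros((8, 8), bool), PITCH)) == 0.0

    def test_vessel_density_half_filled_hull(self):
        region = np.zeros((64, 64), bool)
        region[:20, :30] = True
        flow = region.copy()
        flow[:, ::2] = False  # checkerboard-style half fill
        vd = vessel_density(BinaryFlowMask(flow, PITCH), BinaryFlowMask(region, PITCH))
        assert vd == pytest.approx(flow[region].mean())

    def test_vessel_density_full_region_is_one(self):
        region = np.zeros((32, 32), bool)
        region[5:15, 5:15] = True
        assert vessel_density(BinaryFlowMask(region, PITCH), BinaryFlowMask(region, PITCH)) == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            vessel_density(
                BinaryFlowMask(np.zeros((8, 8), bool), PITCH),
                BinaryFlowMask(np.zeros((8, 8), bool), PITCH),
            )


class TestQuantifyLesion:
    def test_trunk_image_round_trip_fd_near_one(self, trunk_image):
        metrics = quantify_lesion(trunk_image)
        assert metrics.fd == pytest.approx(1.0, abs=0.05)
        assert metrics.sa_mm2 > 0
        assert 0 < metrics.vd <= 1

    def test_pruning_lowers_fd_and_sa(self, noise_free_spec):
        tree = generate_vessel_tree(0.7, seed=9)
        pruned = prune_tree(tree, 8.0)
        m_full = quantify_lesion(rasterize_tree(tree, noise_free_spec, seed=1))
        m_pruned = quantify_lesion(rasterize_tree(pruned, noise_free_spec, seed=1))
        assert m_pruned.fd < m_full.fd
        assert m_pruned.sa_mm2 < m_full.sa_mm2

    def test_duplicate_acquisition_identical_metrics(self, trunk_image):
        a = quantify_lesion(trunk_image)
        b = quantify_lesion(trunk_image)
        assert (a.fd, a.lac, a.sa_mm2, a.vd) == (b.fd, b.lac, b.sa_mm2, b.vd)

    def test_blank_image_flagged_empty(self):
        metrics = quantify_lesion(_img(np.zeros((64, 64))))
        assert metrics.empty_lesion
        assert metrics.sa_mm2 == 0.0
        assert np.isnan(metrics.fd) and np.isnan(metrics.vd)

    def test_scale_consistency_of_surface_area(self):
        # calibers must be resolvable (>= ~2 px) at the coarser grid for
        # the binarized area to be grid-independent
        tree = generate_vessel_tree(0.35, seed=13, caliber_scale=3.0)
        sa = {}
        for px in (320, 640):
            spec = ImageSpec(width_px=px, height_px=px, noise_level=0.0)
            sa[px] = quantify_lesion(rasterize_tree(tree, spec, seed=0)).sa_mm2
        assert abs(sa[640] - sa[320]) / sa[320] < 0.02
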