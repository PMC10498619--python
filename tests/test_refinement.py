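import numpy as np
import pytest

from fabem import (
    EmptySeedRegion,
    FabemError,
    Route,
    SliceClass,
    count_connected_regions,
    make_stage2,
    refine,
    region_grow,
    select_seed,
)

from _oracles import label_oracle, median_oracle, region_grow_oracle
from conftest import blobby_mask


class TestMakeStage2:
    def test_single_isolated_pixel_is_removed(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[5, 5] = 200
        assert not make_stage2(img, 3).any()

    def test_solid_block_interior_survives(self):
        img = np.zeros((14, 14), dtype=np.uint8)
        img[2:12, 2:12] = 80
        out = make_stage2(img, 3)
        assert out[3:11, 3:11].all()

    def test_matches_sliding_window_median_oracle(self, rng):
        for kernel in (3, 5):
            for _ in range(5):
                img = (rng.random((16, 16)) < 0.5).astype(np.uint8) * rng.integers(
                    1, 255
                )
                assert np.array_equal(make_stage2(img, kernel), median_oracle(img, kernel))

    @pytest.mark.parametrize("kernel", [0, 2, 4])
    def test_even_or_nonpositive_kernel_raises(self, kernel):
        with pytest.raises(FabemError):
            make_stage2(np.zeros((8, 8), np.uint8), kernel)


class TestCountConnectedRegions:
    def test_trivial_counts(self):
        assert count_connected_regions(np.zeros((8, 8), bool)) == 0
        blob = np.zeros((8, 8), bool)
        blob[2:5, 2:5] = True
        assert count_connected_regions(blob) == 1

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 2] = mask[3, 3] = True
        assert count_connected_regions(mask, connectivity=8) == 1
        assert count_connected_regions(mask, connectivity=4) == 2

    def test_matches_bfs_labeling_oracle(self, rng):
        for conn in (4, 8):
            for _ in range(10):
                mask = blobby_mask(rng, (24, 24))
                assert count_connected_regions(mask, conn) == label_oracle(mask, conn)[1]


class TestSelectSeed:
    def test_rectangle_scan_matches_brute_force(self):
        mask = np.zeros((512, 512), bool)
        mask[100:301, 200:320] = True
        seed = select_seed(mask, band_halfwidth=5, lift=5)
        # Bottom-most band hit: row 300, leftmost band column 251.
        assert seed == (295, 251)
        assert mask[seed]

    def test_lift_overshoot_falls_back_to_the_only_pixel(self):
        mask = np.zeros((64, 64), bool)
        mask[63, 32] = True  # bottom of the band; lift pushes out of the mask
        seed = select_seed(mask, band_halfwidth=5, lift=5)
        assert seed == (63, 32)

    def test_walks_up_through_an_internal_hole(self):
        mask = np.zeros((64, 64), bool)
        mask[40:61, 20:45] = True
        mask[54:58, 25:40] = False  # the lifted candidate lands in this hole
        seed = select_seed(mask, band_halfwidth=5, lift=5)
        assert mask[seed]
        assert seed.row < 54  # walked up past the hole

    def test_band_empty_uses_pixel_nearest_center(self):
        mask = np.zeros((64, 64), bool)
        mask[10, 5] = True
        mask[30, 50] = True  # closer to the center (31.5, 31.5)
        assert select_seed(mask) == (30, 50)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptySeedRegion):
            select_seed(np.zeros((16, 16), bool))

    def test_deterministic(self, rng):
        mask = blobby_mask(rng, (64, 64))
        assert select_seed(mask) == select_seed(mask)


class TestRegionGrow:
    def test_single_component_is_identity(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        out = region_grow(mask, (5, 5))
        assert np.array_equal(out, mask)

    def test_keeps_only_the_seeded_blob(self):
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:14] = True
        out = region_grow(mask, (3, 3))
        assert out[2:5, 2:5].all() and not out[10:14, 10:14].any()

    def test_matches_bfs_oracle_on_random_masks(self, rng):
        for _ in range(50):
            mask = blobby_mask(rng, (64, 64))
            if not mask.any():
                continue
            rows, cols = np.nonzero(mask)
            k = rng.integers(len(rows))
            seed = (int(rows[k]), int(cols[k]))
            grown = region_grow(mask, seed)
            assert np.array_equal(grown, region_grow_oracle(mask, seed))
            # output ⊆ input, connected, idempotent
            assert not (grown & ~mask).any()
            assert count_connected_regions(grown) == 1
            assert np.array_equal(region_grow(grown, seed), grown)

    def test_single_region_iff_growth_recovers_everything(self, rng):
        for _ in range(10):
            mask = blobby_mask(rng, (32, 32))
            if not mask.any():
                continue
            rows, cols = np.nonzero(mask)
            seed = (int(rows[0]), int(cols[0]))
            full = np.array_equal(region_grow(mask, seed), mask)
            assert full == (count_connected_regions(mask) == 1)

    def test_background_seed_raises(self):
        mask = np.zeros((8, 8), bool)
        mask[1, 1] = True
        with pytest.raises(FabemError):
            region_grow(mask, (5, 5))
        with pytest.raises(FabemError):
            region_grow(mask, (20, 0))


class _ConstClassifier:
    name = "const"

    def __init__(self, label):
        self.label = label

    def classify(self, gray, stage2=None):
        return self.label


class _ConstSegmenter:
    name = "const"

    def __init__(self, mask):
        self.mask = mask

    def segment(self, gray):
        return self.mask


class TestRefine:
    def _gray(self, shape):
        return np.full(shape, 80, dtype=np.uint8)

    def test_single_component_goes_direct_unchanged(self):
        stage2 = np.zeros((32, 32), bool)
        stage2[8:24, 8:24] = True
        res = refine(
            stage2,
            self._gray((32, 32)),
            _ConstClassifier(SliceClass.OTHER_LAYER),
            _ConstSegmenter(stage2),
        )
        assert res.route is Route.DIRECT
        assert np.array_equal(res.final_mask, stage2)
        assert res.n_regions == 1

    def test_single_region_class_routes_to_region_growing(self):
        stage2 = np.zeros((64, 64), bool)
        stage2[30:56, 20:45] = True  # brain over the midline
        stage2[5:9, 30:34] = True  # spurious scalp blob above
        res = refine(
            stage2,
            self._gray((64, 64)),
            _ConstClassifier(SliceClass.OTHER_LAYER),
            _ConstSegmenter(stage2),
        )
        assert res.route is Route.REGION_GROW
        assert res.final_mask[40, 30] and not res.final_mask[6, 31]
        assert not (res.final_mask & ~stage2).any()
        assert res.seed is not None and stage2[res.seed]

    def test_multi_region_class_dispatches_to_the_segmenter(self):
        stage2 = np.zeros((32, 32), bool)
        stage2[4:10, 4:10] = True
        stage2[20:28, 20:28] = True
        seg_out = np.zeros((32, 32), bool)
        seg_out[15:18, 15:18] = True
        res = refine(
            stage2,
            self._gray((32, 32)),
            _ConstClassifier(SliceClass.MULTI_REGION),
            _ConstSegmenter(seg_out),
        )
        assert res.route is Route.SEGMENTER
        assert np.array_equal(res.final_mask, seg_out)

    def test_intersect_stage2_option_ands_the_segmenter_output(self):
        stage2 = np.zeros((32, 32), bool)
        stage2[4:10, 4:10] = True
        stage2[20:28, 20:28] = True
        res = refine(
            stage2,
            self._gray((32, 32)),
            _ConstClassifier(SliceClass.MULTI_REGION),
            _ConstSegmenter(np.ones((32, 32), bool)),
            intersect_stage2=True,
        )
        assert np.array_equal(res.final_mask, stage2)
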