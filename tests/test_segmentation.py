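import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from imatct import (
    CTVolume, SegmentationConfig, LABELS,
    threshold_mask, exclude_bone, exclude_skin, plant_seeds,
    region_grow, segment_soft_tissue, gaussian_filter, FilterSpec,
)
from oracles import bfs_flood_fill, loop_threshold_count


def _vol(values, voxel=0.164):
    return CTVolume(np.asarray(values, dtype=float), voxel)


class TestThresholdMask:
    def test_closed_interval_band(self):
        vol = _vol([[[-700.0, -600.0, 0.0, 100.0, 101.0]]])
        mask = threshold_mask(vol, -600, 100)
        assert mask.sum() == 3  # both band edges included

    def test_full_band_selects_everything_and_empty_band_nothing(self, rng):
        vol = _vol(rng.normal(0, 500, size=(4, 4, 4)))
        assert threshold_mask(vol, -1e9, 1e9).all()
        assert not threshold_mask(vol, 5, 5).any()  # value 5 absent a.s.

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(_vol(np.zeros((2, 2, 2))), 10, -10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), lo=st.integers(-500, 0), width=st.integers(0, 500))
    def test_equals_per_voxel_loop_and_band_monotonicity(self, seed, lo, width):
        values = np.random.default_rng(seed).integers(-600, 600, size=(3, 4, 3)).astype(float)
        vol = _vol(values)
        mask = threshold_mask(vol, lo, lo + width)
        assert int(mask.sum()) == loop_threshold_count(values, lo, lo + width)
        wider = threshold_mask(vol, lo - 50, lo + width + 50)
        assert not (mask & ~wider).any()


class TestExcludeBone:
    def test_cortical_cylinder_recovered_within_one_voxel(self):
        shape = (12, 40, 40)
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        r = np.hypot(yy - 19.5, xx - 19.5)
        cyl = np.broadcast_to(r <= 8, shape)
        values = np.where(cyl, 1500.0, 300.0)
        mask = exclude_bone(_vol(values), SegmentationConfig())
        ring = ndimage.binary_dilation(cyl) & ~ndimage.binary_erosion(cyl)
        assert not (mask ^ cyl)[~ring].any()

    def test_all_soft_tissue_gives_empty_mask(self):
        assert not exclude_bone(_vol(np.full((4, 4, 4), 300.0))).any()

    def test_two_bones_remain_two_components(self):
        values = np.full((6, 20, 20), 300.0)
        values[:, 2:7, 2:7] = 1500.0   # tibia analogue
        values[:, 12:18, 12:18] = 1500.0  # fibula analogue
        mask = exclude_bone(_vol(values), SegmentationConfig())
        _, n = ndimage.label(mask)
        assert n == 2


class TestExcludeSkin:
    @staticmethod
    def _block_in_air(block=20, pad=4):
        n = block + 2 * pad
        values = np.full((n, n, n), -1000.0)
        sl = slice(pad, pad + block)
        values[sl, sl, sl] = 0.0
        return _vol(values)

    def test_zero_depth_gives_empty_mask(self):
        cfg = SegmentationConfig(skin_depth_vox=0)
        assert not exclude_skin(self._block_in_air(), cfg).any()

    def test_two_voxel_shell_matches_iterated_dilation_oracle(self):
        vol = self._block_in_air()
        cfg = SegmentationConfig(skin_depth_vox=2)
        mask = exclude_skin(vol, cfg)
        air = vol.values <= -800
        grown = air.copy()
        for _ in range(2):
            grown = ndimage.binary_dilation(grown, ndimage.generate_binary_structure(3, 1))
        assert np.array_equal(mask, grown & ~air)
        # interior of the block untouched
        interior = np.zeros_like(air)
        interior[7:-7, 7:-7, 7:-7] = True
        assert not (mask & interior).any()

    def test_enclosed_air_pocket_is_not_exterior(self):
        vol = self._block_in_air()
        vol.values[12:14, 12:14, 12:14] = -1000.0  # internal cavity
        cfg = SegmentationConfig(skin_depth_vox=2)
        mask = exclude_skin(vol, cfg)
        around_pocket = np.zeros_like(mask)
        around_pocket[10:16, 10:16, 10:16] = True
        assert not (mask & around_pocket).any()

    def test_volume_without_exterior_raises(self):
        with pytest.raises(ValueError, match="no exterior"):
            exclude_skin(_vol(np.zeros((6, 6, 6))), SegmentationConfig())


class TestPlantSeeds:
    def test_single_voxel_speckles_removed(self, rng):
        values = np.full((10, 10, 10), -1000.0)
        idx = rng.integers(1, 9, size=(5, 3))
        values[idx[:, 0], idx[:, 1], idx[:, 2]] = 300.0  # isolated speckles
        seeds = plant_seeds(_vol(values), (100, 600), SegmentationConfig())
        assert not seeds.any()

    def test_no_voxels_in_band_gives_empty_seeds(self):
        seeds = plant_seeds(_vol(np.zeros((6, 6, 6))), (100, 600))
        assert not seeds.any()

    def test_phantom_muscle_seeds_lie_inside_true_muscle(self, small_phantom):
        _, vol, truth = small_phantom
        filtered = gaussian_filter(vol, FilterSpec())
        cfg = SegmentationConfig()
        seeds = plant_seeds(filtered, cfg.muscle_band, cfg)
        assert seeds.any()
        muscle = truth.mask("muscle")
        assert (seeds & ~muscle).sum() / seeds.sum() < 0.01


class TestRegionGrow:
    def test_matches_bfs_flood_fill_oracle(self, rng):
        values = rng.choice([300.0, -1000.0], p=[0.6, 0.4], size=(16, 16, 16))
        vol = _vol(values)
        eligible = (values >= 100) & (values <= 600)
        seed_candidates = np.argwhere(eligible)
        seeds = np.zeros_like(eligible)
        seeds[tuple(seed_candidates[0])] = True
        cfg = SegmentationConfig(iterations=64, relaxed_margin_hu=0.0)
        seg = region_grow(vol, seeds, np.zeros_like(seeds), cfg)
        expected = bfs_flood_fill(eligible, seeds, connectivity=6)
        assert np.array_equal(seg.mask("muscle"), expected)

    def test_one_iteration_adds_only_band_eligible_neighbours(self):
        values = np.array([[[300.0, 300.0, -1000.0, 300.0, 300.0]]])
        seeds = np.zeros((1, 1, 5), dtype=bool)
        seeds[0, 0, 0] = True
        cfg = SegmentationConfig(iterations=1, relaxed_margin_hu=0.0)
        seg = region_grow(_vol(values), seeds, np.zeros_like(seeds), cfg)
        assert list(seg.mask("muscle")[0, 0]) == [True, True, False, False, False]

    def test_growth_is_monotone_in_iterations(self, rng):
        values = rng.choice([300.0, -400.0, -1000.0], size=(12, 12, 12))
        vol = _vol(values)
        m_seeds = np.zeros((12, 12, 12), dtype=bool)
        f_seeds = np.zeros_like(m_seeds)
        m_seeds[6, 6, 6] = values[6, 6, 6] == 300.0
        f_seeds[2, 2, 2] = values[2, 2, 2] != 300.0
        prev = None
        for k in (1, 3, 5):
            seg = region_grow(vol, m_seeds, f_seeds, SegmentationConfig(iterations=k))
            both = seg.mask("muscle") | seg.mask("subcutaneous_fat")
            if prev is not None:
                assert not (prev & ~both).any()
            prev = both

    def test_contested_voxel_tie_goes_to_muscle(self):
        # midpoints +6 (muscle) and -6 (fat); the 0 HU voxel is equidistant
        values = np.array([[[-6.0, 0.0, 6.0]]])
        m_seeds = np.array([[[False, False, True]]])
        f_seeds = np.array([[[True, False, False]]])
        cfg = SegmentationConfig(muscle_band=(2, 10), fat_band=(-10, -2),
                                 iterations=1, relaxed_margin_hu=10.0)
        seg = region_grow(_vol(values), m_seeds, f_seeds, cfg)
        assert seg.mask("muscle")[0, 0, 1]
        assert not seg.mask("subcutaneous_fat")[0, 0, 1]

    def test_no_seeds_leaves_everything_unassigned(self):
        vol = _vol(np.full((4, 4, 4), 300.0))
        empty = np.zeros((4, 4, 4), dtype=bool)
        seg = region_grow(vol, empty, empty)
        assert (seg.labels == LABELS["unassigned"]).all()

    def test_overlapping_seeds_rejected(self):
        vol = _vol(np.zeros((3, 3, 3)))
        seeds = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            region_grow(vol, seeds, seeds)

    def test_result_is_deterministic(self, rng):
        values = rng.choice([300.0, -400.0], size=(10, 10, 10))
        vol = _vol(values)
        m = np.zeros_like(values, dtype=bool); m[5, 5, 5] = True
        f = np.zeros_like(m); f[1, 1, 1] = True
        a = region_grow(vol, m, f).labels
        b = region_grow(vol, m, f).labels
        assert np.array_equal(a, b)


class TestSegmentSoftTissue:
    def test_all_air_volume_is_all_background(self):
        vol = _vol(np.full((6, 6, 6), -1000.0))
        seg = segment_soft_tissue(vol)
        assert (seg.labels == LABELS["air"]).all()
        assert not seg.mask("muscle").any()

    def test_labels_partition_the_volume(self, small_phantom):
        _, vol, _ = small_phantom
        seg = segment_soft_tissue(gaussian_filter(vol, FilterSpec()))
        counts = np.bincount(seg.labels.ravel(), minlength=6)
        assert counts.sum() == vol.values.size
        # compartments are mutually exclusive by construction of the label
        # volume; muscle and fat must both be present in a leg phantom
        assert counts[LABELS["muscle"]] > 0
        assert counts[LABELS["subcutaneous_fat"]] > 0
        assert counts[LABELS["bone"]] > 0
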