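"""Two-plane seeded region growing: identities, connectivity, oracle."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliovol.grids import BinaryMask, ImageVolume
from gliovol.segmentation import (
    RunawayGrowthError,
    SeedContour,
    SegmentationError,
    manual_edit,
    mask_volume_ml,
    seeds_from_mask,
    segment_semiauto,
)


def _sphere_image(radius=8, shape=(32, 32, 32), inside=1.0, outside=0.0):
    c = (np.asarray(shape) - 1) / 2
    g = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum((g[i] - c[i]) ** 2 for i in range(3))
    mask = d2 <= radius**2
    img = np.where(mask, inside, outside)
    return ImageVolume(img), mask


def _seeds_for(mask):
    return seeds_from_mask(mask, erode=1)


class TestRegionGrowing:
    def test_noiseless_sphere_recovered_exactly_with_analytic_volume(self):
        img, mask = _sphere_image(radius=8)
        ax, co = _seeds_for(mask)
        seg = segment_semiauto(img, ax, co, closing_radius=0)
        np.testing.assert_array_equal(seg.grid, mask)
        analytic = 4.0 / 3.0 * math.pi * 8**3 / 1000.0  # ml at 1 mm voxels
        # within one voxel shell of the discretised sphere surface
        shell = 4.0 * math.pi * 8**2 / 1000.0
        assert abs(seg.volume_ml - analytic) <= shell

    def test_growth_respects_connectivity_between_disjoint_blobs(self):
        img, mask = _sphere_image(radius=5, shape=(48, 24, 24))
        # second bright blob, disjoint from the first
        img.data[34:40, 8:14, 8:14] = 1.0
        ax, co = _seeds_for(mask)
        seg = segment_semiauto(img, ax, co, closing_radius=0)
        np.testing.assert_array_equal(seg.grid, mask)

    def test_all_voxels_within_tolerance_band_without_closing(self, rng):
        img, mask = _sphere_image(radius=7)
        img.data = img.data + rng.normal(0, 0.05, img.shape)
        ax, co = _seeds_for(mask)
        seg = segment_semiauto(img, ax, co, closing_radius=0)
        seed_vals = img.data[ax.to_volume_mask(img.shape) | co.to_volume_mask(img.shape)]
        half = 2.5 * seed_vals.std()
        inside = img.data[seg.grid]
        grown = seg.grid & ~(ax.to_volume_mask(img.shape) | co.to_volume_mask(img.shape))
        assert np.all(img.data[grown] >= seed_vals.mean() - half)
        assert np.all(img.data[grown] <= seed_vals.mean() + half)

    def test_monotone_in_tolerance(self, rng):
        img, mask = _sphere_image(radius=7)
        img.data = img.data + rng.normal(0, 0.1, img.shape)
        ax, co = _seeds_for(mask)
        prev = None
        for k in (1.0, 2.0, 3.0):
            seg = segment_semiauto(img, ax, co, tolerance_k=k)
            if prev is not None:
                assert np.all(prev.grid <= seg.grid)  # loosening never shrinks
            prev = seg

    def test_seed_voxels_always_contained(self, rng):
        img, mask = _sphere_image(radius=6)
        img.data = img.data + rng.normal(0, 0.2, img.shape)
        ax, co = _seeds_for(mask)
        seg = segment_semiauto(img, ax, co, tolerance_k=0.5)
        assert np.all(seg.grid[ax.to_volume_mask(img.shape)])
        assert np.all(seg.grid[co.to_volume_mask(img.shape)])

    def test_matches_naive_bfs_oracle_on_small_images(self, rng):
        """Exhaustive breadth-first in-band growth on random 24³ images."""
        for trial in range(5):
            img = ImageVolume(rng.normal(0.5, 0.3, (24, 24, 24)))
            img.data[8:16, 8:16, 8:16] += 2.0  # bright core
            core = np.zeros(img.shape, bool)
            core[10:14, 10:14, 10:14] = True
            ax, co = seeds_from_mask(core, erode=0)
            seg = segment_semiauto(img, ax, co, tolerance_k=2.0, closing_radius=0)

            seed_vol = ax.to_volume_mask(img.shape) | co.to_volume_mask(img.shape)
            vals = img.data[seed_vol]
            lo, hi = vals.mean() - 2.0 * vals.std(), vals.mean() + 2.0 * vals.std()
            band = (img.data >= lo) & (img.data <= hi)
            visited = np.zeros(img.shape, bool)
            q = deque(map(tuple, np.argwhere(seed_vol & band)))
            for v in q:
                visited[v] = True
            while q:
                x, y, z = q.popleft()
                for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    n = (x+dx, y+dy, z+dz)
                    if all(0 <= n[i] < img.shape[i] for i in range(3)) \
                            and band[n] and not visited[n]:
                        visited[n] = True
                        q.append(n)
            expected = visited | seed_vol
            np.testing.assert_array_equal(seg.grid, expected)

    def test_runaway_growth_raises(self):
        img = ImageVolume(np.ones((32, 32, 32)))  # uniform: band covers all
        core = np.zeros(img.shape, bool)
        core[14:18, 14:18, 14:18] = True
        ax, co = seeds_from_mask(core, erode=0)
        with pytest.raises(RunawayGrowthError):
            segment_semiauto(img, ax, co, volume_cap_ml=1.0)

    def test_empty_seed_rejected(self):
        with pytest.raises(SegmentationError):
            SeedContour("axial", 5, np.zeros((8, 8), bool))


class TestManualEdit:
    def test_empty_edit_is_identity(self):
        m = BinaryMask(np.random.default_rng(0).random((8, 8, 8)) > 0.5)
        out = manual_edit(m)
        np.testing.assert_array_equal(out.grid, m.grid)

    def test_erase_everything_gives_zero_volume(self):
        m = BinaryMask(np.ones((4, 4, 4), bool))
        out = manual_edit(m, erase=m.grid.copy())
        assert mask_volume_ml(out) == 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_add_then_erase_same_set_restores_original(self, seed):
        rng = np.random.default_rng(seed)
        m = BinaryMask(rng.random((6, 6, 6)) > 0.5)
        sel = (rng.random((6, 6, 6)) > 0.7) & ~m.grid
        added = manual_edit(m, add=sel)
        restored = manual_edit(added, erase=sel)
        np.testing.assert_array_equal(restored.grid, m.grid)


class TestVolume:
    @pytest.mark.parametrize(
        "n_voxels, spacing, expected_ml",
        [
            (1000, (1.0, 1.0, 1.0), 1.0),
            (0, (1.0, 1.0, 1.0), 0.0),
            # high-resolution FLAIR voxel size: 2500 × 1.04·1.04·1.12 mm³
            (2500, (1.04, 1.04, 1.12), 2500 * 1.04 * 1.04 * 1.12 / 1000.0),
        ],
    )
    def test_volume_is_count_times_voxel_volume(self, n_voxels, spacing, expected_ml):
        grid = np.zeros((20, 20, 20), bool)
        grid.ravel()[:n_voxels] = True
        m = BinaryMask(grid, spacing)
        assert mask_volume_ml(m) == pytest.approx(expected_ml, rel=1e-12)
        if n_voxels == 2500:
            assert mask_volume_ml(m) == pytest.approx(3.028, abs=5e-4)
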