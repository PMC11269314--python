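
import numpy as np
import pytest

from oaskin import segmentation as seg
from oaskin.rsom import BandVolume


def volume(V, dz=0.01, flattened=False):
    return BandVolume(
        V=np.asarray(V, dtype=float),
        band_MHz=None,
        voxel_size_mm=(dz, 0.015, 0.03),
        flattened=flattened,
    )


class TestDetectSurface:
    def test_bright_plane_over_zero_background(self):
        V = np.zeros((100, 8, 6))
        V[40] = 5.0
        surf = seg.detect_surface(volume(V))
        np.testing.assert_array_equal(surf.indices, 40)

    def test_tilted_plane_within_one_voxel(self):
        nz, nx, ny = 120, 60, 10
        V = np.zeros((nz, nx, ny))
        x = np.arange(nx)
        plane = np.rint(30 + 0.2 * x).astype(int)
        for i in range(nx):
            V[plane[i] :, i, :] = 3.0  # tissue from the plane downward
        surf = seg.detect_surface(volume(V), smooth_sigma_lateral=0.0)
        assert np.all(np.abs(surf.indices - plane[:, None]) <= 1)

    def test_pure_noise_raises(self, rng):
        V = np.abs(rng.normal(0, 0.1, size=(120, 10, 10)))
        with pytest.raises(ValueError, match="no surface found"):
            seg.detect_surface(volume(V))

    def test_flattened_input_rejected(self):
        V = np.zeros((10, 2, 2))
        V[4] = 1.0
        with pytest.raises(ValueError, match="flattened"):
            seg.detect_surface(volume(V, flattened=True))


class TestFlatten:
    def test_constant_surface_is_a_roll_with_zero_fill(self, rng):
        V = rng.random((50, 4, 3))
        surf = seg.SurfaceMap(indices=np.full((4, 3), 7), detection_threshold=0.0)
        out = seg.flatten(volume(V), surf)
        np.testing.assert_array_equal(out.V[: 50 - 7], V[7:])
        assert np.all(out.V[50 - 7 :] == 0.0)
        assert out.flattened

    def test_tilted_surface_variance_removed(self):
        nz, nx, ny = 120, 40, 8
        V = np.zeros((nz, nx, ny))
        plane = np.rint(30 + 0.3 * np.arange(nx)).astype(int)
        for i in range(nx):
            V[plane[i] :, i, :] = 2.0
        vol = volume(V)
        surf = seg.detect_surface(vol, smooth_sigma_lateral=0.0)
        flat = seg.flatten(vol, surf)
        onset = np.argmax(flat.V > 1.0, axis=0)
        assert onset.var() <= 1.0

    def test_intensity_bookkeeping(self, rng):
        V = rng.random((30, 5, 4))
        s = np.full((5, 4), 6)
        out = seg.flatten(volume(V), seg.SurfaceMap(s, 0.0))
        shifted_out = V[:6].sum()
        assert out.V.sum() == pytest.approx(V.sum() - shifted_out)
        assert out.V.size == V.size  # voxel count preserved

    def test_double_flatten_rejected(self, rng):
        V = rng.random((20, 3, 3))
        surf = seg.SurfaceMap(np.zeros((3, 3), int), 0.0)
        flat = seg.flatten(volume(V), surf)
        with pytest.raises(ValueError, match="already flattened"):
            seg.flatten(flat, surf)


class TestSplitStacks:
    @pytest.mark.parametrize(
        "slow_extent_mm,expected",
        [(2.0, 4), (1.0, 2)],  # 0.5 mm stacks
    )
    def test_stack_counts(self, slow_extent_mm, expected, rng):
        dy = 0.03
        ny = int(np.floor(slow_extent_mm / dy)) + 1
        V = rng.random((20, 4, ny))
        stacks = seg.split_stacks(volume(V, flattened=True), 0.5)
        assert len(stacks) == expected

    def test_concatenation_reproduces_input(self, rng):
        V = rng.random((20, 4, 67))
        stacks = seg.split_stacks(volume(V, flattened=True), 0.5)
        np.testing.assert_array_equal(
            np.concatenate([s.V for s in stacks], axis=2), V
        )

    def test_unflattened_rejected(self, rng):
        with pytest.raises(ValueError, match="flattened"):
            seg.split_stacks(volume(rng.random((20, 4, 67))), 0.5)

    def test_too_thin_stacks_rejected(self, rng):
        V = rng.random((20, 4, 8))
        with pytest.raises(ValueError, match="3 slow"):
            # 8 slow steps of 30 µm = 0.24 mm; 0.06 mm stacks -> 2 steps each
            seg.split_stacks(volume(V, flattened=True), 0.06)


class TestStackMip:
    def test_constant_along_slow_axis(self, rng):
        sl = rng.random((15, 6))
        V = np.repeat(sl[:, :, None], 5, axis=2)
        np.testing.assert_array_equal(
            seg.stack_mip(volume(V, flattened=True)), sl
        )

    def test_single_bright_voxel(self):
        V = np.zeros((10, 8, 4))
        V[3, 5, 2] = 9.0
        mip = seg.stack_mip(volume(V, flattened=True))
        assert mip[3, 5] == 9.0
        assert (mip > 0).sum() == 1

    def test_matches_bruteforce_max(self, rng):
        V = rng.random((7, 5, 6))
        mip = seg.stack_mip(volume(V, flattened=True))
        for i in range(7):
            for j in range(5):
                assert mip[i, j] == max(V[i, j, k] for k in range(6))


def brute_force_min_path(cost: np.ndarray, max_slope: int):
    """Exhaustive enumeration over all admissible (slope-limited) paths."""
    n_rows, n_cols = cost.shape
    best = {"path": None, "cost": np.inf}

    def recurse(col, row, acc, prefix):
        acc += cost[row, col]
        prefix = prefix + (row,)
        if col == n_cols - 1:
            if acc < best["cost"]:
                best["path"], best["cost"] = prefix, acc
            return
        lo, hi = max(row - max_slope, 0), min(row + max_slope, n_rows - 1)
        for nxt in range(lo, hi + 1):
            recurse(col + 1, nxt, acc, prefix)

    for start in range(n_rows):
        recurse(0, start, 0.0, ())
    return np.array(best["path"]), best["cost"]


class TestDpShortestPath:
    @pytest.mark.parametrize("shape,slope", [((6, 5), 1), ((8, 8), 2), ((5, 7), 3)])
    def test_matches_exhaustive_enumeration(self, shape, slope, rng):
        cost = rng.random(shape)  # continuous costs: unique optimum a.s.
        path = seg.dp_shortest_path(cost, slope)
        expected, expected_cost = brute_force_min_path(cost, slope)
        np.testing.assert_array_equal(path, expected)
        got = sum(cost[r, j] for j, r in enumerate(path))
        assert got == pytest.approx(expected_cost)

    def test_single_zero_cost_path_returned_exactly(self):
        # 8 rows x 6 columns, one admissible zero-cost path, all else 1
        cost = np.ones((8, 6))
        zig = [2, 3, 4, 4, 3, 2]
        for j, r in enumerate(zig):
            cost[r, j] = 0.0
        path = seg.dp_shortest_path(cost, max_slope=1)
        np.testing.assert_array_equal(path, zig)
        expected, _ = brute_force_min_path(cost, 1)
        np.testing.assert_array_equal(path, expected)

    def test_uniform_cost_flattest_minimal_depth_path(self):
        path = seg.dp_shortest_path(np.ones((9, 7)), max_slope=2)
        np.testing.assert_array_equal(path, np.zeros(7, dtype=int))

    def test_slope_constraint_respected(self, rng):
        cost = rng.random((20, 15))
        for slope in (1, 2, 4):
            path = seg.dp_shortest_path(cost, slope)
            assert np.all(np.abs(np.diff(path)) <= slope)


class TestSegmentBoundary:
    def test_bright_band_edge_found(self):
        # bright rows 10-30, dark below: boundary at row 30 +- 1
        mip = np.zeros((60, 40))
        mip[10:31, :] = 1.0
        b_mm = seg.segment_dermis_bottom(mip, dz_mm=0.01, search_window_mm=(0.1, 0.5))
        rows = b_mm / 0.01 - 1
        assert np.all(np.abs(rows - 30) <= 1)

    def test_dark_to_bright_polarity(self):
        mip = np.zeros((80, 30))
        mip[50:, :] = 1.0  # bright from row 50 downward
        b_mm = seg.segment_dwat_bottom(mip, dz_mm=0.01, search_window_mm=(0.2, 0.7))
        rows = b_mm / 0.01 - 1
        assert np.all(np.abs(rows - 49) <= 1)

    def test_empty_search_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            seg.segment_dermis_bottom(np.ones((50, 10)), 0.01, (0.3, 0.3))


class TestThicknessAndMasks:
    def _boundaries(self, values_mm, n_cols=10, dz=0.01):
        b = np.array([[v] * n_cols for v in values_mm])
        return seg.LayerBoundaries(
            boundaries_mm=b, dz_mm=dz,
            stack_slow_indices=[np.arange(2) + 2 * i for i in range(len(values_mm))],
        )

    def test_mean_of_four_stack_boundaries(self):
        b = self._boundaries([0.2, 0.2, 0.3, 0.3])
        assert seg.dermis_thickness(b) == pytest.approx(0.25)

    def test_single_stack_linear_boundary(self):
        cols = np.linspace(0.2, 0.4, 21)
        b = seg.LayerBoundaries(cols[None, :], 0.01, [np.arange(4)])
        assert seg.dermis_thickness(b) == pytest.approx(0.3)

    def test_dwat_window_index_arithmetic(self):
        # boundary 0.3 mm, dz 0.01 mm, extension 1 mm -> rows 30..129
        b = self._boundaries([0.3], n_cols=4)
        vol = volume(np.zeros((140, 4, 2)), dz=0.01, flattened=True)
        mask = seg.dwat_window(b, extension_mm=1.0, volume=vol)
        rows = np.nonzero(mask.mask[:, 0, 0])[0]
        assert rows[0] == 30 and rows[-1] == 129 and len(rows) == 100

    def test_dwat_window_clipped_with_warning(self):
        b = self._boundaries([0.3], n_cols=4)
        vol = volume(np.zeros((50, 4, 2)), dz=0.01, flattened=True)
        with pytest.warns(UserWarning, match="clipped"):
            mask = seg.dwat_window(b, extension_mm=1.0, volume=vol)
        assert mask.mask[30:, 0, 0].all()

    def test_dermis_and_dwat_masks_disjoint(self, rng):
        vals = rng.uniform(0.1, 0.4, size=3)
        b = seg.LayerBoundaries(
            np.tile(vals[:, None], (1, 6)), 0.01,
            [np.arange(2) + 2 * i for i in range(3)],
        )
        vol = volume(np.zeros((120, 6, 6)), dz=0.01, flattened=True)
        dermis = seg.dermis_mask(b, vol)
        dwat = seg.dwat_window(b, 0.5, vol)
        assert not np.any(dermis.mask & dwat.mask)

    def test_zero_extension_rejected(self):
        b = self._boundaries([0.3])
        with pytest.raises(ValueError):
            seg.dwat_window(b, extension_mm=0.0, volume=volume(np.zeros((50, 10, 2)), flattened=True))


class TestChainInvariants:
    def test_flatten_split_mip_preserves_global_max(self, rng):
        V = np.zeros((80, 10, 67))
        V[20] = 1.0  # surface plane
        V[30:60] = rng.random((30, 10, 67))
        V[44, 3, 12] = 7.5  # global max, inside tissue
        vol = volume(V, flattened=False)
        surf = seg.detect_surface(vol)
        flat = seg.flatten(vol, surf)
        stacks = seg.split_stacks(flat, 0.5)
        mips = [seg.stack_mip(s) for s in stacks]
        assert max(m.max() for m in mips) == 7.5
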