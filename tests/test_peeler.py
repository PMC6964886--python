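"""Layer masks, peeling, projections and layer statistics."""

import numpy as np
import pytest

from leafpeel import (
    HeightMap,
    ImageStack,
    LayerMask,
    PeelSpec,
    make_layer_mask,
    peel,
    project,
    quantify_layer,
)
from leafpeel.errors import EmptyLayerError
from leafpeel.peeler import full_mask, layer_stats_frame

SHAPE = (12, 16, 16)  # (nz, ny, nx)


def flat_hm(height: float, shape=SHAPE) -> HeightMap:
    ny, nx = shape[1:]
    return HeightMap(np.full((ny, nx), height, np.float32), np.ones((ny, nx), bool), nz=shape[0])


def smooth_random_hm(rng, shape=SHAPE) -> HeightMap:
    ny, nx = shape[1:]
    h = rng.uniform(1.0, shape[0] - 2.0, (ny, nx)).astype(np.float32)
    return HeightMap(h, np.ones((ny, nx), bool), nz=shape[0])


def brute_force_mask(hm: HeightMap, offset: float, depth: float, nz: int) -> np.ndarray:
    """Independent oracle: per-voxel enumeration of ceil(h+o) <= z < ceil(h+o+d)."""
    ny, nx = hm.height.shape
    mask = np.zeros((nz, ny, nx), bool)
    for y in range(ny):
        for x in range(nx):
            lo = int(np.ceil(hm.height[y, x] + offset))
            hi = int(np.ceil(hm.height[y, x] + offset + depth))
            for z in range(max(lo, 0), min(hi, nz)):
                mask[z, y, x] = True
    return mask


class TestMakeLayerMask:
    def test_flat_height_five_depth_three_selects_567(self):
        mask = make_layer_mask(SHAPE, flat_hm(5.0), PeelSpec(0, 3)).mask
        zs = np.where(mask[:, 0, 0])[0]
        np.testing.assert_array_equal(zs, [5, 6, 7])
        assert mask.sum() == 3 * 16 * 16

    def test_layer_beyond_stack_clips_to_empty_without_error(self):
        mask = make_layer_mask(SHAPE, flat_hm(11.0), PeelSpec(2, 3)).mask
        assert mask.sum() == 0

    def test_micrometre_units_use_axial_voxel_size(self):
        # dz = 0.5 um: 1 um offset / 2 um depth -> 2 slices / 4 slices
        mask = make_layer_mask(SHAPE, flat_hm(3.0), PeelSpec(1.0, 2.0, "um"),
                               voxel_size_um=(0.5, 1, 1)).mask
        zs = np.where(mask[:, 4, 4])[0]
        np.testing.assert_array_equal(zs, [5, 6, 7, 8])

    def test_matches_brute_force_enumeration(self, rng):
        hm = smooth_random_hm(rng)
        for offset, depth in [(0, 1), (0.7, 2.3), (2, 3.5), (1.5, 0.4), (9, 5)]:
            got = make_layer_mask(SHAPE, hm, PeelSpec(offset, depth)).mask
            np.testing.assert_array_equal(got, brute_force_mask(hm, offset, depth, SHAPE[0]))

    def test_adjacent_layers_are_disjoint_and_tile(self, rng):
        hm = smooth_random_hm(rng)
        for d1, d2 in [(1, 1), (2.5, 1.5), (0.3, 4.0), (3, 8)]:
            a = make_layer_mask(SHAPE, hm, PeelSpec(0, d1)).mask
            b = make_layer_mask(SHAPE, hm, PeelSpec(d1, d2)).mask
            union = make_layer_mask(SHAPE, hm, PeelSpec(0, d1 + d2)).mask
            assert not (a & b).any()
            np.testing.assert_array_equal(a | b, union)

    def test_increasing_offset_weakly_deepens_mean_selected_z(self, rng):
        hm = smooth_random_hm(rng)
        z = np.arange(SHAPE[0])[:, None, None]
        prev = None
        for offset in [0.0, 1.0, 2.5, 4.0]:
            mask = make_layer_mask(SHAPE, hm, PeelSpec(offset, 3)).mask
            sel = mask.sum(axis=0)
            mean_z = (z * mask).sum(axis=0)[sel > 0] / sel[sel > 0]
            if prev is not None and prev.shape == mean_z.shape:
                assert (mean_z >= prev - 1e-9).all()
            prev = mean_z

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            PeelSpec(0, 0)


class TestPeel:
    def _stack(self, rng):
        vox = rng.integers(0, 100, size=(2, *SHAPE)).astype(np.uint16)
        return ImageStack(vox, ["membrane", "reporter"])

    def test_full_mask_is_identity(self, rng):
        stack = self._stack(rng)
        out = peel(stack, full_mask(SHAPE))
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_empty_mask_zeroes_everything(self, rng):
        out = peel(self._stack(rng), LayerMask(np.zeros(SHAPE, bool)))
        assert out.voxels.sum() == 0

    def test_peeled_total_equals_masked_sum(self, rng):
        stack = self._stack(rng)
        mask = LayerMask(rng.random(SHAPE) > 0.5)
        out = peel(stack, mask)
        for c in range(2):
            assert out.voxels[c].sum() == stack.voxels[c][mask.mask].sum()

    def test_peel_is_idempotent(self, rng):
        stack = self._stack(rng)
        mask = LayerMask(rng.random(SHAPE) > 0.5)
        once = peel(stack, mask)
        twice = peel(once, mask)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            peel(self._stack(rng), LayerMask(np.ones((3, 4, 4), bool)))


class TestProject:
    def test_all_ones_depth_four_sums_to_four(self):
        stack = ImageStack(np.ones((1, *SHAPE), np.float32))
        mask = make_layer_mask(SHAPE, flat_hm(2.0), PeelSpec(0, 4))
        np.testing.assert_array_equal(project(stack, mask, "sum").pixels, 4.0)

    def test_empty_mask_projects_to_zero(self, rng):
        stack = ImageStack(rng.random((1, *SHAPE)).astype(np.float32))
        for method in ("sum", "max"):
            assert project(stack, LayerMask(np.zeros(SHAPE, bool)), method).pixels.sum() == 0

    def test_sum_projection_conserves_masked_total_exactly(self, rng):
        """Integer stacks: sum of projection == sum of masked voxels, exact."""
        for _ in range(25):
            vox = rng.integers(0, 1000, size=(1, *SHAPE)).astype(np.int64)
            mask = LayerMask(rng.random(SHAPE) > rng.random())
            stack = ImageStack(vox)
            proj = project(stack, mask, "sum")
            assert proj.pixels.sum() == vox[0][mask.mask].sum()

    def test_full_mask_sum_equals_classic_z_projection(self, rng):
        vox = rng.integers(0, 50, size=(2, *SHAPE)).astype(np.uint16)
        stack = ImageStack(vox)
        proj = project(stack, full_mask(SHAPE), "sum")
        np.testing.assert_array_equal(proj.pixels, vox.sum(axis=1, dtype=np.int64))

    def test_max_projection_matches_numpy_max(self, rng):
        vox = rng.integers(0, 50, size=(1, *SHAPE)).astype(np.uint16)
        mask = LayerMask(rng.random(SHAPE) > 0.3)
        proj = project(ImageStack(vox), mask, "max")
        expected = np.where(mask.mask[None], vox, 0).max(axis=1)
        np.testing.assert_array_equal(proj.pixels, expected)

    def test_unknown_method_rejected(self, rng):
        stack = ImageStack(np.ones((1, *SHAPE)))
        with pytest.raises(ValueError, match="method"):
            project(stack, full_mask(SHAPE), "median")


class TestQuantify:
    def test_constant_intensity_stats(self):
        vox = np.full((1, *SHAPE), 6.0, np.float32)
        mask = make_layer_mask(SHAPE, flat_hm(3.0), PeelSpec(0, 2))
        stats = quantify_layer(ImageStack(vox), mask, 0)
        n = 2 * 16 * 16
        assert stats.voxel_count == n
        assert stats.total_intensity == pytest.approx(6.0 * n)
        assert stats.mean_intensity == pytest.approx(6.0)

    def test_mean_times_count_equals_total(self, rng):
        vox = rng.random((1, *SHAPE)).astype(np.float32)
        mask = LayerMask(rng.random(SHAPE) > 0.4)
        stats = quantify_layer(ImageStack(vox), mask, 0)
        assert stats.mean_intensity * stats.voxel_count == pytest.approx(stats.total_intensity)

    def test_empty_mask_raises_not_nan(self):
        stack = ImageStack(np.ones((1, *SHAPE)))
        with pytest.raises(EmptyLayerError, match="empty layer"):
            quantify_layer(stack, LayerMask(np.zeros(SHAPE, bool)), 0)

    def test_stats_frame_has_one_row_per_channel(self, rng):
        vox = rng.random((3, *SHAPE)).astype(np.float32)
        df = layer_stats_frame(ImageStack(vox), full_mask(SHAPE), layer_name="epidermis")
        assert list(df["channel"]) == [0, 1, 2]
        assert set(df["layer"]) == {"epidermis"}
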