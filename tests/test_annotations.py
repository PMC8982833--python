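"""Annotation-strength transforms and tumor-size statistics.

Brute-force oracles: per-slice min/max scans for box tightness, flood
fill for component counts, dense angle scans for diameters.
"""

import numpy as np
import pytest
from scipy import ndimage

from thoraseg.annotations import (
    mask_to_points,
    rasterize_boxes,
    transform_to_weak,
    tumor_size,
)
from thoraseg.volume_core import AxialBox, AxialBoxSet

from conftest import grid, random_mask


def brute_force_boxes(m):
    """Oracle: per-slice 4-connected components with min/max extent scans."""
    out = []
    s2 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for k in range(m.shape[2]):
        labels, n = ndimage.label(m[:, :, k], structure=s2)
        for i in range(1, n + 1):
            rr, cc = np.where(labels == i)
            out.append((k, rr.min(), rr.max(), cc.min(), cc.max()))
    return sorted(out)


class TestTransformToWeak:
    def test_empty_mask_gives_empty_set(self):
        assert len(transform_to_weak(grid(np.zeros((8, 8, 8), np.uint8)))) == 0

    def test_single_voxel_tight_box(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[4, 7, 2] = 1
        bs = transform_to_weak(grid(m))
        assert bs.boxes == [AxialBox(2, 4, 4, 7, 7)]

    def test_sphere_boxes_match_brute_force_and_shrink_toward_poles(self, sphere_mask):
        bs = transform_to_weak(sphere_mask)
        got = sorted(
            (b.slice_index, b.row_min, b.row_max, b.col_min, b.col_max) for b in bs
        )
        assert got == brute_force_boxes(sphere_mask.data)
        eq = next(b for b in bs if b.slice_index == 20)
        assert (eq.row_min, eq.row_max, eq.col_min, eq.col_max) == (15, 25, 15, 25)
        widths = {b.slice_index: b.row_max - b.row_min for b in bs}
        ks = sorted(widths)
        assert all(widths[a] <= widths[b] for a, b in zip(ks, ks[1:]) if b <= 20)
        assert all(widths[a] >= widths[b] for a, b in zip(ks, ks[1:]) if a >= 20)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_masks_match_brute_force(self, seed):
        m = random_mask(np.random.default_rng(seed), p=0.15)
        bs = transform_to_weak(grid(m))
        got = sorted(
            (b.slice_index, b.row_min, b.row_max, b.col_min, b.col_max) for b in bs
        )
        assert got == brute_force_boxes(m)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0,1"):
            transform_to_weak(grid(np.full((4, 4, 4), 3)))


class TestRasterize:
    def test_empty_set_gives_zero_volume(self):
        like = grid(np.zeros((8, 8, 8)))
        bs = AxialBoxSet(boxes=[], grid_shape=(8, 8, 8))
        assert rasterize_boxes(bs, like).grid.data.sum() == 0

    def test_inclusive_bounds_area(self):
        like = grid(np.zeros((10, 10, 10)))
        bs = AxialBoxSet(boxes=[AxialBox(3, 1, 2, 4, 6)], grid_shape=(10, 10, 10))
        g = rasterize_boxes(bs, like).grid.data
        assert g.sum() == 6
        assert g[:, :, 3].sum() == 6 and g[1:3, 4:7, 3].all()

    def test_misaligned_grid_rejected(self):
        bs = AxialBoxSet(boxes=[], grid_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="grid"):
            rasterize_boxes(bs, grid(np.zeros((9, 9, 9))))


def box_key(s):
    return sorted(
        (b.slice_index, b.row_min, b.row_max, b.col_min, b.col_max) for b in s
    )


def random_blob_mask(rng, shape=(24, 24, 12), n_blobs=2):
    """Tumor-like mask: a few distant digital ellipsoids (their per-slice
    boxes stay disjoint, the regime weak annotations are defined for)."""
    m = np.zeros(shape, np.uint8)
    centers = [(6, 6, 3), (17, 17, 8)][:n_blobs]
    for c in centers:
        semi = rng.uniform(2, 4, 3)
        idx = np.indices(shape)
        d = sum(((a - cc) / s) ** 2 for a, cc, s in zip(idx, c, semi))
        m |= (d <= 1).astype(np.uint8)
    return m


class TestWeakInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_superset_property_on_noise_masks(self, seed):
        m = random_mask(np.random.default_rng(seed), p=0.12)
        g = grid(m)
        rast = rasterize_boxes(transform_to_weak(g), g).grid
        # boxes always cover the originating mask
        assert np.all(rast.data >= m)

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotence_through_rasterization_on_blob_masks(self, seed):
        m = random_blob_mask(np.random.default_rng(seed))
        g = grid(m)
        bs = transform_to_weak(g)
        rast = rasterize_boxes(bs, g).grid
        assert box_key(transform_to_weak(rast)) == box_key(bs)

    def test_overlapping_component_boxes_merge(self):
        # a staircase component whose tight box swallows a nearby voxel:
        # deriving boxes from the rasterization merges the two components
        m = np.zeros((8, 8, 1), np.uint8)
        for r, c in [(1, 1), (2, 1), (2, 2), (3, 2), (3, 3), (4, 3), (4, 4)]:
            m[r, c, 0] = 1
        m[1, 3, 0] = 1  # separate voxel inside the staircase's box
        g = grid(m)
        bs = transform_to_weak(g)
        assert len(bs) == 2
        merged = transform_to_weak(rasterize_boxes(bs, g).grid)
        assert len(merged) == 1
        rast2 = rasterize_boxes(merged, g).grid
        assert np.all(rast2.data >= m)  # cover never shrinks

    def test_equality_for_filled_rectangles(self):
        m = np.zeros((12, 12, 4), np.uint8)
        m[2:6, 3:9, 1] = 1
        g = grid(m)
        rast = rasterize_boxes(transform_to_weak(g), g).grid
        np.testing.assert_array_equal(rast.data, m)


class TestMaskToPoints:
    def test_single_voxel(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2, 3, 4] = 1
        out = mask_to_points(grid(m)).grid.data
        assert out[2, 3, 4] == 1 and out.sum() == 1

    def test_sphere_center(self, sphere_mask):
        out = mask_to_points(sphere_mask).grid.data
        assert out[20, 20, 20] == 1 and out.sum() == 1

    def test_two_blobs_two_points(self):
        m = np.zeros((20, 20, 20), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        m[12:16, 12:16, 12:16] = 1
        assert mask_to_points(grid(m)).grid.data.sum() == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_point_count_equals_component_count(self, seed):
        m = random_mask(np.random.default_rng(seed), p=0.05)
        _, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
        assert mask_to_points(grid(m)).grid.data.sum() == n

    def test_empty_mask_gives_empty_guidance(self):
        out = mask_to_points(grid(np.zeros((4, 4, 4), np.uint8)))
        assert out.grid.data.sum() == 0 and out.kind == "point"


def oracle_diameters(points_mm, n_angles=3600):
    """Dense-scan oracle: d_long from all pairs, d_short as the minimal
    projection extent over a fine grid of directions."""
    diff = points_mm[:, None, :] - points_mm[None, :, :]
    d_long = float(np.sqrt((diff**2).sum(-1)).max())
    ths = np.linspace(0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(ths), np.sin(ths)], axis=1)
    proj = points_mm @ dirs.T
    d_short = float((proj.max(axis=0) - proj.min(axis=0)).min())
    return d_long, d_short


class TestTumorSize:
    def test_single_voxel_degenerate(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, 2] = 1
        st = tumor_size(grid(m, spacing=(1, 1, 1.5)))
        assert st.volume_cm3 == pytest.approx(1.5e-3)
        assert st.diameter_mm == 0.0

    def test_sphere_diameter_close_to_analytic(self):
        n = 25
        idx = np.indices((n, n, n))
        m = (sum((a - 12) ** 2 for a in idx) <= 100).astype(np.uint8)  # r = 10 vox
        st = tumor_size(grid(m))
        assert st.diameter_mm == pytest.approx(20.0, abs=1.0)

    @pytest.mark.parametrize(
        "shape_fn",
        [
            lambda m: m.__setitem__((slice(5, 25), slice(5, 15), 3), 1),  # 20x10 box
            lambda m: m.__setitem__((slice(4, 9), slice(2, 30), 7), 1),  # 5x28 box
        ],
    )
    def test_rectangle_against_angle_scan_oracle(self, shape_fn):
        m = np.zeros((40, 40, 10), np.uint8)
        shape_fn(m)
        g = grid(m)
        st = tumor_size(g)
        k = int(np.argmax(m.sum(axis=(0, 1))))
        pts = np.argwhere(m[:, :, k]).astype(float)
        d_long, d_short = oracle_diameters(pts)
        assert st.diameter_mm == pytest.approx((d_long + d_short) / 2, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_blobs_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        m = np.zeros((30, 30, 6), np.uint8)
        blob = (r.random((12, 14)) > 0.4).astype(np.uint8)
        m[8 : 8 + 12, 6 : 6 + 14, 2] = blob
        if not m.any():
            return
        g = grid(m, spacing=(0.8, 1.2, 1.0))
        st = tumor_size(g)
        pts = np.argwhere(m[:, :, 2]).astype(float) * np.array([0.8, 1.2])
        d_long, d_short = oracle_diameters(pts)
        assert st.diameter_mm == pytest.approx((d_long + d_short) / 2, abs=0.05)
        assert st.volume_cm3 == pytest.approx(m.sum() * 0.8 * 1.2 * 1.0 / 1000)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            tumor_size(grid(np.zeros((4, 4, 4), np.uint8)))

    def test_measured_on_max_area_slice(self):
        m = np.zeros((20, 20, 5), np.uint8)
        m[5:15, 5:15, 2] = 1  # 10x10 dominant slice
        m[9:11, 9:11, 3] = 1  # small satellite slice
        st = tumor_size(grid(m))
        pts = np.argwhere(m[:, :, 2]).astype(float)
        d_long, d_short = oracle_diameters(pts)
        assert st.diameter_mm == pytest.approx((d_long + d_short) / 2, abs=0.05)
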