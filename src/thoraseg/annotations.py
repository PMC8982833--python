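"""Transforms between annotation strengths.

A strong annotation is a voxel-wise binary tumor mask; a weak annotation
is the set of tight 2D bounding boxes around the tumor on each axial
slice.  The teacher consumes guidance volumes rasterized from either
boxes or per-component centroid points; tumor-size statistics feed the
size-balanced sampling of the training set and the phantom calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_core import (
    AxialBox,
    AxialBoxSet,
    VolumeGrid,
    require_binary,
)

__all__ = [
    "GuidanceVolume",
    "TumorSizeStats",
    "transform_to_weak",
    "rasterize_boxes",
    "mask_to_points",
    "tumor_size",
]

# in-plane 4-connectivity for per-slice components
_STRUCT_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
# 26-connectivity for 3D components
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GuidanceVolume:
    """Binary volume concatenated to the image as the teacher's second channel."""

    grid: VolumeGrid
    kind: str  # "box" | "point"

    def __post_init__(self) -> None:
        if self.kind not in ("box", "point"):
            raise ValueError(f"guidance kind must be 'box' or 'point', got {self.kind!r}")
        require_binary(self.grid, "guidance volume")


@dataclass
class TumorSizeStats:
    """Tumor size summary: volume in cm^3 and RECIST-like mean diameter in mm.

    diameter_mm is the mean of the longest and shortest diameter measured
    on the axial slice of maximal in-plane tumor area, in world space.
    """

    volume_cm3: float
    diameter_mm: float


def transform_to_weak(mask: VolumeGrid) -> AxialBoxSet:
    """Derive the weak annotation from a strong label.

    For every axial slice, each in-slice 4-connected foreground component
    contributes one tight inclusive bounding box; empty slices contribute
    nothing.
    """
    require_binary(mask, "transform_to_weak input")
    m = mask.data.astype(bool)
    boxes: list[AxialBox] = []
    for k in np.flatnonzero(m.any(axis=(0, 1))):
        labels, n = ndimage.label(m[:, :, k], structure=_STRUCT_2D)
        for sl in ndimage.find_objects(labels):
            boxes.append(
                AxialBox(
                    slice_index=int(k),
                    row_min=sl[0].start,
                    row_max=sl[0].stop - 1,
                    col_min=sl[1].start,
                    col_max=sl[1].stop - 1,
                )
            )
    return AxialBoxSet(boxes=boxes, grid_shape=mask.shape, spacing=mask.spacing)


def rasterize_boxes(boxes: AxialBoxSet, like: VolumeGrid) -> GuidanceVolume:
    """Fill the boxes into a binary volume aligned with `like`."""
    if tuple(boxes.grid_shape) != like.shape:
        raise ValueError(
            f"box set indexed against grid {boxes.grid_shape}, "
            f"target grid is {like.shape}"
        )
    out = np.zeros(like.shape, dtype=np.uint8)
    for b in boxes:
        out[b.row_min : b.row_max + 1, b.col_min : b.col_max + 1, b.slice_index] = 1
    return GuidanceVolume(grid=like.with_data(out, normalized=False), kind="box")


def mask_to_points(mask: VolumeGrid) -> GuidanceVolume:
    """One centroid voxel per 26-connected 3D foreground component.

    If a component's centroid rounds to a background voxel (e.g. a
    crescent), the nearest foreground voxel of that component is used.
    An empty mask yields an empty (all-zero) guidance volume.
    """
    require_binary(mask, "mask_to_points input")
    m = mask.data.astype(bool)
    out = np.zeros(mask.shape, dtype=np.uint8)
    labels, n = ndimage.label(m, structure=_STRUCT_3D)
    for i in range(1, n + 1):
        idx = np.argwhere(labels == i)
        c = idx.mean(axis=0)
        v = np.round(c).astype(int)
        if not (labels[tuple(v)] == i):
            d2 = ((idx - c) ** 2).sum(axis=1)
            v = idx[np.argmin(d2)]
        out[tuple(v)] = 1
    return GuidanceVolume(grid=mask.with_data(out, normalized=False), kind="point")


def _max_area_slice(m: np.ndarray) -> int:
    return int(np.argmax(m.sum(axis=(0, 1))))


def _slice_diameters(points_mm: np.ndarray) -> tuple[float, float]:
    """Long/short diameters of a 2D point cloud (voxel centres, mm).

    d_long is the maximal pairwise distance; d_short the minimal width of
    the convex hull over all in-plane directions (rotating-calipers on
    hull edges).  Degenerate clouds (point / collinear) give 0 widths.
    """
    if len(points_mm) == 1:
        return 0.0, 0.0
    pts = points_mm
    if len(pts) > 400:
        # pairwise scan is O(n^2); the hull carries both extremes
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear; fall through with all points
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    d_long = float(dist.max())

    # minimal width: for each candidate edge direction of the hull, the
    # extent along its normal; min over directions.  For robustness (and
    # degenerate hulls) scan directions defined by all point pairs.
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    dirs = diff.reshape(-1, 2)
    dirs = dirs[(dirs**2).sum(1) > 0]
    if len(dirs) == 0:
        return d_long, 0.0
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    normals = np.stack([-dirs[:, 1], dirs[:, 0]], axis=1)
    proj = pts @ normals.T  # (npts, ndirs)
    widths = proj.max(axis=0) - proj.min(axis=0)
    d_short = float(widths.min())
    return d_long, d_short


def tumor_size(mask: VolumeGrid) -> TumorSizeStats:
    """Volume (cm^3) and mean-of-long/short diameter (mm) of a tumor mask.

    The diameter is measured on the axial slice of maximal in-plane area:
    the longest diameter is the maximal pairwise world-space distance
    between foreground voxel centres and the shortest is the minimal
    width of the in-plane point cloud, RECIST-style.
    """
    require_binary(mask, "tumor_size input")
    m = mask.data.astype(bool)
    count = int(m.sum())
    if count == 0:
        raise ValueError("tumor_size requires a non-empty mask")
    volume_cm3 = count * mask.voxel_volume_mm3 / 1000.0
    k = _max_area_slice(m)
    rc = np.argwhere(m[:, :, k]).astype(float)
    rc[:, 0] *= mask.spacing[0]
    rc[:, 1] *= mask.spacing[1]
    d_long, d_short = _slice_diameters(rc)
    return TumorSizeStats(volume_cm3=volume_cm3, diameter_mm=(d_long + d_short) / 2.0)
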