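"""CT preprocessing: clipping, z-score, resampling, teacher and lung crops.

Pipeline order is clip -> zscore -> resample -> crop.  Intensities are
clipped to the CT soft-tissue/bone range [-1024, 1000] HU, standardized
per volume, resampled to an anisotropic 1 x 1 x 1.5 mm grid, then cropped:
a fixed tumor-centred patch for the (guided) teacher, or one crop per
lung for the fully automatic student.  Lung masks come from an external
producer (e.g. the `lungmask` tool) or from the phantom generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_core import VolumeGrid, require_aligned, require_binary

__all__ = [
    "PreprocessConfig",
    "PatchRecord",
    "LungCropRecord",
    "clip_intensities",
    "zscore",
    "resample",
    "crop_teacher_patch",
    "apply_patch_crop",
    "place_patch",
    "crop_lung_halves",
    "apply_lung_crop",
    "stitch_halves",
]


@dataclass
class PreprocessConfig:
    clip_lo: float = -1024.0
    clip_hi: float = 1000.0
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    teacher_patch: tuple[int, int, int] = (128, 128, 128)
    lung_margin: int = 8
    # lung crops are rounded up so each axis divides the student's total
    # downsampling factor 2^levels (4 levels -> 16)
    lung_divisor: int = 16

    def __post_init__(self) -> None:
        if not self.clip_lo < self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if any(p <= 0 or p % 2 for p in self.teacher_patch):
            raise ValueError("teacher_patch dims must be positive even numbers")

    @property
    def pad_value(self) -> float:
        """Background fill for padded planes, before normalization."""
        return self.clip_lo


def clip_intensities(vol: VolumeGrid, cfg: PreprocessConfig) -> VolumeGrid:
    """Clip HU values to [clip_lo, clip_hi]; in-range voxels unchanged."""
    return vol.with_data(np.clip(vol.data, cfg.clip_lo, cfg.clip_hi))


def zscore(vol: VolumeGrid, eps: float = 1e-8) -> VolumeGrid:
    """Per-volume z-score standardization: (x - mean) / max(std, eps).

    Statistics are computed over all voxels of this volume (population
    std).  Refuses to run twice: the returned grid is flagged
    `normalized` and re-normalizing it is an error.
    """
    if vol.normalized:
        raise ValueError("volume is already z-score normalized")
    x = vol.data.astype(np.float64)
    mu = x.mean()
    sd = x.std()
    out = (x - mu) / max(sd, eps)
    return vol.with_data(out.astype(np.float32), normalized=True)


def zscored_value(vol_before: VolumeGrid, value: float, eps: float = 1e-8) -> float:
    """The z-score a given raw intensity maps to, for pad-value bookkeeping."""
    x = vol_before.data.astype(np.float64)
    return float((value - x.mean()) / max(x.std(), eps))


def resample(
    vol: VolumeGrid,
    target_spacing: tuple[float, float, float],
    role: str,
) -> VolumeGrid:
    """Resample to `target_spacing`; trilinear for images, NN for labels.

    Output shape is round(shape * spacing / target) per axis (min 1);
    origin is preserved.  A volume already at the target spacing passes
    through voxel-identically.
    """
    if role not in ("image", "label"):
        raise ValueError(f"role must be 'image' or 'label', got {role!r}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if np.allclose(vol.spacing, target_spacing):
        return vol.with_data(vol.data.copy())
    in_shape = np.array(vol.shape)
    in_sp = np.array(vol.spacing)
    tgt = np.array(target_spacing)
    out_shape = np.maximum(1, np.round(in_shape * in_sp / tgt).astype(int))
    axes = [np.arange(n) * tgt[i] / in_sp[i] for i, n in enumerate(out_shape)]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 1 if role == "image" else 0
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32 if role == "image" else vol.data.dtype),
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="nearest",
    ).reshape(tuple(out_shape))
    return VolumeGrid(
        data=out, spacing=target_spacing, origin=vol.origin, normalized=vol.normalized
    )


def resample_like(vol: VolumeGrid, like: VolumeGrid, role: str) -> VolumeGrid:
    """Resample `vol` onto `like`'s exact grid (shape + spacing).

    Used to map predictions made at the pipeline's working resolution
    back onto the original image grid; NN for labels, trilinear for
    images.
    """
    if role not in ("image", "label"):
        raise ValueError(f"role must be 'image' or 'label', got {role!r}")
    if vol.shape == like.shape and np.allclose(vol.spacing, like.spacing):
        return like.with_data(vol.data.copy(), normalized=vol.normalized)
    axes = [
        np.arange(n) * like.spacing[i] / vol.spacing[i]
        for i, n in enumerate(like.shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 1 if role == "image" else 0
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32 if role == "image" else vol.data.dtype),
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="nearest",
    ).reshape(like.shape)
    return VolumeGrid(
        data=out, spacing=like.spacing, origin=like.origin, normalized=vol.normalized
    )


# ---------------------------------------------------------------------------
# Teacher patch crop


@dataclass
class PatchRecord:
    """Where a teacher patch came from: source slices and padding applied."""

    src_shape: tuple[int, int, int]
    starts: tuple[int, int, int]  # crop start in the source grid
    stops: tuple[int, int, int]  # crop stop (exclusive)
    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]


def _patch_axis(n: int, center: float, size: int) -> tuple[int, int, int, int]:
    """Per-axis crop bounds: centre, shift inward at borders, pad only
    when the volume is smaller than the patch."""
    if n >= size:
        start = int(round(center)) - size // 2
        start = min(max(start, 0), n - size)
        return start, start + size, 0, 0
    pad_total = size - n
    before = pad_total // 2
    return 0, n, before, pad_total - before


def crop_teacher_patch(
    image: VolumeGrid,
    guidance_center: tuple[float, float, float],
    cfg: PreprocessConfig,
    pad_value: float = 0.0,
) -> tuple[VolumeGrid, PatchRecord]:
    """Fixed-size patch centred on the weak annotation's centroid.

    Near a border the window shifts inward; axes shorter than the patch
    are padded symmetrically with `pad_value` (the normalized clip_lo for
    z-scored images, 0 for labels).  The returned record reapplies the
    identical crop to a paired grid and places predictions back.
    """
    center = tuple(float(c) for c in guidance_center)
    if not all(0 <= c <= n - 1 for c, n in zip(center, image.shape)):
        raise ValueError(f"guidance_center {center} outside grid {image.shape}")
    bounds = [_patch_axis(n, c, s) for n, c, s in zip(image.shape, center, cfg.teacher_patch)]
    record = PatchRecord(
        src_shape=image.shape,
        starts=tuple(b[0] for b in bounds),
        stops=tuple(b[1] for b in bounds),
        pad_before=tuple(b[2] for b in bounds),
        pad_after=tuple(b[3] for b in bounds),
    )
    return apply_patch_crop(image, record, pad_value), record


def apply_patch_crop(grid: VolumeGrid, record: PatchRecord, pad_value: float = 0.0) -> VolumeGrid:
    """Apply a recorded patch crop (e.g. to the paired label)."""
    if grid.shape != record.src_shape:
        raise ValueError(f"grid shape {grid.shape} != record source {record.src_shape}")
    sl = tuple(slice(a, b) for a, b in zip(record.starts, record.stops))
    out = grid.data[sl]
    pads = tuple(zip(record.pad_before, record.pad_after))
    if any(p or q for p, q in pads):
        out = np.pad(out, pads, constant_values=pad_value)
    new_origin = tuple(
        o + (s - pb) * sp
        for o, s, pb, sp in zip(grid.origin, record.starts, record.pad_before, grid.spacing)
    )
    return VolumeGrid(
        data=out, spacing=grid.spacing, origin=new_origin, normalized=grid.normalized
    )


def place_patch(
    patch_data: np.ndarray, record: PatchRecord, fill: float = 0.0
) -> np.ndarray:
    """Inverse of the patch crop: embed patch content in a full-size array.

    Padded planes are discarded; everywhere outside the crop is `fill`.
    """
    out = np.full(record.src_shape, fill, dtype=patch_data.dtype)
    inner = tuple(
        slice(pb, pb + (b - a))
        for pb, a, b in zip(record.pad_before, record.starts, record.stops)
    )
    sl = tuple(slice(a, b) for a, b in zip(record.starts, record.stops))
    out[sl] = patch_data[inner]
    return out


# ---------------------------------------------------------------------------
# Per-lung student crops


@dataclass
class LungCropRecord:
    """Offsets of one lung crop for stitching predictions back."""

    src_shape: tuple[int, int, int]
    starts: tuple[int, int, int]
    stops: tuple[int, int, int]
    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]
    side: str  # "left" | "right" in array-x order


def _lung_axis(lo: int, hi: int, n: int, margin: int, divisor: int) -> tuple[int, int, int, int]:
    """Expand [lo, hi) by margin, clamp, then grow to a divisor multiple.

    Growth stays inside the grid where possible; if the whole grid axis
    is shorter than the rounded extent the remainder becomes padding.
    """
    lo = max(0, lo - margin)
    hi = min(n, hi + margin)
    size = hi - lo
    target = -(-size // divisor) * divisor
    grow = target - size
    lo2 = max(0, lo - grow // 2)
    hi2 = min(n, lo2 + target)
    lo2 = max(0, hi2 - target)
    size2 = hi2 - lo2
    pad = target - size2
    return lo2, hi2, pad // 2, pad - pad // 2


def crop_lung_halves(
    image: VolumeGrid,
    lung_mask: VolumeGrid,
    cfg: PreprocessConfig,
    pad_value: float = 0.0,
) -> list[tuple[VolumeGrid, LungCropRecord]]:
    """Split the thorax into two crops, one around each lung.

    The two largest 26-connected components of the lung mask define the
    crops: bounding box + `lung_margin`, clamped to the grid, with each
    axis rounded up to a multiple of `lung_divisor` so the student's
    downsampling path divides evenly.
    """
    require_aligned(image, lung_mask, "image and lung mask")
    require_binary(lung_mask, "lung mask")
    labels, n = ndimage.label(lung_mask.data, structure=np.ones((3, 3, 3)))
    if n < 2:
        raise ValueError(
            f"lung mask has {n} connected component(s); supply a mask with two "
            "lungs (e.g. from the lungmask tool)"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    objs = ndimage.find_objects(labels)
    crops = []
    for lab in keep:
        sl = objs[lab - 1]
        bounds = [
            _lung_axis(s.start, s.stop, nax, cfg.lung_margin, cfg.lung_divisor)
            for s, nax in zip(sl, image.shape)
        ]
        rec = LungCropRecord(
            src_shape=image.shape,
            starts=tuple(b[0] for b in bounds),
            stops=tuple(b[1] for b in bounds),
            pad_before=tuple(b[2] for b in bounds),
            pad_after=tuple(b[3] for b in bounds),
            side="",
        )
        crops.append(rec)
    # order by x centroid: array-x ascending = anatomical right lung first in RAS
    crops.sort(key=lambda r: r.starts[0] + r.stops[0])
    crops[0].side = "left"
    crops[1].side = "right"
    return [(apply_lung_crop(image, rec, pad_value), rec) for rec in crops]


def apply_lung_crop(grid: VolumeGrid, rec: LungCropRecord, pad_value: float = 0.0) -> VolumeGrid:
    sl = tuple(slice(a, b) for a, b in zip(rec.starts, rec.stops))
    out = grid.data[sl]
    pads = tuple(zip(rec.pad_before, rec.pad_after))
    if any(p or q for p, q in pads):
        out = np.pad(out, pads, constant_values=pad_value)
    new_origin = tuple(
        o + (s - pb) * sp
        for o, s, pb, sp in zip(grid.origin, rec.starts, rec.pad_before, grid.spacing)
    )
    return VolumeGrid(
        data=out, spacing=grid.spacing, origin=new_origin, normalized=grid.normalized
    )


def stitch_halves(
    halves: list[tuple[np.ndarray, LungCropRecord]],
    like: VolumeGrid,
) -> VolumeGrid:
    """OR the per-lung binary predictions back onto the full grid.

    A voxel covered by both crops is foreground if either prediction
    marks it; voxels outside every crop are background.
    """
    out = np.zeros(like.shape, dtype=np.uint8)
    for data, rec in halves:
        inner = tuple(
            slice(pb, pb + (b - a))
            for pb, a, b in zip(rec.pad_before, rec.starts, rec.stops)
        )
        sl = tuple(slice(a, b) for a, b in zip(rec.starts, rec.stops))
        out[sl] |= data[inner].astype(np.uint8)
    return VolumeGrid(
        data=out, spacing=like.spacing, origin=like.origin, normalized=False
    )
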