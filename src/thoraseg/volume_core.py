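"""Domain types for 3D CT volumes and axial bounding-box annotations.

All volumes live on a fixed internal grid convention: a right-handed
(x, y, z) array axis order with the third array axis the axial
(cranio-caudal) direction.  NIfTI files are reoriented to this convention
(closest-canonical RAS) on load, so slice indices in :class:`AxialBox`
are unambiguous.  Indexing is 0-based and box bounds are
inclusive-inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FormatError",
    "AlignmentError",
    "VolumeGrid",
    "AxialBox",
    "AxialBoxSet",
    "StrongCase",
    "WeakCase",
    "PseudoCase",
    "read_volume",
    "write_volume",
    "read_boxes",
    "write_boxes",
]


class FormatError(ValueError):
    """A file or payload does not match the expected format."""


class AlignmentError(ValueError):
    """Two grids that must share shape/spacing/origin do not."""


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  Semantics depend on role: HU for raw CT, unitless
        after z-score normalization, {0, 1} for masks, [0, 1] for
        probability maps.
    spacing : tuple of float
        Voxel size in mm along (x, y, axial-z); strictly positive.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    normalized : bool
        Set once z-score normalization has been applied; guards against
        applying it twice.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"VolumeGrid requires a 3D scalar array, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, **kw) -> "VolumeGrid":
        """New grid sharing this grid's geometry but holding `data`."""
        g = replace(self, data=data)
        for k, v in kw.items():
            setattr(g, k, v)
        return g

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())


def aligned(a: VolumeGrid, b: VolumeGrid, *, atol: float = 1e-5) -> bool:
    """True iff two grids share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def require_aligned(a: VolumeGrid, b: VolumeGrid, what: str = "grids") -> None:
    if not aligned(a, b):
        raise AlignmentError(
            f"{what} must be aligned: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing} vs {b.spacing}, origins {a.origin} vs {b.origin}"
        )


def require_binary(g: VolumeGrid, what: str = "mask") -> None:
    if not g.is_binary():
        bad = np.unique(g.data)[:8]
        raise ValueError(f"{what} must contain only {{0,1}}, found values {bad}")


# ---------------------------------------------------------------------------
# Annotations


@dataclass(frozen=True)
class AxialBox:
    """Tight 2D axis-aligned box on one axial slice (inclusive bounds).

    Rows index the first array axis (x), cols the second (y); the slice
    index is along the third (axial) axis.
    """

    slice_index: int
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate box bounds: {self}")

    def valid_for(self, shape: tuple[int, int, int]) -> bool:
        return (
            0 <= self.slice_index < shape[2]
            and 0 <= self.row_min <= self.row_max < shape[0]
            and 0 <= self.col_min <= self.col_max < shape[1]
        )

    @property
    def area_voxels(self) -> int:
        return (self.row_max - self.row_min + 1) * (self.col_max - self.col_min + 1)


@dataclass
class AxialBoxSet:
    """A weak annotation: per-axial-slice 2D boxes indexed against a grid."""

    boxes: list[AxialBox]
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        bad = [b for b in self.boxes if not b.valid_for(self.grid_shape)]
        if bad:
            raise ValueError(
                f"{len(bad)} box(es) out of range for grid {self.grid_shape}: {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)

    def centroid(self) -> tuple[float, float, float] | None:
        """Area-weighted centroid (voxel coords) of the filled boxes.

        Returns None for an empty set.  This is the crop anchor used by
        the tumor-centred teacher patch.
        """
        if not self.boxes:
            return None
        tot = 0.0
        acc = np.zeros(3)
        for b in self.boxes:
            a = b.area_voxels
            acc += a * np.array(
                [(b.row_min + b.row_max) / 2.0, (b.col_min + b.col_max) / 2.0, b.slice_index]
            )
            tot += a
        return tuple(acc / tot)


# ---------------------------------------------------------------------------
# Cases


@dataclass
class StrongCase:
    """A voxel-wise (semantically) annotated CT case."""

    image: VolumeGrid
    mask: VolumeGrid
    case_id: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        require_aligned(self.image, self.mask, "StrongCase image and mask")
        require_binary(self.mask, "StrongCase mask")


@dataclass
class WeakCase:
    """A CT case annotated only with per-slice axial bounding boxes."""

    image: VolumeGrid
    boxes: AxialBoxSet
    case_id: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        if tuple(self.boxes.grid_shape) != self.image.shape:
            raise ValueError(
                f"box set indexed against {self.boxes.grid_shape}, image is {self.image.shape}"
            )


@dataclass
class PseudoCase:
    """A weak case promoted by the teacher's pseudo-semantic mask."""

    image: VolumeGrid
    pseudo_mask: VolumeGrid
    source_boxes: AxialBoxSet
    case_id: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        require_aligned(self.image, self.pseudo_mask, "PseudoCase image and pseudo_mask")
        require_binary(self.pseudo_mask, "PseudoCase pseudo_mask")


# ---------------------------------------------------------------------------
# NIfTI IO


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI volume, reorienting to the internal axis convention.

    The image is brought to nibabel's closest canonical (RAS) orientation
    so that the third array axis is axial.  4D or non-scalar payloads are
    rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {e}") from e
    if img.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D scalar volume, file is {img.ndim}D "
            f"with shape {img.shape}"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return VolumeGrid(data=data, spacing=tuple(zooms), origin=tuple(origin))


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a grid as NIfTI; masks are stored with an integer dtype."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = grid.data
    if grid.is_binary():
        data = data.astype(np.uint8)
    elif not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.int16)
    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Box sidecar JSON


def write_boxes(box_set: AxialBoxSet, path: str | Path) -> None:
    payload = {
        "case_id": box_set.case_id,
        "shape": list(box_set.grid_shape),
        "spacing": list(box_set.spacing),
        "boxes": [
            {
                "slice": b.slice_index,
                "row_min": b.row_min,
                "row_max": b.row_max,
                "col_min": b.col_min,
                "col_max": b.col_max,
            }
            for b in box_set.boxes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_boxes(path: str | Path) -> AxialBoxSet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: malformed box JSON: {e}") from e
    try:
        shape = tuple(int(n) for n in payload["shape"])
        boxes = [
            AxialBox(
                slice_index=int(b["slice"]),
                row_min=int(b["row_min"]),
                row_max=int(b["row_max"]),
                col_min=int(b["col_min"]),
                col_max=int(b["col_max"]),
            )
            for b in payload["boxes"]
        ]
    except (KeyError, TypeError, ValueError) as e:
        raise FormatError(f"{path}: invalid box payload: {e}") from e
    return AxialBoxSet(
        boxes=boxes,
        grid_shape=shape,
        spacing=tuple(payload.get("spacing", (1.0, 1.0, 1.0))),
        case_id=payload.get("case_id", ""),
    )
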