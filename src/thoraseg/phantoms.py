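"""Synthetic thorax phantoms for desk-scale testing of the pipeline.

A phantom is a crude CT look-alike: an elliptical body at soft-tissue
intensity over an air background, two low-intensity lung ellipsoids, and
one or more high-contrast tumor blobs inside the lungs.  Blobs are
spheres perturbed by low-order random radial harmonics so that, unlike
perfect spheres, their axial bounding boxes carry strictly less
information than their masks — preserving the strong/weak distinction
the teacher-student method relies on.  Gaussian noise is added to the
image only; masks are exact.

The size distribution is configurable so cohorts can be calibrated to a
published per-dataset tumor volume/diameter summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import transform_to_weak, tumor_size
from .volume_core import StrongCase, VolumeGrid, WeakCase

__all__ = ["PhantomConfig", "CohortBundle", "generate_phantom", "generate_cohort"]

_AIR_HU = -1024.0


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    lung_intensity: float = -700.0
    body_intensity: float = 0.0
    tumor_intensity: float = 40.0
    noise_sd: float = 20.0
    tumor_count: int = 1
    tumor_radius_range: tuple[float, float] = (4.0, 9.0)  # mm
    diameter_target: tuple[float, float] | None = None  # (mean, sd) mm
    perturb: float = 0.12  # radial harmonic amplitude; 0 -> exact spheres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_count < 1:
            raise ValueError("tumor_count must be >= 1")
        if self.tumor_radius_range[0] <= 0:
            raise ValueError("tumor radius must be positive")
        for v in (self.lung_intensity, self.body_intensity, self.tumor_intensity):
            if not (-1024.0 <= v <= 1000.0):
                raise ValueError("phantom intensities must lie within the CT clip range")


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center_mm, semi_mm):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _blob_mask(shape, spacing, center_mm, r0, rng, perturb) -> np.ndarray:
    """A sphere of radius r0 with a smooth random radial perturbation."""
    # sample harmonics: first and second order terms along random directions
    n_terms = 2
    v = rng.standard_normal((n_terms, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = rng.standard_normal((n_terms, 3))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    a = rng.uniform(-perturb, perturb, n_terms)
    b = rng.uniform(-perturb, perturb, n_terms)

    r_max = r0 * 1.35
    lo = [max(0, int((c - r_max) / s) - 1) for c, s in zip(center_mm, spacing)]
    hi = [min(n, int((c + r_max) / s) + 2) for c, s, n in zip(center_mm, spacing, shape)]
    sub = np.meshgrid(
        *[np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)], indexing="ij"
    )
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(sub, center_mm)))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = [np.where(d > 0, (g - c) / d, 0.0) for g, c in zip(sub, center_mm)]
    factor = np.ones_like(d)
    for t in range(n_terms):
        dot_v = sum(ui * vi for ui, vi in zip(u, v[t]))
        dot_w = sum(ui * wi for ui, wi in zip(u, w[t]))
        factor = factor + a[t] * dot_v + b[t] * (dot_w**2 - 1.0 / 3.0)
    factor = np.clip(factor, 0.72, 1.32)
    inside = d <= r0 * factor
    out = np.zeros(shape, dtype=np.uint8)
    out[tuple(slice(l, h) for l, h in zip(lo, hi))] = inside
    return out


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
    """Generate (image, tumor_mask, lung_mask); bitwise reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    shape, spacing = cfg.shape, cfg.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    center = extent / 2.0

    body = _ellipsoid(shape, spacing, center, extent * np.array([0.46, 0.46, 0.48]))
    lung_semi = extent * np.array([0.16, 0.26, 0.32])
    lung_centers = [
        center + np.array([-0.22 * extent[0], 0.0, 0.0]),
        center + np.array([+0.22 * extent[0], 0.0, 0.0]),
    ]
    lungs = [
        _ellipsoid(shape, spacing, c, lung_semi) for c in lung_centers
    ]
    lung_mask = (lungs[0] | lungs[1]).astype(np.uint8)

    tumor_mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(cfg.tumor_count):
        placed = False
        for _attempt in range(60):
            if cfg.diameter_target is not None:
                mean, sd = cfg.diameter_target
                r0 = max(1.5, rng.normal(mean, sd) / 2.0)
            else:
                r0 = rng.uniform(*cfg.tumor_radius_range)
            r_out = r0 * (1.0 + cfg.perturb * 1.4)
            side = int(rng.integers(0, 2))
            lc = lung_centers[side]
            # margin in normalized ellipsoid coordinates so the blob fits
            margin = r_out / lung_semi
            if np.any(margin >= 0.95):
                continue
            eps = rng.uniform(-1, 1, 3) * (0.95 - margin)
            c = lc + eps * lung_semi
            blob = _blob_mask(shape, spacing, c, r0, rng, cfg.perturb)
            if not blob.any():
                continue
            if (blob & ~lungs[side]).any() or (blob & tumor_mask).any():
                continue
            tumor_mask |= blob
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not fit a tumor inside a lung; reduce tumor_radius_range "
                "or diameter_target relative to the phantom shape"
            )

    image = np.full(shape, _AIR_HU)
    image[body] = cfg.body_intensity
    image[lung_mask.astype(bool)] = cfg.lung_intensity
    image[tumor_mask.astype(bool)] = cfg.tumor_intensity
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, shape)

    mk = lambda d: VolumeGrid(data=d, spacing=spacing, origin=(0.0, 0.0, 0.0))
    return mk(image.astype(np.float32)), mk(tumor_mask), mk(lung_mask)


@dataclass
class CohortBundle:
    """A simulated mixed-supervision cohort.

    Weak cases expose only their derived axial boxes; the underlying
    truth (for scoring pseudo-annotations) and the lung masks are held in
    side tables rather than on the cases themselves.
    """

    strong: list[StrongCase]
    weak: list[WeakCase]
    heldout: list[StrongCase]
    weak_truth: dict[str, VolumeGrid]
    lung_masks: dict[str, VolumeGrid]


def generate_cohort(
    cfg: PhantomConfig,
    n_strong: int,
    n_weak: int,
    seed: int,
    n_heldout: int = 0,
) -> CohortBundle:
    """Simulate a strongly/weakly annotated cohort plus held-out test cases.

    Per-case seeds derive deterministically from the cohort seed.  Strong
    and held-out cases keep their semantic masks; weak cases carry only
    the tight per-slice boxes computed from the (privately retained)
    truth.
    """
    if n_strong < 0 or n_weak < 0 or n_heldout < 0:
        raise ValueError("cohort sizes must be non-negative")
    ss = np.random.SeedSequence(seed)
    total = n_strong + n_weak + n_heldout
    case_seeds = [int(s) % (2**31) for s in ss.generate_state(max(total, 1))]
    strong, weak, heldout = [], [], []
    weak_truth: dict[str, VolumeGrid] = {}
    lung_masks: dict[str, VolumeGrid] = {}

    from dataclasses import replace

    for i in range(total):
        case_cfg = replace(cfg, seed=case_seeds[i])
        image, mask, lungs = generate_phantom(case_cfg)
        if i < n_strong:
            cid = f"strong_{i:03d}"
            strong.append(StrongCase(image=image, mask=mask, case_id=cid, patient_id=cid))
        elif i < n_strong + n_weak:
            cid = f"weak_{i - n_strong:03d}"
            boxes = transform_to_weak(mask)
            boxes.case_id = cid
            weak.append(WeakCase(image=image, boxes=boxes, case_id=cid, patient_id=cid))
            weak_truth[cid] = mask
        else:
            cid = f"test_{i - n_strong - n_weak:03d}"
            heldout.append(StrongCase(image=image, mask=mask, case_id=cid, patient_id=cid))
        lung_masks[cid] = lungs
    return CohortBundle(
        strong=strong,
        weak=weak,
        heldout=heldout,
        weak_truth=weak_truth,
        lung_masks=lung_masks,
    )
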