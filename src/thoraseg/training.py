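"""Two-phase mixed-supervision training.

Phase one trains the guided teacher on the strongly annotated cases: for
each case the weak annotation is derived from the strong label, rasterized
into a guidance channel, and the teacher learns to reproduce the strong
label from (image, guidance).  Phase two applies the trained teacher to
the weakly annotated cases, binarizes its output and stores the results
as pseudo-strong cases.  Phase three trains the fully automatic student
on the union of strong and pseudo-strong cases, per lung half.

Optimization follows the published regime: Adam, Dice loss, physical
batch one with gradients accumulated to a virtual batch, rare tumor
sizes upsampled, best checkpoint selected by lowest validation loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotations as ann
from . import preprocess as pp
from .autograd import Adam, Tensor, dice_loss_t
from .networks import NetConfig, SegNet, build_student, build_teacher
from .volume_core import (
    PseudoCase,
    StrongCase,
    VolumeGrid,
    WeakCase,
    require_aligned,
)

log = logging.getLogger("thoraseg")

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "Checkpoint",
    "TeacherSample",
    "StudentSample",
    "dice_loss",
    "prepare_teacher_sample",
    "prepare_student_samples",
    "train_teacher",
    "pseudo_annotate",
    "train_student",
    "balance_by_size",
    "make_split",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    virtual_batch: int = 8
    physical_batch: int = 1
    max_epochs: int = 350
    seed: int = 0
    loss_smooth: float = 1e-5
    balance: bool = True

    def __post_init__(self) -> None:
        if self.virtual_batch % self.physical_batch:
            raise ValueError("virtual_batch must be a multiple of physical_batch")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class SplitSpec:
    train: list[str]
    val: list[str]
    test: list[str]
    test_fraction: float = 0.15


@dataclass
class Checkpoint:
    """Trained weights plus the config and training log that produced them."""

    net_cfg: NetConfig
    state: list[np.ndarray]
    log: pd.DataFrame
    guidance_kind: str | None = None
    arch: str = "teacher"  # teacher | so | do

    def build(self) -> SegNet:
        net = SegNet(self.net_cfg, seed=0)
        net.load_state(self.state)
        return net


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    import json

    meta = {
        "net_cfg": vars(ckpt.net_cfg),
        "guidance_kind": ckpt.guidance_kind,
        "arch": ckpt.arch,
        "log_columns": list(ckpt.log.columns),
    }
    arrays = {f"p{i}": a for i, a in enumerate(ckpt.state)}
    np.savez(
        path,
        meta=np.array(json.dumps(meta)),
        log=ckpt.log.to_numpy(dtype=np.float64),
        **arrays,
    )


def load_checkpoint(path) -> Checkpoint:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        n = len([k for k in z.files if k.startswith("p")])
        state = [z[f"p{i}"] for i in range(n)]
        logdf = pd.DataFrame(z["log"], columns=meta["log_columns"])
    return Checkpoint(
        net_cfg=NetConfig(**meta["net_cfg"]),
        state=state,
        log=logdf,
        guidance_kind=meta["guidance_kind"],
        arch=meta["arch"],
    )


# ---------------------------------------------------------------------------
# Dice loss (library surface; the graph version lives in autograd)


def dice_loss(prob, target, eps: float = 1e-5) -> float:
    """Soft Dice loss 1 - (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps).

    Accepts aligned VolumeGrids or plain arrays of equal shape.
    """
    if isinstance(prob, VolumeGrid) and isinstance(target, VolumeGrid):
        require_aligned(prob, target, "dice_loss inputs")
        p, g = prob.data, target.data
    else:
        p = np.asarray(prob, dtype=np.float64)
        g = np.asarray(target, dtype=np.float64)
        if p.shape != g.shape:
            raise ValueError(f"dice_loss shape mismatch: {p.shape} vs {g.shape}")
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    num = 2.0 * (p * g).sum() + eps
    den = p.sum() + g.sum() + eps
    return float(1.0 - num / den)


# ---------------------------------------------------------------------------
# Sample preparation


@dataclass
class TeacherSample:
    """A tumor-centred teacher patch: 2-channel input and binary target."""

    case_id: str
    inputs: np.ndarray  # (2, D, H, W): z-scored image + guidance
    target: np.ndarray  # (1, D, H, W)


@dataclass
class StudentSample:
    """One lung-half crop: image input, mask target, size statistic."""

    case_id: str
    inputs: np.ndarray  # (1, D, H, W)
    target: np.ndarray  # (1, D, H, W)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    tumor_volume_cm3: float = 0.0


def _conform_image(image: VolumeGrid, pre_cfg: pp.PreprocessConfig) -> tuple[VolumeGrid, float]:
    """clip -> zscore -> resample; also returns the normalized pad value."""
    clipped = pp.clip_intensities(image, pre_cfg)
    pad = pp.zscored_value(clipped, pre_cfg.pad_value)
    normed = pp.zscore(clipped)
    return pp.resample(normed, pre_cfg.target_spacing, "image"), pad


def _guidance_for(mask_rs: VolumeGrid, kind: str) -> VolumeGrid:
    if kind == "box":
        return ann.rasterize_boxes(ann.transform_to_weak(mask_rs), mask_rs).grid
    if kind == "point":
        return ann.mask_to_points(mask_rs).grid
    raise ValueError(f"guidance_kind must be 'box' or 'point', got {kind!r}")


def _foreground_centroid(g: VolumeGrid) -> tuple[float, float, float] | None:
    idx = np.argwhere(g.data > 0)
    if len(idx) == 0:
        return None
    return tuple(idx.mean(axis=0))


def prepare_teacher_sample(
    case: StrongCase,
    guidance_kind: str,
    pre_cfg: pp.PreprocessConfig,
) -> TeacherSample:
    """Conform a strong case to a guided teacher patch.

    The weak annotation is derived from the strong label on the resampled
    grid; the patch is centred on the centroid of the rasterized boxes
    (the only tumor locator available in the weak regime).
    """
    img_rs, pad = _conform_image(case.image, pre_cfg)
    mask_rs = pp.resample(case.mask, pre_cfg.target_spacing, "label")
    guid = _guidance_for(mask_rs, guidance_kind)
    box_guid = guid if guidance_kind == "box" else _guidance_for(mask_rs, "box")
    center = _foreground_centroid(box_guid)
    if center is None:
        raise ValueError(f"case {case.case_id}: empty mask, cannot centre teacher patch")
    img_patch, rec = pp.crop_teacher_patch(img_rs, center, pre_cfg, pad_value=pad)
    guid_patch = pp.apply_patch_crop(guid, rec, pad_value=0)
    mask_patch = pp.apply_patch_crop(mask_rs, rec, pad_value=0)
    inputs = np.stack(
        [img_patch.data.astype(np.float32), guid_patch.data.astype(np.float32)]
    )
    return TeacherSample(
        case_id=case.case_id,
        inputs=inputs,
        target=mask_patch.data.astype(np.float32)[None],
    )


def prepare_student_samples(
    image: VolumeGrid,
    mask: VolumeGrid,
    lung_mask: VolumeGrid,
    pre_cfg: pp.PreprocessConfig,
) -> list[StudentSample]:
    """Conform one (pseudo-)strong case to two lung-half student samples."""
    img_rs, pad = _conform_image(image, pre_cfg)
    mask_rs = pp.resample(mask, pre_cfg.target_spacing, "label")
    lung_rs = pp.resample(lung_mask, pre_cfg.target_spacing, "label")
    samples = []
    for img_half, rec in pp.crop_lung_halves(img_rs, lung_rs, pre_cfg, pad_value=pad):
        mask_half = pp.apply_lung_crop(mask_rs, rec, pad_value=0)
        vol = (
            float(mask_half.data.sum()) * mask_half.voxel_volume_mm3 / 1000.0
        )
        samples.append(
            StudentSample(
                case_id="",
                inputs=img_half.data.astype(np.float32)[None],
                target=mask_half.data.astype(np.float32)[None],
                spacing=pre_cfg.target_spacing,
                tumor_volume_cm3=vol,
            )
        )
    return samples


def _box_target(mask_channel: np.ndarray, spacing) -> np.ndarray:
    """Axial-box rasterization of a mask, the DO student's second target."""
    m = VolumeGrid(mask_channel.astype(np.uint8), spacing=spacing)
    if not m.data.any():
        return np.zeros_like(mask_channel, dtype=np.float32)
    return (
        ann.rasterize_boxes(ann.transform_to_weak(m), m).grid.data.astype(np.float32)
    )


# ---------------------------------------------------------------------------
# Core loop


def _run_training(
    net: SegNet,
    samples: list,
    targets_of,
    cfg: TrainConfig,
    val_samples: list | None = None,
) -> Checkpoint:
    """Shared Adam + accumulated-gradients loop with val-loss selection.

    `targets_of(sample)` yields one target array per network head; the
    sample loss is the sum of per-head Dice losses.  Gradients are
    averaged over each virtual batch so the effective learning rate does
    not depend on the accumulation count.
    """
    if not samples:
        raise ValueError("training requires at least one sample")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.lr)
    n_heads = net.cfg.out_heads

    def sample_losses(s):
        outs = net.forward_t(Tensor(s.inputs))
        return [
            dice_loss_t(o, t, eps=cfg.loss_smooth) for o, t in zip(outs, targets_of(s))
        ]

    rows = []
    best_val = math.inf
    best_state = net.state()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(samples))
        ep_head = np.zeros(n_heads)
        for start in range(0, len(order), cfg.virtual_batch):
            group = order[start : start + cfg.virtual_batch]
            opt.zero_grad()
            for i in group:
                losses = sample_losses(samples[int(i)])
                # sample loss = sum of head losses; mean over the virtual
                # batch via the backward seed
                for l in losses:
                    l.backward(seed=1.0 / len(group))
                ep_head += [float(l.data) for l in losses]
                if not all(np.isfinite(float(l.data)) for l in losses):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, sample {samples[int(i)].case_id!r}"
                    )
            opt.step()
        ep_head /= len(order)
        train_loss = float(ep_head.sum())
        row = {"epoch": epoch, "train_loss": train_loss}
        for h in range(n_heads):
            row[f"head{h}_loss"] = float(ep_head[h])
        if val_samples:
            v_tot = 0.0
            for s in val_samples:
                v_tot += sum(float(l.data) for l in sample_losses(s))
            val_loss = v_tot / len(val_samples)
            row["val_loss"] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.state()
        rows.append(row)
        log.info(
            "epoch %d train_loss %.4f%s",
            epoch,
            train_loss,
            f" val_loss {row['val_loss']:.4f}" if "val_loss" in row else "",
        )
    if not val_samples:
        best_state = net.state()
    logdf = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["epoch", "train_loss"]
    )
    return Checkpoint(net_cfg=net.cfg, state=best_state, log=logdf)


# ---------------------------------------------------------------------------
# Algorithm phases


def train_teacher(
    cases: list[StrongCase],
    guidance_kind: str,
    net_cfg: NetConfig,
    cfg: TrainConfig,
    pre_cfg: pp.PreprocessConfig | None = None,
    val_cases: list[StrongCase] | None = None,
    prepared: bool = False,
) -> Checkpoint:
    """Train the guided teacher on the strongly annotated dataset.

    Weak annotations are derived from each strong label, rasterized as
    the guidance channel and fed with the image; the Dice loss compares
    the prediction with the strong label.  Returns the checkpoint with
    the lowest validation loss (final weights when no validation cases
    are given).
    """
    if not cases:
        raise ValueError("train_teacher requires a non-empty strong dataset")
    pre_cfg = pre_cfg or pp.PreprocessConfig()
    if prepared:
        samples = list(cases)
        val_samples = list(val_cases) if val_cases else None
    else:
        samples = [prepare_teacher_sample(c, guidance_kind, pre_cfg) for c in cases]
        val_samples = (
            [prepare_teacher_sample(c, guidance_kind, pre_cfg) for c in val_cases]
            if val_cases
            else None
        )
    net = build_teacher(net_cfg, seed=cfg.seed)
    ckpt = _run_training(net, samples, lambda s: [s.target], cfg, val_samples)
    ckpt.guidance_kind = guidance_kind
    ckpt.arch = "teacher"
    return ckpt


def pseudo_annotate(
    teacher: Checkpoint,
    weak_cases: list[WeakCase],
    pre_cfg: pp.PreprocessConfig | None = None,
    threshold: float = 0.5,
) -> list[PseudoCase]:
    """Convert weak cases into pseudo-strong cases with the trained teacher.

    Each case is conformed, the boxes are rasterized into the guidance
    channel, a tumor-centred patch is predicted, binarized at the
    threshold and placed back into the full grid (background elsewhere),
    then resampled onto the case's original grid.  Cases with an empty
    box set cannot be located and are skipped with a warning.
    """
    pre_cfg = pre_cfg or pp.PreprocessConfig()
    net = teacher.build()
    out: list[PseudoCase] = []
    for case in weak_cases:
        if len(case.boxes) == 0:
            log.warning("case %s has no boxes; skipping pseudo-annotation", case.case_id)
            continue
        img_rs, pad = _conform_image(case.image, pre_cfg)
        guid_orig = ann.rasterize_boxes(case.boxes, case.image).grid
        guid_rs = pp.resample(guid_orig, pre_cfg.target_spacing, "label")
        if teacher.guidance_kind == "point":
            # reduce each box component to its centroid point
            guid_in = ann.mask_to_points(guid_rs).grid
        else:
            guid_in = guid_rs
        center = _foreground_centroid(guid_rs)
        img_patch, rec = pp.crop_teacher_patch(img_rs, center, pre_cfg, pad_value=pad)
        guid_patch = pp.apply_patch_crop(guid_in, rec, pad_value=0)
        prob = net.predict(
            np.stack(
                [img_patch.data.astype(np.float32), guid_patch.data.astype(np.float32)]
            )
        )[0]
        pred = (prob >= threshold).astype(np.uint8)
        full = pp.place_patch(pred, rec, fill=0)
        mask_rs = VolumeGrid(
            full, spacing=pre_cfg.target_spacing, origin=img_rs.origin
        )
        mask_orig = pp.resample_like(mask_rs, case.image, "label")
        out.append(
            PseudoCase(
                image=case.image,
                pseudo_mask=case.image.with_data(
                    mask_orig.data.astype(np.uint8), normalized=False
                ),
                source_boxes=case.boxes,
                case_id=case.case_id,
                patient_id=case.patient_id,
            )
        )
    return out


def train_student(
    strong_samples: list[StudentSample],
    pseudo_samples: list[StudentSample],
    arch: str,
    net_cfg: NetConfig,
    cfg: TrainConfig,
    val_samples: list[StudentSample] | None = None,
) -> Checkpoint:
    """Train the fully automatic student on strong + pseudo-strong samples.

    Samples are lung-half crops (see :func:`prepare_student_samples`);
    with `pseudo_samples` empty this is exactly the supervised baseline.
    The SO student optimizes Dice on the tumor head; the DO student adds
    an equally weighted Dice loss between its second head and the axial
    box rasterization of the target mask.
    """
    if arch not in ("so", "do"):
        raise ValueError(f"arch must be 'so' or 'do', got {arch!r}")
    samples = list(strong_samples) + list(pseudo_samples)
    if not samples:
        raise ValueError("train_student requires at least one sample")
    if cfg.balance:
        stats = [
            ann.TumorSizeStats(volume_cm3=s.tumor_volume_cm3, diameter_mm=0.0)
            for s in samples
        ]
        samples = balance_by_size(samples, stats)
    dual = arch == "do"
    net = build_student(net_cfg, dual=dual, seed=cfg.seed)

    if dual:
        cache: dict[int, np.ndarray] = {}

        def targets_of(s):
            key = id(s)
            if key not in cache:
                cache[key] = _box_target(s.target[0], s.spacing)[None]
            return [s.target, cache[key]]

    else:

        def targets_of(s):
            return [s.target]

    ckpt = _run_training(net, samples, targets_of, cfg, val_samples)
    ckpt.arch = arch
    return ckpt


# ---------------------------------------------------------------------------
# Sampling utilities


def balance_by_size(cases: list, stats: list[ann.TumorSizeStats]) -> list:
    """Upsample rare tumor sizes by replication.

    Volumes are binned into quartile bins of the given distribution; each
    case appears ceil(max_bin_count / own_bin_count) times so every bin
    reaches at least the largest bin's count.  Deterministic in input
    order.
    """
    if not cases:
        raise ValueError("balance_by_size requires a non-empty case list")
    if len(cases) != len(stats):
        raise ValueError("one TumorSizeStats required per case")
    vols = np.array([s.volume_cm3 for s in stats], dtype=float)
    edges = np.quantile(vols, [0.25, 0.5, 0.75])
    bins = np.searchsorted(edges, vols, side="left")
    counts = np.bincount(bins, minlength=4)
    max_count = counts.max()
    out = []
    for case, b in zip(cases, bins):
        rep = math.ceil(max_count / counts[b])
        out.extend([case] * rep)
    return out


def make_split(
    case_ids: list[str],
    patient_ids: list[str],
    seed: int,
    test_fraction: float = 0.15,
    val_fraction: float = 0.15,
) -> SplitSpec:
    """Random patient-level train/val/test split.

    `test_fraction` of patients form the test set; `val_fraction` of the
    remainder form the validation set.  All scans of one patient land in
    the same subset; the split is reproducible by seed.
    """
    if len(case_ids) != len(patient_ids):
        raise ValueError("one patient id required per case")
    patients = sorted(set(patient_ids))
    if len(patients) < 3:
        raise ValueError("make_split requires at least 3 patients")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_test = max(1, round(test_fraction * len(patients)))
    n_val = max(1, round(val_fraction * (len(patients) - n_test)))
    test_p = set(order[:n_test])
    val_p = set(order[n_test : n_test + n_val])
    spec = SplitSpec(train=[], val=[], test=[], test_fraction=test_fraction)
    for cid, pid in zip(case_ids, patient_ids):
        (spec.test if pid in test_p else spec.val if pid in val_p else spec.train).append(cid)
    return spec
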