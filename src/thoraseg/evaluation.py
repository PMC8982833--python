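"""Segmentation and object-wise detection metrics, plus full-case inference.

DSC measures voxel-wise overlap; the object-wise metrics treat each
26-connected component as one tumor and apply the >= 25% overlap rule: a
ground-truth object is detected when at least a quarter of its volume is
covered by the prediction, and a predicted object is a true positive
when at least a quarter of it lies on the ground truth.  DSC-TP restricts
the Dice computation to the matched objects, isolating segmentation
quality from detection failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import preprocess as pp
from .volume_core import VolumeGrid, require_aligned, require_binary

__all__ = [
    "MatchTable",
    "EvalReport",
    "dsc",
    "match_objects",
    "dsc_tp",
    "evaluate_case",
    "evaluate_cases",
    "segment_case",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _as_bool(grid, what: str) -> np.ndarray:
    if isinstance(grid, VolumeGrid):
        require_binary(grid, what)
        return grid.data.astype(bool)
    a = np.asarray(grid)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{what} must be binary")
    return a.astype(bool)


def dsc(pred, gt) -> float:
    """Dice similarity coefficient in percent: 100 * 2|P∩G| / (|P|+|G|).

    Defined as 100 when both masks are empty.
    """
    if isinstance(pred, VolumeGrid) and isinstance(gt, VolumeGrid):
        require_aligned(pred, gt, "dsc inputs")
    p = _as_bool(pred, "prediction")
    g = _as_bool(gt, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"dsc shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 100.0
    return 100.0 * 2.0 * int((p & g).sum()) / denom


@dataclass
class MatchTable:
    """Audit trail of the object matching between prediction and GT."""

    n_gt: int
    n_pred: int
    detected_gt: list[int]  # GT labels with >= tau coverage by the prediction
    tp_pred: list[int]  # predicted labels with >= tau coverage by the GT
    gt_coverage: dict[int, float]
    pred_coverage: dict[int, float]
    tau: float

    @property
    def tp(self) -> int:
        return len(self.detected_gt)

    @property
    def fp(self) -> int:
        return self.n_pred - len(self.tp_pred)

    @property
    def fn(self) -> int:
        return self.n_gt - len(self.detected_gt)

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / self.n_gt if self.n_gt else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * len(self.tp_pred) / self.n_pred if self.n_pred else 0.0

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if (r + p) > 0 else 0.0


def match_objects(pred, gt, tau: float = 0.25) -> MatchTable:
    """Object matching under the >= tau fractional-overlap criterion.

    Components are 26-connected.  Coverage is normalized by each object's
    own volume: GT-side coverage drives recall, prediction-side coverage
    drives precision.  The >= comparison is inclusive.
    """
    p = _as_bool(pred, "prediction")
    g = _as_bool(gt, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"match_objects shape mismatch: {p.shape} vs {g.shape}")
    gl, n_gt = ndimage.label(g, structure=_STRUCT_26)
    pl, n_pred = ndimage.label(p, structure=_STRUCT_26)
    gt_cov: dict[int, float] = {}
    detected = []
    for i in range(1, n_gt + 1):
        obj = gl == i
        cov = float((obj & p).sum()) / float(obj.sum())
        gt_cov[i] = cov
        if cov >= tau:
            detected.append(i)
    pred_cov: dict[int, float] = {}
    tp_pred = []
    for i in range(1, n_pred + 1):
        obj = pl == i
        cov = float((obj & g).sum()) / float(obj.sum())
        pred_cov[i] = cov
        if cov >= tau:
            tp_pred.append(i)
    return MatchTable(
        n_gt=n_gt,
        n_pred=n_pred,
        detected_gt=detected,
        tp_pred=tp_pred,
        gt_coverage=gt_cov,
        pred_coverage=pred_cov,
        tau=tau,
    )


def dsc_tp(pred, gt, table: MatchTable) -> float | None:
    """DSC restricted to true-positive objects; None when nothing matched.

    Computed between the union of detected GT objects and the union of
    predicted TP objects, so false-positive blobs and missed tumors do
    not dilute the segmentation-quality estimate.
    """
    p = _as_bool(pred, "prediction")
    g = _as_bool(gt, "ground truth")
    if not table.detected_gt:
        return None
    gl, _ = ndimage.label(g, structure=_STRUCT_26)
    pl, _ = ndimage.label(p, structure=_STRUCT_26)
    g_tp = np.isin(gl, table.detected_gt)
    p_tp = np.isin(pl, table.tp_pred) if table.tp_pred else np.zeros_like(p)
    return dsc(p_tp.astype(np.uint8), g_tp.astype(np.uint8))


# ---------------------------------------------------------------------------
# Reports


@dataclass
class EvalReport:
    """Per-case metrics plus mean +/- std aggregates."""

    per_case: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        cols = ["dsc", "dsc_tp", "f1", "recall", "precision"]
        rows = {}
        for c in cols:
            vals = self.per_case[c].dropna()
            rows[c] = {
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "std": float(vals.std(ddof=0)) if len(vals) else float("nan"),
            }
        return pd.DataFrame(rows).T

    def formatted(self) -> str:
        agg = self.aggregate()
        lines = [f"{m:<10s} {r['mean']:6.2f} ± {r['std']:5.2f}" for m, r in agg.iterrows()]
        return "\n".join(lines)


def evaluate_case(pred, gt, tau: float = 0.25, case_id: str = "") -> dict:
    table = match_objects(pred, gt, tau)
    d_tp = dsc_tp(pred, gt, table)
    return {
        "case_id": case_id,
        "dsc": dsc(pred, gt),
        "dsc_tp": d_tp,
        "tp": table.tp,
        "fp": table.fp,
        "fn": table.fn,
        "recall": table.recall,
        "precision": table.precision,
        "f1": table.f1,
    }


def evaluate_cases(pairs, tau: float = 0.25) -> EvalReport:
    """Evaluate (case_id, pred, gt) triples into an EvalReport.

    Cases where DSC-TP is undefined (no detected objects) carry NaN there
    and are excluded from the DSC-TP aggregate.
    """
    rows = [evaluate_case(p, g, tau, case_id=cid) for cid, p, g in pairs]
    df = pd.DataFrame(rows)
    df["dsc_tp"] = df["dsc_tp"].astype(float)
    return EvalReport(per_case=df)


# ---------------------------------------------------------------------------
# Full-case student inference


def segment_case(
    student,
    image: VolumeGrid,
    lung_mask: VolumeGrid,
    pre_cfg: pp.PreprocessConfig | None = None,
    threshold: float = 0.5,
) -> VolumeGrid:
    """End-to-end automatic segmentation of one raw CT volume.

    Runs the full pipeline — clip, z-score, resample, per-lung cropping,
    student inference on each half, binarization, stitching, and
    nearest-neighbour resampling back — and returns a binary mask aligned
    with the input image.  Voxels outside both lung crops are background.
    """
    from .training import Checkpoint, _conform_image  # local import avoids cycle

    pre_cfg = pre_cfg or pp.PreprocessConfig()
    net = student.build() if isinstance(student, Checkpoint) else student
    img_rs, pad = _conform_image(image, pre_cfg)
    lung_rs = pp.resample(lung_mask, pre_cfg.target_spacing, "label")
    halves = []
    for img_half, rec in pp.crop_lung_halves(img_rs, lung_rs, pre_cfg, pad_value=pad):
        prob = net.predict(img_half.data.astype(np.float32)[None])[0]
        halves.append(((prob >= threshold).astype(np.uint8), rec))
    stitched = pp.stitch_halves(halves, img_rs)
    out = pp.resample_like(stitched, image, "label")
    return image.with_data(out.data.astype(np.uint8), normalized=False)
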