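"""Segmentation evaluation: pixel accuracy, IoU, boundary-F1 and timing.

All metrics treat a slice as a two-class problem (brain / non-brain) and the
"mean" variants (MPA, MIoU, MBF) average the per-class values.  MBF uses a
distance tolerance of 0.75% of the image diagonal.  Conventions for
degenerate inputs (a class absent from both masks scores 1.0; both
boundaries empty scores 1.0; one boundary empty scores 0.0) avoid NaNs and
never trigger on the brain class of the phantom suite.

Average extraction time is AET = T / N seconds per slice; the batch runner
repeats the timing pass (default 5) and averages.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import FabemError
from .preliminary import _as_mask

DEFAULT_TOLERANCE_FRAC = 0.0075
DEFAULT_TIMING_REPEATS = 5


def _pair(pred, gt) -> Tuple[np.ndarray, np.ndarray]:
    pred = _as_mask(pred)
    gt = _as_mask(gt)
    if pred.shape != gt.shape:
        raise FabemError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def class_confusion(pred, gt) -> Tuple[int, int, int, int]:
    """(TP, FP, FN, TN) pixel counts for the brain (foreground) class."""
    pred, gt = _pair(pred, gt)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return tp, fp, fn, tn


def _safe_div(num: float, den: float, empty_value: float = 1.0) -> float:
    return num / den if den > 0 else empty_value


def per_class_pa(pred, gt) -> Tuple[float, float]:
    """(brain recall, background recall); an absent class scores 1.0."""
    tp, fp, fn, tn = class_confusion(pred, gt)
    return _safe_div(tp, tp + fn), _safe_div(tn, tn + fp)


def per_class_iou(pred, gt) -> Tuple[float, float]:
    """(brain IoU, background IoU); an empty union scores 1.0."""
    tp, fp, fn, tn = class_confusion(pred, gt)
    return _safe_div(tp, tp + fp + fn), _safe_div(tn, tn + fn + fp)


def mpa(pred, gt) -> float:
    """Mean pixel accuracy over the two classes."""
    return float(np.mean(per_class_pa(pred, gt)))


def miou(pred, gt) -> float:
    """Mean intersection-over-union over the two classes."""
    return float(np.mean(per_class_iou(pred, gt)))


def boundary_pixels(mask) -> np.ndarray:
    """Inner boundary: foreground pixels 8-adjacent to background or border."""
    mask = _as_mask(mask)
    eroded = ndimage.minimum_filter(mask, size=3, mode="constant", cval=0)
    return mask & ~eroded


def default_tolerance(shape, frac: float = DEFAULT_TOLERANCE_FRAC) -> float:
    """Boundary tolerance in pixels: ``frac`` of the image diagonal."""
    H, W = shape[:2]
    return frac * math.hypot(H, W)


def boundary_f1(pred, gt, theta: float) -> float:
    """Boundary F1 for one class at tolerance ``theta`` (pixels, Euclidean).

    Precision is the fraction of predicted boundary pixels within ``theta``
    of any ground-truth boundary pixel; recall symmetrically.
    """
    if theta <= 0:
        raise FabemError(f"tolerance theta must be > 0, got {theta}")
    pred, gt = _pair(pred, gt)
    pb = boundary_pixels(pred)
    gb = boundary_pixels(gt)
    pb_any, gb_any = bool(pb.any()), bool(gb.any())
    if not pb_any and not gb_any:
        return 1.0
    if pb_any != gb_any:
        return 0.0
    dist_to_gt = ndimage.distance_transform_edt(~gb)
    dist_to_pred = ndimage.distance_transform_edt(~pb)
    precision = float(np.mean(dist_to_gt[pb] <= theta))
    recall = float(np.mean(dist_to_pred[gb] <= theta))
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mean_boundary_f1(pred, gt, theta: Optional[float] = None) -> float:
    """MBF: mean of the brain-class and background-class boundary F1."""
    pred, gt = _pair(pred, gt)
    if theta is None:
        theta = default_tolerance(pred.shape)
    return float(
        np.mean([boundary_f1(pred, gt, theta), boundary_f1(~pred, ~gt, theta)])
    )


def aet(T: float, N: int) -> float:
    """Average extraction time per slice: total seconds / slice count."""
    if N < 1:
        raise FabemError(f"slice count must be >= 1, got {N}")
    if T < 0:
        raise FabemError(f"total time must be >= 0, got {T}")
    return T / N


@dataclass
class MetricsReport:
    """Aggregate evaluation over a batch of (pred, gt) mask pairs."""

    pa_brain: float
    pa_background: float
    iou_brain: float
    iou_background: float
    bf_brain: float
    bf_background: float
    mpa: float
    miou: float
    mbf: float
    n_slices: int
    theta: float
    aet_seconds: Optional[float] = None
    per_slice: List[dict] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "MPA": self.mpa,
            "MIoU": self.miou,
            "MBF": self.mbf,
            "AET": self.aet_seconds,
            "PA_brain": self.pa_brain,
            "PA_background": self.pa_background,
            "IoU_brain": self.iou_brain,
            "IoU_background": self.iou_background,
            "BF_brain": self.bf_brain,
            "BF_background": self.bf_background,
            "n_slices": self.n_slices,
            "theta_pixels": self.theta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({**self.as_dict(), "per_slice": self.per_slice}, fh, indent=2)

    def to_csv(self, path) -> None:
        cols = ["name", "MPA", "MIoU", "MBF", "PA_brain", "IoU_brain", "BF_brain"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            writer.writeheader()
            for row in self.per_slice:
                writer.writerow(row)


def evaluate_batch(
    pairs: Sequence[Tuple],
    theta_frac: float = DEFAULT_TOLERANCE_FRAC,
    names: Optional[Sequence[str]] = None,
    aet_seconds: Optional[float] = None,
) -> MetricsReport:
    """Score a batch of (pred, gt) pairs; per-slice class means, then the
    mean over slices (the averaging order is per-slice first)."""
    if not pairs:
        raise FabemError("cannot evaluate an empty batch")
    rows = []
    for idx, (pred, gt) in enumerate(pairs):
        pred, gt = _pair(pred, gt)
        theta = default_tolerance(pred.shape, theta_frac)
        pa_b, pa_bg = per_class_pa(pred, gt)
        iou_b, iou_bg = per_class_iou(pred, gt)
        bf_b = boundary_f1(pred, gt, theta)
        bf_bg = boundary_f1(~pred, ~gt, theta)
        rows.append(
            {
                "name": names[idx] if names else f"slice_{idx:04d}",
                "PA_brain": pa_b,
                "PA_background": pa_bg,
                "IoU_brain": iou_b,
                "IoU_background": iou_bg,
                "BF_brain": bf_b,
                "BF_background": bf_bg,
                "MPA": (pa_b + pa_bg) / 2,
                "MIoU": (iou_b + iou_bg) / 2,
                "MBF": (bf_b + bf_bg) / 2,
                "theta": theta,
            }
        )
    mean = lambda key: float(np.mean([r[key] for r in rows]))  # noqa: E731
    return MetricsReport(
        pa_brain=mean("PA_brain"),
        pa_background=mean("PA_background"),
        iou_brain=mean("IoU_brain"),
        iou_background=mean("IoU_background"),
        bf_brain=mean("BF_brain"),
        bf_background=mean("BF_background"),
        mpa=mean("MPA"),
        miou=mean("MIoU"),
        mbf=mean("MBF"),
        n_slices=len(rows),
        theta=rows[0]["theta"],
        aet_seconds=aet_seconds,
        per_slice=rows,
    )
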