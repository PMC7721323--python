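"""Segmentation scoring (mean IoU) and inter-scheme area agreement.

The accuracy of a predicted mask against ground truth is summarized by the
mean intersection over union: for each class, IoU = TP / (TP + FP + FN) on
pixel-level classifications pooled over all evaluated images, then averaged
over classes.  Background counts as a class; classes absent from both
prediction and truth (TP + FP + FN = 0) are excluded from the mean rather
than contributing 0/0.

``area_agreement`` quantifies how well two per-image plant-area measurement
series agree (e.g. areas from masks of two different class schemes) as the
R² of an ordinary least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .schemes import ClassScheme, SegmentationMask


@dataclass
class ConfusionAccumulator:
    """Running per-class TP/FP/FN pixel counts over a set of images."""

    scheme: ClassScheme
    tp: np.ndarray = field(init=False)
    fp: np.ndarray = field(init=False)
    fn: np.ndarray = field(init=False)
    n_images: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        k = self.scheme.n_classes
        self.tp = np.zeros(k, dtype=np.int64)
        self.fp = np.zeros(k, dtype=np.int64)
        self.fn = np.zeros(k, dtype=np.int64)

    def add(self, pred: SegmentationMask, truth: SegmentationMask) -> "ConfusionAccumulator":
        """Accumulate one image pair; order of images is irrelevant."""
        if pred.scheme.name != self.scheme.name or truth.scheme.name != self.scheme.name:
            raise ValueError(
                f"scheme mismatch: accumulator {self.scheme.name}, "
                f"pred {pred.scheme.name}, truth {truth.scheme.name}"
            )
        if pred.shape != truth.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
        k = self.scheme.n_classes
        confusion = np.bincount(
            truth.labels.ravel() * k + pred.labels.ravel(), minlength=k * k
        ).reshape(k, k)
        diag = np.diag(confusion)
        self.tp += diag
        self.fp += confusion.sum(axis=0) - diag
        self.fn += confusion.sum(axis=1) - diag
        self.n_images += 1
        return self

    def per_class_iou(self) -> dict[str, float]:
        """IoU per class; NaN for classes absent from prediction and truth."""
        union = self.tp + self.fp + self.fn
        with np.errstate(invalid="ignore"):
            iou = np.where(union > 0, self.tp / np.maximum(union, 1), np.nan)
        return {c: float(iou[i]) for i, c in enumerate(self.scheme.classes)}


def accumulate(
    acc: ConfusionAccumulator, pred: SegmentationMask, truth: SegmentationMask
) -> ConfusionAccumulator:
    """Functional form of :meth:`ConfusionAccumulator.add`."""
    return acc.add(pred, truth)


def mean_iou(acc: ConfusionAccumulator) -> float:
    """Mean over non-absent classes of TP / (TP + FP + FN)."""
    union = acc.tp + acc.fp + acc.fn
    present = union > 0
    if not present.any():
        raise ValueError("mean IoU undefined: no class has any pixels")
    return float((acc.tp[present] / union[present]).mean())


def binary_iou(pred: SegmentationMask, truth: SegmentationMask, class_name: str) -> float:
    """IoU of a single class between two masks (NaN if absent from both)."""
    p = pred.class_pixels(class_name)
    t = truth.class_pixels(class_name)
    union = int((p | t).sum())
    if union == 0:
        return float("nan")
    return int((p & t).sum()) / union


@dataclass(frozen=True)
class AgreementResult:
    """OLS agreement between two paired per-image area series."""

    areas_x: np.ndarray
    areas_y: np.ndarray
    r_squared: float
    slope: float
    intercept: float


def area_agreement(areas_x, areas_y) -> AgreementResult:
    """R² of an ordinary least-squares fit of y on x (untransformed areas)."""
    x = np.asarray(areas_x, dtype=np.float64)
    y = np.asarray(areas_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("area series must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    fit = stats.linregress(x, y)
    return AgreementResult(
        areas_x=x,
        areas_y=y,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
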