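"""Segmentation evaluation: Dice, mean IoU, mean pixel accuracy, accuracy-at-IoU.

``X`` denotes the predicted pixel set, ``Y`` the ground-truth set, ``k`` the
number of classes.  For the leukocyte task k = 2 (background, leukocyte) and
the foreground class is 1.

* Dice = 2|X ∩ Y| / (|X| + |Y|) over the foreground pixels.
* MIoU = mean over classes present in the ground truth of |X ∩ Y| / |X ∪ Y|.
* MPA = mean over classes of the per-class recall (correct pixels of class i
  divided by ground-truth pixels of class i).
* accuracy-at-IoU = fraction of images whose foreground IoU strictly exceeds
  a threshold (0.8 by default).

Two empty foregrounds count as perfect agreement (Dice = IoU = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentationMask",
    "MetricReport",
    "dice",
    "iou",
    "miou",
    "mpa",
    "accuracy_at_iou",
    "evaluate_pairs",
]

FOREGROUND = 1


def _labels(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.labels
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.int64)
    return arr


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class SegmentationMask:
    """Per-pixel class labels."""

    labels: np.ndarray
    num_classes: int = 2

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        if labels.size and labels.max() >= self.num_classes:
            raise ValueError(
                f"label {labels.max()} exceeds num_classes={self.num_classes}"
            )
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be nonnegative")


@dataclass(frozen=True)
class MetricReport:
    """The four summary metrics plus the per-image foreground IoU list."""

    dice: float
    miou: float
    mpa: float
    accuracy: float
    per_image_iou: tuple = ()
    iou_threshold: float = 0.8

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "miou": self.miou,
            "mpa": self.mpa,
            "accuracy": self.accuracy,
            "iou_threshold": self.iou_threshold,
            "per_image_iou": list(self.per_image_iou),
        }


def dice(pred, truth, foreground: int = FOREGROUND) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|) of the foreground class."""
    p = _labels(pred) == foreground
    t = _labels(truth) == foreground
    _check_shapes(p, t)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, t).sum()) / denom


def iou(pred, truth, class_index: int = FOREGROUND) -> float:
    """Intersection over union |X∩Y| / |X∪Y| for one class."""
    p = _labels(pred) == class_index
    t = _labels(truth) == class_index
    _check_shapes(p, t)
    union = int(np.logical_or(p, t).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(p, t).sum()) / union


def miou(pred, truth) -> float:
    """Mean IoU over the classes present in the ground truth."""
    p = _labels(pred)
    t = _labels(truth)
    _check_shapes(p, t)
    classes = np.unique(t)
    return float(np.mean([iou(p, t, int(c)) for c in classes]))


def mpa(pred, truth) -> float:
    """Mean pixel accuracy: per-class recall averaged over ground-truth classes."""
    p = _labels(pred)
    t = _labels(truth)
    _check_shapes(p, t)
    accs = []
    for c in np.unique(t):
        in_class = t == c
        accs.append(int(np.logical_and(p == c, in_class).sum()) / int(in_class.sum()))
    return float(np.mean(accs))


def accuracy_at_iou(pairs, threshold: float = 0.8, foreground: int = FOREGROUND) -> float:
    """Fraction of (pred, truth) pairs whose foreground IoU strictly exceeds
    the threshold."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("accuracy_at_iou requires at least one mask pair")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    hits = sum(1 for p, t in pairs if iou(p, t, foreground) > threshold)
    return hits / len(pairs)


def evaluate_pairs(pairs, iou_threshold: float = 0.8) -> MetricReport:
    """Aggregate report over a list of (pred, truth) mask pairs.

    Dice, MIoU and MPA are computed on the pixel union of all pairs (every
    image weighted by its pixel count); accuracy-at-IoU is per image.
    """
    pairs = [( _labels(p), _labels(t)) for p, t in pairs]
    if not pairs:
        raise ValueError("evaluate_pairs requires at least one mask pair")
    for p, t in pairs:
        _check_shapes(p, t)
    all_p = np.concatenate([p.ravel() for p, _ in pairs])
    all_t = np.concatenate([t.ravel() for _, t in pairs])
    per_image = tuple(iou(p, t) for p, t in pairs)
    return MetricReport(
        dice=dice(all_p, all_t),
        miou=miou(all_p, all_t),
        mpa=mpa(all_p, all_t),
        accuracy=accuracy_at_iou(pairs, iou_threshold),
        per_image_iou=per_image,
        iou_threshold=iou_threshold,
    )
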