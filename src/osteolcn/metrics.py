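"""Segmentation overlap metrics.

Dice score coefficient (DSC) and Jaccard index / intersection-over-union (IoU)
between a prediction ``P`` and a ground truth ``G``::

    DSC = 2|P ∩ G| / (|P| + |G|)
    IoU = |P ∩ G| / |P ∪ G|

Multi-class label maps over {background=0, osteocyte=1, dendrite=2} are scored
per class (one-vs-rest binarisation) plus a mean IoU (mIoU) over a configurable
class set.  By convention an empty-vs-empty comparison scores 1.0 for both
metrics: predicting the absence of an absent class is a perfect prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "dice", "iou", "evaluate_label"]

#: Classes scored by default in mIoU: osteocyte (1) and dendrite (2).
DEFAULT_CLASSES = (1, 2)


@dataclass
class MetricsReport:
    """Per-image segmentation scores.

    ``dice`` is the foreground-union DSC (all non-background pixels pooled into
    a single binary mask before comparison); ``dice_macro`` is the unweighted
    mean of per-class DSCs over the same class set as ``miou``.
    """

    dice: float
    dice_macro: float
    miou: float
    iou_per_class: dict[int, float]
    pixel_counts: dict[int, tuple[int, int]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {"dice": self.dice, "dice_macro": self.dice_macro, "miou": self.miou}
        for cls, value in self.iou_per_class.items():
            out[f"iou_class_{cls}"] = value
        return out


def _check_shapes(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p)
    g = np.asarray(g)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p.astype(bool), g.astype(bool)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice score coefficient between two binary masks.

    Both masks empty returns 1.0.
    """
    p, g = _check_shapes(pred, truth)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union (Jaccard index) between two binary masks.

    Both masks empty returns 1.0.
    """
    p, g = _check_shapes(pred, truth)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def evaluate_label(
    pred: np.ndarray,
    truth: np.ndarray,
    classes: tuple[int, ...] = DEFAULT_CLASSES,
) -> MetricsReport:
    """Score a multi-class label map against a ground-truth label map.

    Parameters
    ----------
    pred, truth
        Integer label maps of equal shape with values in {0, 1, 2}.
    classes
        Class ids entering mIoU and the macro Dice (background excluded by
        default, matching per-class osteocyte/dendrite reporting).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    known = set(np.unique(pred)) | set(np.unique(truth))
    if not set(classes) <= {0, 1, 2}:
        raise ValueError(f"unknown class ids in {classes!r}; expected subset of {{0,1,2}}")
    if not known <= {0, 1, 2}:
        raise ValueError(f"unknown class ids in labels: {sorted(known - {0, 1, 2})}")

    iou_per_class: dict[int, float] = {}
    dice_per_class: dict[int, float] = {}
    counts: dict[int, tuple[int, int]] = {}
    for cls in classes:
        p = pred == cls
        g = truth == cls
        iou_per_class[cls] = iou(p, g)
        dice_per_class[cls] = dice(p, g)
        counts[cls] = (int(p.sum()), int(g.sum()))

    return MetricsReport(
        dice=dice(pred > 0, truth > 0),
        dice_macro=float(np.mean([dice_per_class[c] for c in classes])),
        miou=float(np.mean([iou_per_class[c] for c in classes])),
        iou_per_class=iou_per_class,
        pixel_counts=counts,
    )
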