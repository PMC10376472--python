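"""Overlap metrics, confusion accounting, quality labelling and 2D->3D stacking.

All overlap metrics are computed on pixel/voxel grids (counts, not physically
weighted volumes): images are assumed to have been resampled to a common
in-plane resolution upstream, so counts and areas are proportional.

Conventions
-----------
* A pair of empty masks is perfect agreement on absence: DSC = IoU = 1.0.
  Use :func:`empty_pair` to flag such records so downstream QC can exclude
  them.
* Confusion-matrix polarity follows the QC reading: "positive" means
  *predicted good quality*, "negative" means *predicted bad quality*.  The
  negative detection rate NDR = TN / (TN + FN) is then the fraction of
  actually-bad segmentations that the classifier caught.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QualityLevel",
    "ConfusionCounts",
    "QualityLabel",
    "CUTOFF_2D",
    "CUTOFF_3D",
    "dsc",
    "iou",
    "precision_recall",
    "empty_pair",
    "ndr",
    "label_quality",
    "quality_cutoff",
    "stack_slices",
]

#: Slice-level (2D) DSC cutoff separating good from bad quality.
CUTOFF_2D = 0.7
#: Subject-level (3D) DSC cutoff.
CUTOFF_3D = 0.85


class QualityLevel(str, enum.Enum):
    """Evaluation level: per-slice 2D or reconstructed per-subject 3D."""

    slice2D = "slice2D"
    subject3D = "subject3D"


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of segmentation *instances* (not pixels).

    Polarity: "positive" = predicted good quality, "negative" = predicted
    bad.  Fields are defined by (actual, predicted) pairs:

    * tp: actually good, predicted good
    * fp: actually good, predicted bad  (good segmentation wrongly flagged)
    * tn: actually bad,  predicted bad  (bad segmentation caught by QC)
    * fn: actually bad,  predicted good (bad segmentation that slipped through)

    The actually-bad instances are tn + fn, so NDR = tn/(tn+fn) is the
    detection rate for bad segmentations; it is undefined when tn + fn == 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class QualityLabel:
    value: str  # "good" | "bad"
    level: QualityLevel
    cutoff: float

    @property
    def is_good(self) -> bool:
        return self.value == "good"


def _as_bool(mask: np.ndarray) -> np.ndarray:
    a = np.asarray(mask)
    if a.ndim < 2:
        raise ValueError(f"mask must be at least rank-2, got shape {a.shape}")
    return a.astype(bool, copy=False)


def _check_shapes(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    return p, r


def dsc(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X|+|Y|).

    Returns 1.0 when both masks are empty (agreement on absence).
    """
    p, r = _check_shapes(pred, ref)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    inter = int(np.count_nonzero(p & r))
    return 2.0 * inter / denom


def iou(pred: np.ndarray, ref: np.ndarray) -> float:
    """Intersection over union (Jaccard index); 1.0 for two empty masks."""
    p, r = _check_shapes(pred, ref)
    union = int(np.count_nonzero(p | r))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(p & r))
    return inter / union


def precision_recall(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Pixelwise precision tp/(tp+fp) and recall tp/(tp+fn).

    Each is defined as 1.0 when its denominator is zero (nothing predicted /
    nothing to find).
    """
    p, r = _check_shapes(pred, ref)
    tp = int(np.count_nonzero(p & r))
    n_pred = int(p.sum())
    n_ref = int(r.sum())
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_ref if n_ref else 1.0
    return precision, recall


def empty_pair(pred: np.ndarray, ref: np.ndarray) -> bool:
    """True when neither mask contains any foreground (structure absent)."""
    p, r = _check_shapes(pred, ref)
    return not (p.any() or r.any())


def ndr(c: ConfusionCounts) -> float:
    """Negative detection rate TN / (FN + TN).

    The fraction of actually-bad segmentations flagged as bad.  Undefined
    (raises) when there are no actual-bad instances.
    """
    denom = c.tn + c.fn
    if denom == 0:
        raise ValueError("NDR undefined: no actual-bad instances (tn + fn == 0)")
    return c.tn / denom


def quality_cutoff(level: QualityLevel | str) -> float:
    level = QualityLevel(level)
    return CUTOFF_2D if level is QualityLevel.slice2D else CUTOFF_3D


def label_quality(
    dsc_value: float,
    level: QualityLevel | str,
    cutoff: float | None = None,
) -> QualityLabel:
    """Label a segmentation good/bad by its DSC.

    Bad iff DSC < cutoff; the boundary value is good.  Default cutoffs are
    0.7 at slice level and 0.85 at subject level.
    """
    level = QualityLevel(level)
    if not (0.0 <= dsc_value <= 1.0):
        raise ValueError(f"DSC must be in [0, 1], got {dsc_value}")
    cut = quality_cutoff(level) if cutoff is None else float(cutoff)
    value = "bad" if dsc_value < cut else "good"
    return QualityLabel(value=value, level=level, cutoff=cut)


def stack_slices(slices: list[np.ndarray], z_spacing: float) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reconstruct a 3D mask from an ordered (base -> apex) list of 2D slices.

    Returns the stacked boolean array (slices x rows x cols) and its
    (z, y, x) spacing, taking the in-plane spacing as 1.0 mm.
    """
    if not slices:
        raise ValueError("cannot stack an empty list of slices")
    arrays = [_as_bool(s) for s in slices]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous slice shapes: {sorted(shapes)}")
    if arrays[0].ndim != 2:
        raise ValueError("stack_slices expects 2D slices")
    if z_spacing <= 0:
        raise ValueError(f"z_spacing must be positive, got {z_spacing}")
    return np.stack(arrays, axis=0), (float(z_spacing), 1.0, 1.0)
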