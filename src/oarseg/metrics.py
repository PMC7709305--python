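"""Evaluation metrics: Sørensen–Dice coefficient (plain and TP-weighted),
3D Hausdorff distance, and a contour-complexity score.

Definitions
-----------
SDC = 2*tp / (2*tp + fp + fn) over voxel sets; the soft variant replaces the
counts by sums of probabilities.  The TP-weighted variant scales the true
positive term by a factor w, which amplifies the relative influence of
surface-level errors (fp/fn) for w < 1:

    SDC_w = 2*w*tp / (2*w*tp + fp + fn)

The Hausdorff distance is the larger of the two directed max-min Euclidean
distances between the foreground voxel centers of two masks, measured in
voxel-index units (physical units available via ``spacing``).

Contour complexity is the mean, over axial (z) slices containing foreground,
of contour circumference divided by enclosed area; lower values mean smoother
contours (a disk of radius r scores ~ 2/r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "confusion_counts",
    "sdc",
    "weighted_sdc",
    "soft_weighted_sdc",
    "hausdorff_3d",
    "contour_complexity",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. HD of an empty mask)."""

    def __init__(self, message: str, empty_side: str | None = None):
        super().__init__(message)
        self.empty_side = empty_side


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level confusion counts of a prediction against a reference."""

    tp: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Counts for hard masks, or probability sums for a soft prediction."""
    p = np.asarray(pred, dtype=np.float64)
    r = np.asarray(ref, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    tp = float(np.sum(p * r))
    fp = float(np.sum(p * (1.0 - r)))
    fn = float(np.sum((1.0 - p) * r))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def sdc(pred: np.ndarray, ref: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2tp/(2tp+fp+fn) in [0, 1].

    Accepts hard {0,1} masks or a soft probability map as ``pred``.  When both
    sides are empty the agreement on absence is perfect; this degenerate case
    returns 1.0 with a warning.
    """
    return weighted_sdc(pred, ref, w=1.0)


def weighted_sdc(pred: np.ndarray, ref: np.ndarray, w: float) -> float:
    """TP-weighted Dice 2w*tp/(2w*tp+fp+fn); equals ``sdc`` at w=1."""
    if not w > 0:
        raise ValueError(f"tp weight must be > 0, got {w}")
    c = confusion_counts(pred, ref)
    denom = 2.0 * w * c.tp + c.fp + c.fn
    if denom == 0.0:
        warnings.warn("SDC of two empty masks: defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * w * c.tp / denom


def soft_weighted_sdc(prob: np.ndarray, ref: np.ndarray, w: float = 1.0) -> float:
    """Soft Dice on a probability map (alias emphasising the soft reading)."""
    return weighted_sdc(prob, ref, w=w)


def hausdorff_3d(a: np.ndarray, b: np.ndarray,
                 spacing: tuple[float, float, float] | None = None) -> float:
    """Symmetric Hausdorff distance between two non-empty binary masks.

    max( max_{p in a} min_{q in b} |p-q| , max_{q in b} min_{p in a} |p-q| )
    over foreground voxel centers.  Distances are in voxel-index units unless
    ``spacing`` (mm per axis) is given.
    """
    pa = np.argwhere(np.asarray(a) > 0).astype(np.float64)
    pb = np.argwhere(np.asarray(b) > 0).astype(np.float64)
    if pa.size == 0 or pb.size == 0:
        side = "a" if pa.size == 0 else "b"
        if pa.size == 0 and pb.size == 0:
            side = "both"
        raise UndefinedMetricError(f"Hausdorff undefined: mask {side} empty", empty_side=side)
    if spacing is not None:
        pa = pa * np.asarray(spacing, dtype=np.float64)
        pb = pb * np.asarray(spacing, dtype=np.float64)
    d_ab = cKDTree(pb).query(pa, k=1)[0].max()
    d_ba = cKDTree(pa).query(pb, k=1)[0].max()
    return float(max(d_ab, d_ba))


def contour_complexity(mask: np.ndarray) -> float:
    """Mean over axial slices of (contour circumference / enclosed area).

    Circumference is measured by sub-pixel iso-contouring at level 0.5
    (marching squares); raw pixel-edge counting would systematically
    overestimate perimeters and is not used.  Slices without foreground are
    skipped.  Units: 1/pixel.
    """
    m = np.asarray(mask)
    if not m.any():
        raise UndefinedMetricError("contour complexity undefined for an empty mask")
    scores = []
    for z in range(m.shape[2]):
        sl = m[:, :, z].astype(float)
        area = sl.sum()
        if area == 0:
            continue
        perim = 0.0
        for contour in measure.find_contours(np.pad(sl, 1), 0.5):
            perim += float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))
        scores.append(perim / area)
    return float(np.mean(scores))
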