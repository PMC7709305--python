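"""Training cost functions: soft Dice, TP-weighted soft Dice, and the
combined Dice + Hausdorff cost.

The combined cost is

    cost = (1 - soft_SDC) + HD / (0.33 * x)

where x is the ROI diagonal (the maximum possible Hausdorff distance inside
the crop), so the HD term lives in [0, 1/0.33].  The 0.33 factor keeps the
normalizer from nullifying the HD term's influence.  The printed form of this
cost adds SDC itself; since SDC is maximized while a cost is minimized, the
Dice term is implemented as (1 - soft SDC) so both terms point the same way
(``dice_term="neg_sdc"`` restores the literal reading).  The HD term is
evaluated on the 0.5-binarized prediction and enters as a non-differentiable
penalty: gradients flow through the Dice term only.  A distance-transform
soft surrogate is available via ``soft_hd=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import UndefinedMetricError, hausdorff_3d

__all__ = ["LossSpec", "soft_dice_loss", "soft_dice_grad", "hd_penalty", "combined_loss", "loss_value"]

HD_NORMALIZER_FACTOR = 0.33


@dataclass(frozen=True)
class LossSpec:
    """Selects the training cost.

    kind: 'sdc' (plain soft Dice), 'sdc_weighted' (TP weight ``tp_weight``,
    typically 0.5 or 0.05), or 'sdc_plus_hd' (Dice plus normalized Hausdorff,
    requiring ``roi_diagonal``).
    """

    kind: str = "sdc"
    tp_weight: float = 1.0
    roi_diagonal: float | None = None
    dice_term: str = "one_minus_sdc"  # or "neg_sdc"
    soft_hd: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("sdc", "sdc_weighted", "sdc_plus_hd"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not self.tp_weight > 0:
            raise ValueError("tp_weight must be > 0")
        if self.kind == "sdc_plus_hd" and not (self.roi_diagonal and self.roi_diagonal > 0):
            raise ValueError("sdc_plus_hd requires a positive roi_diagonal")

    @property
    def w(self) -> float:
        return self.tp_weight if self.kind == "sdc_weighted" else 1.0

    @property
    def hd_normalizer(self) -> float:
        """0.33 * ROI diagonal — the divisor of the HD term."""
        if self.roi_diagonal is None:
            raise ValueError("roi_diagonal not set")
        return HD_NORMALIZER_FACTOR * self.roi_diagonal


def _soft_counts(prob: np.ndarray, ref: np.ndarray, w: float, eps: float):
    p = prob.astype(np.float64)
    r = ref.astype(np.float64)
    inter = float(np.sum(p * r))
    num = 2.0 * w * inter
    den = 2.0 * w * inter + float(np.sum(p * (1 - r))) + float(np.sum((1 - p) * r)) + eps
    return p, r, inter, num, den


def soft_dice_loss(prob: np.ndarray, ref: np.ndarray, w: float = 1.0, eps: float = 0.0) -> float:
    """(1 - soft weighted SDC).  ``eps`` stabilises empty-reference batches
    (default 0: no smoothing)."""
    _, _, _, num, den = _soft_counts(prob, ref, w, eps)
    if den == 0.0:
        return 0.0
    return 1.0 - num / den


def soft_dice_grad(prob: np.ndarray, ref: np.ndarray, w: float = 1.0, eps: float = 0.0) -> np.ndarray:
    """Analytic gradient of ``soft_dice_loss`` with respect to each probability.

    With I = sum(p*r), den = 2wI + fp + fn:
      d(sdc)/dp_i = [2*w*r_i*den - num*((2w-2)*r_i + 1)] / den^2
    and the loss gradient is its negative.
    """
    p, r, _, num, den = _soft_counts(prob, ref, w, eps)
    if den == 0.0:
        return np.zeros_like(p)
    dsdc = (2.0 * w * r * den - num * ((2.0 * w - 2.0) * r + 1.0)) / (den * den)
    return -dsdc


def hd_penalty(prob: np.ndarray, ref: np.ndarray, spec: LossSpec) -> float:
    """Normalized Hausdorff term HD/(0.33 x) on the 0.5-binarized prediction.

    An empty binarized prediction has no finite HD; the term is then set to
    its maximum x/(0.33 x) = 1/0.33.  With ``soft_hd`` the max surface
    distance is approximated from the reference's Euclidean distance
    transform weighted by the probabilities (differentiable in spirit, used
    here as a cheaper penalty only).
    """
    binar = (np.asarray(prob) >= 0.5).astype(np.uint8)
    if spec.soft_hd:
        dt = ndimage.distance_transform_edt(ref == 0)
        dt_in = ndimage.distance_transform_edt(ref > 0)
        hd = float(np.max(prob * dt) + np.max((1.0 - prob) * (ref > 0) * dt_in))
        return min(hd, spec.roi_diagonal) / spec.hd_normalizer
    try:
        hd = hausdorff_3d(binar, ref)
    except UndefinedMetricError:
        return spec.roi_diagonal / spec.hd_normalizer  # maximal penalty, flagged by caller
    return hd / spec.hd_normalizer


def combined_loss(prob: np.ndarray, ref: np.ndarray, spec: LossSpec) -> float:
    """Dice term plus normalized HD penalty (kind 'sdc_plus_hd')."""
    if spec.kind != "sdc_plus_hd":
        raise ValueError("combined_loss requires kind='sdc_plus_hd'")
    if spec.dice_term == "neg_sdc":
        dice = -(1.0 - soft_dice_loss(prob, ref, w=1.0))
    else:
        dice = soft_dice_loss(prob, ref, w=1.0)
    return dice + hd_penalty(prob, ref, spec)


def loss_value(prob: np.ndarray, ref: np.ndarray, spec: LossSpec) -> float:
    """Scalar training loss under any LossSpec (used for monitoring)."""
    if spec.kind == "sdc_plus_hd":
        return combined_loss(prob, ref, spec)
    return soft_dice_loss(prob, ref, w=spec.w)
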