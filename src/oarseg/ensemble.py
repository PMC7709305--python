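"""Cut-off based voxel voting over multiple models' binary predictions.

Each of N member predictions marks voxels positive; the ensemble mask keeps a
voxel only when at least ``cutoff`` members agree.  Cut-off 1 is the union,
cut-off N the intersection, and a simple majority (>= 6 of 11 under the
default ensemble size) is the recommended operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ValidationError, validate_binary_mask
from .metrics import UndefinedMetricError, hausdorff_3d, sdc

__all__ = ["vote", "threshold_votes", "majority_cutoff", "sweep_cutoffs",
           "average_probabilities", "SweepResult"]

DEFAULT_ENSEMBLE_SIZE = 11


def vote(preds: Sequence[np.ndarray]) -> np.ndarray:
    """Per-voxel count of positive member predictions (integer VoteMap)."""
    if len(preds) < 1:
        raise ValidationError("need at least one prediction")
    masks = [validate_binary_mask(np.asarray(p), f"prediction {i}") for i, p in enumerate(preds)]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValidationError("all predictions must share one grid shape")
    return np.sum(np.stack(masks, axis=0), axis=0, dtype=np.int32)


def threshold_votes(votes: np.ndarray, cutoff: int, n: int | None = None) -> np.ndarray:
    """Binary mask of voxels with at least ``cutoff`` votes (1 <= cutoff <= N)."""
    n = int(votes.max()) if n is None else int(n)
    if not 1 <= cutoff <= max(n, 1):
        raise ValidationError(f"cutoff {cutoff} out of range [1, {n}]")
    return (votes >= cutoff).astype(np.uint8)


def majority_cutoff(n: int) -> int:
    """Smallest cut-off constituting a strict majority of n members
    (6 for the default 11-model ensemble)."""
    return n // 2 + 1


def average_probabilities(probs: Sequence[np.ndarray], threshold: float = 0.5) -> np.ndarray:
    """Alternative combination rule: threshold the mean probability map."""
    return (np.mean(np.stack(probs, axis=0), axis=0) >= threshold).astype(np.uint8)


@dataclass(frozen=True)
class SweepResult:
    """Per-cutoff ensemble metrics plus the stand-alone member baseline."""

    table: pd.DataFrame  # columns: cutoff, sdc, hd, hd_defined
    standalone_sdc_mean: float
    standalone_sdc_sd: float
    standalone_hd_mean: float
    standalone_hd_sd: float


def sweep_cutoffs(preds: Sequence[np.ndarray], ref: np.ndarray) -> SweepResult:
    """Evaluate every cut-off 1..N against a reference mask.

    At high cut-offs the ensemble mask may be empty; its HD is then undefined
    (flagged, recorded as NaN) and its SDC is 0.  The stand-alone baseline is
    the mean and sample SD of each metric over the N individual predictions.
    """
    ref = validate_binary_mask(np.asarray(ref), "reference")
    if not ref.any():
        raise ValidationError("reference mask is empty")
    votes = vote(preds)
    n = len(preds)
    rows = []
    for cutoff in range(1, n + 1):
        mask = threshold_votes(votes, cutoff, n=n)
        if mask.any():
            rows.append({"cutoff": cutoff, "sdc": sdc(mask, ref),
                         "hd": hausdorff_3d(mask, ref), "hd_defined": True})
        else:
            rows.append({"cutoff": cutoff, "sdc": 0.0, "hd": np.nan, "hd_defined": False})
    solo_sdc = [sdc(np.asarray(p), ref) for p in preds]
    solo_hd = []
    for p in preds:
        try:
            solo_hd.append(hausdorff_3d(np.asarray(p), ref))
        except UndefinedMetricError:
            solo_hd.append(np.nan)
    ddof = 1 if n > 1 else 0
    return SweepResult(
        table=pd.DataFrame(rows),
        standalone_sdc_mean=float(np.mean(solo_sdc)),
        standalone_sdc_sd=float(np.std(solo_sdc, ddof=ddof)),
        standalone_hd_mean=float(np.nanmean(solo_hd)),
        standalone_hd_sd=float(np.nanstd(solo_hd, ddof=ddof) if n > 1 else 0.0),
    )
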