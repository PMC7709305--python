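"""Preprocessing chain: laterality flip, centroid-centered ROI crop, HU
windowing, and normalization.

The chain mirrors the standard setup for gland segmentation networks: a
fixed-size subvolume is cropped around the organ (to bound memory), extreme HU
values are clipped away with a window, and intensities are rescaled to [0, 1]
and mean-centered.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np

from .core import CTVolume, HUWindow, ROISpec, SegCase

__all__ = [
    "flip_lateral",
    "crop_roi",
    "apply_hu_window",
    "normalize",
    "preprocess_case",
]


def flip_lateral(case: SegCase) -> SegCase:
    """Mirror a case along the left-right axis and toggle its laterality.

    Under the anatomical symmetry assumption a right gland flipped left-right
    is usable as an extra left-gland training case (and vice versa).
    """
    flipped = lambda a: np.ascontiguousarray(a[::-1, :, :])
    return case.replace(
        image=case.image.with_voxels(flipped(case.image.voxels)),
        organ_mask=flipped(case.organ_mask),
        body_mask=flipped(case.body_mask),
        laterality="left" if case.laterality == "right" else "right",
    )


def _crop_slices(centroid: np.ndarray, crop_shape: Tuple[int, int, int],
                 vol_shape: Tuple[int, int, int]):
    """Per-axis (source slice, destination slice) for a crop of ``crop_shape``
    centered on the rounded centroid, clipped to the volume."""
    out = []
    for ax in range(3):
        c = int(np.round(centroid[ax]))
        start = c - crop_shape[ax] // 2
        stop = start + crop_shape[ax]
        src_lo, src_hi = max(start, 0), min(stop, vol_shape[ax])
        dst_lo = src_lo - start
        dst_hi = dst_lo + (src_hi - src_lo)
        out.append((slice(src_lo, src_hi), slice(dst_lo, dst_hi)))
    return out


def crop_roi(case: SegCase, spec: ROISpec) -> SegCase:
    """Crop a fixed-size ROI centered on the organ-mask centroid.

    The centroid is rounded to the nearest voxel, making the crop
    deterministic and translation-equivariant.  Where the box extends past the
    volume, the image is padded with the window's lower HU bound (air-like
    relative to the window) and the masks with 0.
    """
    centroid = case.organ_centroid()
    ext = np.ptp(np.argwhere(case.organ_mask > 0), axis=0) + 1
    if np.any(ext > np.asarray(spec.crop_shape)):
        warnings.warn(
            f"organ extent {tuple(int(e) for e in ext)} exceeds crop shape "
            f"{spec.crop_shape} for case {case.case_id!r}; organ will be truncated",
            stacklevel=2)
    pairs = _crop_slices(centroid, spec.crop_shape, case.shape)
    src = tuple(p[0] for p in pairs)
    dst = tuple(p[1] for p in pairs)

    img = np.full(spec.crop_shape, spec.hu_window.lower, dtype=np.float32)
    img[dst] = case.image.voxels[src]
    om = np.zeros(spec.crop_shape, dtype=np.uint8)
    om[dst] = case.organ_mask[src]
    bm = np.zeros(spec.crop_shape, dtype=np.uint8)
    bm[dst] = case.body_mask[src]
    # padding is outside the body, so organ <= body still holds
    return case.replace(image=case.image.with_voxels(img), organ_mask=om, body_mask=bm)


def apply_hu_window(volume: CTVolume, window: HUWindow) -> CTVolume:
    """Clip every voxel into [window.lower, window.upper]."""
    return volume.with_voxels(np.clip(volume.voxels, window.lower, window.upper))


def normalize(volume: CTVolume, window: HUWindow) -> CTVolume:
    """Affinely map window.lower -> 0 and window.upper -> 1, then subtract the
    volume mean so the result is centered on 0.

    The divisor is the window width rather than the per-volume min/max: after
    clipping the two generically coincide, and fixed bounds keep the map
    deterministic for degenerate (e.g. constant) volumes.
    """
    v = (volume.voxels.astype(np.float64) - window.lower) / window.width
    v -= v.mean()
    return volume.with_voxels(v.astype(np.float32))


def preprocess_case(case: SegCase, spec: ROISpec) -> SegCase:
    """Full chain: crop ROI -> HU window -> normalize; masks cropped alongside."""
    cropped = crop_roi(case, spec)
    windowed = apply_hu_window(cropped.image, spec.hu_window)
    normed = normalize(windowed, spec.hu_window)
    return cropped.replace(image=normed)
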