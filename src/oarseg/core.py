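"""Core data model for CT segmentation cases.

The package works on 3D CT volumes in Hounsfield units (HU) paired with binary
masks.  Arrays use the axis convention ``(x, y, z)`` = (left-right,
anterior-posterior, inferior-superior), 0-based voxel indices; the left-right
flip therefore reverses axis 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "CTVolume",
    "HUWindow",
    "ROISpec",
    "SegCase",
    "DEFAULT_CROP_SHAPE",
    "DEFAULT_WINDOW",
    "default_roi_spec",
    "validate_binary_mask",
]

# Default network input (ROI) shapes per organ, in voxels (x, y, z).
DEFAULT_CROP_SHAPE = {"SMG": (64, 64, 32), "PG": (96, 64, 64)}


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


class FormatError(ValueError):
    """A file or array is structurally inconsistent (e.g. shape mismatch)."""


@dataclass(frozen=True)
class HUWindow:
    """A clipping range for HU values, given as center/width.

    ``lower = center - width/2`` and ``upper = center + width/2``.  Windows
    narrow the displayed/learned intensity range to boost soft-tissue contrast.
    """

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValidationError(f"window width must be > 0, got {self.width}")

    @property
    def lower(self) -> float:
        return self.center - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.center + self.width / 2.0

    @classmethod
    def from_bounds(cls, lower: float, upper: float) -> "HUWindow":
        if not upper > lower:
            raise ValidationError(f"window bounds require lower < upper, got ({lower}, {upper})")
        return cls(center=(lower + upper) / 2.0, width=upper - lower)


# Organ default windows: soft-tissue ranges used when no patient-specific
# window is searched.
DEFAULT_WINDOW = {
    "SMG": HUWindow.from_bounds(-75.0, 175.0),
    "PG": HUWindow.from_bounds(-190.0, 310.0),
}


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of HU values with per-axis voxel spacing in mm."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValidationError(f"CTVolume requires a 3D array, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("CTVolume voxels must all be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValidationError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return CTVolume(voxels=voxels, spacing=self.spacing)


def validate_binary_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Check that ``mask`` is a 3D {0,1} array; return it as uint8."""
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ValidationError(f"{name} must be 3D, got ndim={m.ndim}")
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"{name} must contain only 0/1, found values {vals[:5]}")
    return m.astype(np.uint8)


@dataclass(frozen=True)
class ROISpec:
    """Per-organ region-of-interest settings: crop shape and HU window."""

    organ: str
    crop_shape: Tuple[int, int, int]
    hu_window: HUWindow

    def __post_init__(self) -> None:
        if self.organ not in ("SMG", "PG"):
            raise ValidationError(f"organ must be 'SMG' or 'PG', got {self.organ!r}")
        cs = tuple(int(c) for c in self.crop_shape)
        if len(cs) != 3 or any(c <= 0 for c in cs):
            raise ValidationError(f"crop_shape must be 3 positive ints, got {self.crop_shape}")
        object.__setattr__(self, "crop_shape", cs)

    @property
    def roi_diagonal(self) -> float:
        """Euclidean diagonal of the crop box in voxels — the maximum possible
        Hausdorff distance inside the ROI."""
        return float(np.sqrt(sum(c ** 2 for c in self.crop_shape)))


def default_roi_spec(organ: str, crop_shape: Tuple[int, int, int] | None = None,
                     hu_window: HUWindow | None = None) -> ROISpec:
    """Organ defaults: SMG crops 64x64x32 with window (-75, 175); PG crops
    96x64x64 with window (-190, 310)."""
    if organ not in DEFAULT_CROP_SHAPE:
        raise ValidationError(f"unknown organ {organ!r}")
    return ROISpec(
        organ=organ,
        crop_shape=crop_shape or DEFAULT_CROP_SHAPE[organ],
        hu_window=hu_window or DEFAULT_WINDOW[organ],
    )


@dataclass(frozen=True)
class SegCase:
    """A CT volume with its organ and body masks — the unit of training and
    evaluation.

    Invariants: the organ mask is non-empty, binary, and a subset of the
    (binary) body mask; all arrays share one grid.
    """

    image: CTVolume
    organ_mask: np.ndarray
    body_mask: np.ndarray
    organ: str
    laterality: str
    case_id: str = ""

    def __post_init__(self) -> None:
        om = validate_binary_mask(self.organ_mask, "organ_mask")
        bm = validate_binary_mask(self.body_mask, "body_mask")
        if om.shape != self.image.shape or bm.shape != self.image.shape:
            raise FormatError(
                f"mask/image shape mismatch: image {self.image.shape}, "
                f"organ {om.shape}, body {bm.shape}")
        if not om.any():
            raise ValidationError("organ_mask is empty")
        if np.any(om > bm):
            raise ValidationError("organ_mask is not a subset of body_mask")
        if self.organ not in ("SMG", "PG"):
            raise ValidationError(f"organ must be 'SMG' or 'PG', got {self.organ!r}")
        if self.laterality not in ("left", "right"):
            raise ValidationError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        object.__setattr__(self, "organ_mask", om)
        object.__setattr__(self, "body_mask", bm)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.image.shape

    def replace(self, **kw) -> "SegCase":
        return dataclasses.replace(self, **kw)

    def organ_centroid(self) -> np.ndarray:
        """Voxel-space centroid of the organ mask (float, per axis)."""
        return np.mean(np.argwhere(self.organ_mask > 0), axis=0)
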