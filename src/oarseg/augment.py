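"""Data augmentation: traditional (flip / rotation / Gaussian noise) and
domain-specific CT augmentation (elastic deformation + density shifts).

Traditional transforms produce images that are easy to tell apart from real
CT (a scan is never truly flipped or rotated by 90 degrees), whereas the
domain-specific operations aim to stay inside plausible CT anatomy: an
elastic deformation simulates a different anatomy, and constant HU shifts
inside the body and organ contours simulate patient-to-patient density
variation.  Density shifts are in HU, so augmentation operates on raw (or
windowed-but-unnormalized) volumes; the pipeline order is augment first, then
preprocess.

All operations are deterministic given a seeded ``numpy.random.Generator``
and return new, valid cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume, SegCase
from .preprocess import flip_lateral

__all__ = [
    "TraditionalAugParams",
    "DomainAugParams",
    "rng_from_seed",
    "add_gaussian_noise",
    "random_rotate",
    "traditional_augment",
    "elastic_deform",
    "shift_body_density",
    "shift_oar_density",
    "domain_specific_augment",
]


def rng_from_seed(seed: int) -> np.random.Generator:
    """Seeded random stream; identical seeds give identical augmentations."""
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TraditionalAugParams:
    """Traditional augmentation settings: each enabled op fires independently
    with probability ``prob``; Gaussian image noise has mean 0 and
    ``noise_sigma`` HU (default 15)."""

    noise_sigma: float = 15.0
    enable_flip: bool = True
    enable_rotation: bool = True
    enable_noise: bool = True
    prob: float = 0.5
    in_plane_only: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must be in [0, 1]")


@dataclass(frozen=True)
class DomainAugParams:
    """Domain-specific augmentation settings.

    elastic_alpha scales the smoothed displacement field (voxels),
    elastic_sigma is the Gaussian smoothing width of that field, and
    affine_alpha scales a random perturbation of the identity affine.  The
    organ presets are 38 / 3.8 / 3.8 for the SMG and 58 / 5.8 / 5.8 for the
    PG.  Density shifts draw a single N(0, sigma) HU offset for the body
    (sigma 100) and the organ (sigma 30).
    """

    elastic_alpha: float = 38.0
    elastic_sigma: float = 3.8
    affine_alpha: float = 3.8
    body_shift_sigma: float = 100.0
    oar_shift_sigma: float = 30.0

    def __post_init__(self) -> None:
        for name in ("elastic_alpha", "elastic_sigma", "affine_alpha",
                     "body_shift_sigma", "oar_shift_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def for_organ(cls, organ: str) -> "DomainAugParams":
        if organ.upper() == "SMG":
            return cls(elastic_alpha=38.0, elastic_sigma=3.8, affine_alpha=3.8)
        if organ.upper() == "PG":
            return cls(elastic_alpha=58.0, elastic_sigma=5.8, affine_alpha=5.8)
        raise ValueError(f"unknown organ {organ!r}")


def add_gaussian_noise(volume: CTVolume, sigma: float,
                       rng: np.random.Generator) -> CTVolume:
    """Add independent N(0, sigma^2) HU noise per voxel."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    return volume.with_voxels(volume.voxels + rng.normal(0.0, sigma, volume.shape))


def _fill_value(case: SegCase, fill: float | None) -> float:
    return float(case.image.voxels.min()) if fill is None else float(fill)


def _resample_case(case: SegCase, coords, fill: float) -> SegCase:
    """Apply one geometric map to the image (linear) and both masks
    (nearest-neighbour, so they stay binary and organ <= body is kept)."""
    img = ndimage.map_coordinates(case.image.voxels.astype(np.float32), coords,
                                  order=1, mode="constant", cval=fill)
    om = ndimage.map_coordinates(case.organ_mask, coords, order=0,
                                 mode="constant", cval=0)
    bm = ndimage.map_coordinates(case.body_mask, coords, order=0,
                                 mode="constant", cval=0)
    return case.replace(image=case.image.with_voxels(img), organ_mask=om, body_mask=bm)


def random_rotate(case: SegCase, rng: np.random.Generator,
                  angles_deg: tuple[float, float, float] | None = None,
                  in_plane_only: bool = False, fill: float | None = None) -> SegCase:
    """Rotate image and masks by one random 3D rotation about the volume center.

    Euler angles are drawn uniformly on [0, 360) per axis ("rotation in all
    angles"); with ``in_plane_only`` only the axial (z) angle is drawn.  The
    image is interpolated linearly; masks use nearest-neighbour.  Voxels
    rotated in from outside are filled with ``fill`` (default: image minimum)
    for the image and 0 for the masks.
    """
    if angles_deg is None:
        a = rng.uniform(0.0, 360.0, size=3)
        if in_plane_only:
            a[0] = a[1] = 0.0
        angles_deg = tuple(a)
    if all(ang % 360.0 == 0.0 for ang in angles_deg):
        return case
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    rot = rx @ ry @ rz
    center = (np.asarray(case.shape, dtype=np.float64) - 1.0) / 2.0
    grids = np.indices(case.shape, dtype=np.float64)
    rel = grids - center[:, None, None, None]
    coords = np.einsum("ij,j...->i...", rot, rel) + center[:, None, None, None]
    return _resample_case(case, coords, _fill_value(case, fill))


def traditional_augment(case: SegCase, params: TraditionalAugParams,
                        rng: np.random.Generator) -> SegCase:
    """Randomly apply flip, rotation and Gaussian noise (each with its own
    probability); if no enabled operation fires, the draw is repeated so at
    least one always applies."""
    enabled = [params.enable_flip, params.enable_rotation, params.enable_noise]
    if not any(enabled):
        raise ValueError("no traditional augmentation operation enabled")
    while True:
        fire = [e and (rng.random() < params.prob) for e in enabled]
        if any(fire):
            break
    out = case
    if fire[0]:
        out = flip_lateral(out)
    if fire[1]:
        out = random_rotate(out, rng, in_plane_only=params.in_plane_only)
    if fire[2]:
        out = out.replace(image=add_gaussian_noise(out.image, params.noise_sigma, rng))
    return out


def elastic_deform(case: SegCase, alpha: float, sigma: float, affine_alpha: float,
                   rng: np.random.Generator, fill: float | None = None) -> SegCase:
    """Elastic deformation plus a random affine jitter.

    The displacement field is per-axis uniform[-1, 1] white noise, smoothed
    with a Gaussian of width ``sigma`` and scaled by ``alpha``; the affine
    component perturbs the linear part of the identity by
    uniform[-1, 1] * affine_alpha / max(shape).  One field warps the image
    (linear interpolation) and both masks (nearest-neighbour).
    """
    if alpha == 0.0 and affine_alpha == 0.0:
        return case
    shape = case.shape
    disp = [ndimage.gaussian_filter(rng.uniform(-1.0, 1.0, shape), sigma) * alpha
            for _ in range(3)]
    mat = np.eye(3) + rng.uniform(-1.0, 1.0, (3, 3)) * affine_alpha / max(shape)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    grids = np.indices(shape, dtype=np.float64)
    rel = grids - center[:, None, None, None]
    coords = np.einsum("ij,j...->i...", mat, rel) + center[:, None, None, None]
    coords += np.stack(disp)
    return _resample_case(case, coords, _fill_value(case, fill))


def shift_body_density(case: SegCase, sigma: float, rng: np.random.Generator,
                       delta: float | None = None) -> SegCase:
    """Add one N(0, sigma^2) HU constant to every voxel inside the body mask
    (default sigma 100 HU); ``delta`` forces the offset for testing."""
    if delta is None:
        if sigma == 0.0:
            return case
        delta = float(rng.normal(0.0, sigma))
    img = case.image.voxels.astype(np.float64, copy=True)
    img[case.body_mask > 0] += delta
    return case.replace(image=case.image.with_voxels(img))


def shift_oar_density(case: SegCase, sigma: float, rng: np.random.Generator,
                      delta: float | None = None) -> SegCase:
    """As :func:`shift_body_density` but restricted to the organ mask
    (default sigma 30 HU)."""
    if delta is None:
        if sigma == 0.0:
            return case
        delta = float(rng.normal(0.0, sigma))
    img = case.image.voxels.astype(np.float64, copy=True)
    img[case.organ_mask > 0] += delta
    return case.replace(image=case.image.with_voxels(img))


def domain_specific_augment(case: SegCase, params: DomainAugParams,
                            rng: np.random.Generator) -> SegCase:
    """Apply the three domain-specific operations, always and in order:
    elastic deformation, body density shift, organ density shift."""
    out = elastic_deform(case, params.elastic_alpha, params.elastic_sigma,
                         params.affine_alpha, rng)
    out = shift_body_density(out, params.body_shift_sigma, rng)
    out = shift_oar_density(out, params.oar_shift_sigma, rng)
    return out
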