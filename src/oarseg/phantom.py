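"""Synthetic CT phantom generator.

Produces :class:`~oarseg.core.SegCase` objects with the statistical structure
the toolkit assumes about head-and-neck CT: an elliptical body contour filled
with soft-tissue HU, a low-contrast gland-like organ inside it (the salivary
glands sit only ~15 HU above surrounding soft tissue), an optional bone-like
rod and air background, randomized organ shape (a perturbed ellipsoid), and
left/right laterality.  Ground-truth organ and body masks are exact by
construction, so every downstream component can be exercised without any
clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .core import CTVolume, SegCase, ValidationError

__all__ = ["PhantomConfig", "generate_phantom", "generate_cohort"]

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity settings of the phantom.

    Defaults emulate the reported acquisition scale: ~1 mm in-plane spacing
    with 2.5 mm slices, soft tissue around 40 HU, gland tissue around 55 HU
    (15 HU mean contrast, heavily overlapping distributions), cortical-bone
    rod at 700 HU and air at -1000 HU.
    """

    grid_shape: Tuple[int, int, int] = (128, 128, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 2.5)
    body_hu_mean: float = 40.0
    body_hu_sd: float = 15.0
    gland_hu_mean: float = 55.0
    gland_hu_sd: float = 10.0
    # uniform sampling ranges of the gland ellipsoid semi-axes, voxels (x, y, z)
    gland_semiaxes: Tuple[Tuple[float, float], ...] = ((8.0, 14.0), (7.0, 12.0), (4.0, 7.0))
    bone_hu: float = 700.0
    air_hu: float = -1000.0
    noise_sd: float = 5.0
    # gland center offset from the midline, as a fraction of the body x semi-axis
    lateral_offset: float = 0.35
    # amplitude of the smooth radial perturbation of the gland surface
    irregularity: float = 0.3
    include_bone: bool = True
    organ: str = "SMG"

    @classmethod
    def desk_scale(cls, organ: str = "SMG") -> "PhantomConfig":
        """A small grid (32x32x16) for fast end-to-end pipelines and tests."""
        return cls(grid_shape=(32, 32, 16),
                   gland_semiaxes=((3.0, 4.5), (2.5, 4.0), (2.0, 3.0)),
                   organ=organ)


def _ellipsoid_field(shape, center, semiaxes) -> np.ndarray:
    """Implicit ellipsoid function; < 1 inside."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    f = np.zeros(shape, dtype=np.float32)
    for g, c, a in zip(grids, center, semiaxes):
        f += ((g.astype(np.float32) - c) / a) ** 2
    return f


def generate_phantom(config: PhantomConfig, seed: int, laterality: str = "left",
                     case_id: str | None = None) -> SegCase:
    """Generate one phantom case; pure function of (config, seed, laterality).

    The gland is an ellipsoid, offset to the requested side of the midline,
    whose implicit surface is perturbed by a smooth random field so each case
    has its own shape.  The body is filled with N(body_mean, body_sd) HU, the
    gland with N(gland_mean, gland_sd), bone and air are constants, and
    independent Gaussian image noise is added on top.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in config.grid_shape)
    center = np.array([(s - 1) / 2.0 for s in shape])

    body_semi = np.array([0.42 * s for s in shape])
    body = _ellipsoid_field(shape, center, body_semi) < 1.0

    sign = -1.0 if laterality == "left" else 1.0
    semi = np.array([rng.uniform(lo, hi) for lo, hi in config.gland_semiaxes])
    g_center = center.copy()
    g_center[0] += sign * config.lateral_offset * body_semi[0]
    # small positional jitter so the cohort varies in location too
    g_center += rng.uniform(-1.5, 1.5, size=3)

    f = _ellipsoid_field(shape, g_center, semi)
    if config.irregularity > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(shape).astype(np.float32),
                                        sigma=max(2.0, float(semi.min())))
        noise /= max(noise.std(), 1e-9)
        f = f + config.irregularity * noise
    organ = f < 1.0
    if not organ.any():
        raise ValidationError("phantom configuration produced an empty gland")
    if np.any(organ & ~body):
        raise ValidationError("phantom configuration places the gland outside the body")

    image = np.full(shape, config.air_hu, dtype=np.float32)
    image[body] = rng.normal(config.body_hu_mean, config.body_hu_sd, int(body.sum()))
    image[organ] = rng.normal(config.gland_hu_mean, config.gland_hu_sd, int(organ.sum()))

    if config.include_bone:
        rod_r = max(1.5, 0.06 * min(shape[0], shape[1]))
        rod_c = (center[0], center[1] + 0.28 * shape[1])
        xs, ys = np.ogrid[0:shape[0], 0:shape[1]]
        rod = ((xs - rod_c[0]) ** 2 + (ys - rod_c[1]) ** 2) < rod_r ** 2
        rod3 = np.broadcast_to(rod[:, :, None], shape) & body & ~organ
        image[rod3] = config.bone_hu

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, shape)
    np.clip(image, HU_MIN, HU_MAX, out=image)

    return SegCase(
        image=CTVolume(image, spacing=config.spacing),
        organ_mask=organ.astype(np.uint8),
        body_mask=body.astype(np.uint8),
        organ=config.organ,
        laterality=laterality,
        case_id=case_id or f"phantom-{seed:08d}-{laterality[0]}",
    )


def generate_cohort(n: int, config: PhantomConfig, seed: int) -> List[SegCase]:
    """Generate ``n`` independent phantoms with balanced lateralities
    (left/right counts differ by at most 1)."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    cases = []
    for i in range(n):
        lat = "left" if i % 2 == 0 else "right"
        cases.append(generate_phantom(config, int(seeds[i]), laterality=lat,
                                      case_id=f"phantom-{seed}-{i:03d}-{lat[0]}"))
    return cases
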