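"""NIfTI I/O and YAML configuration helpers.

Volumes and masks are exchanged as ``.nii``/``.nii.gz`` files; voxel spacing
is taken from the header zooms.  Masks are written as uint8 {0,1}.
"""

from __future__ import annotations

import os
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .core import (CTVolume, FormatError, HUWindow, ROISpec, SegCase,
                   ValidationError, default_roi_spec)

__all__ = ["read_volume", "write_volume", "read_case", "write_case", "roi_spec_from_yaml"]


def read_volume(path: str | os.PathLike) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=data, spacing=spacing)


def write_volume(volume: CTVolume, path: str | os.PathLike, *, dtype=np.float32) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=dtype), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_case(image_path, organ_mask_path, body_mask_path, organ: str,
              laterality: str, case_id: str = "") -> SegCase:
    """Read an image/organ-mask/body-mask NIfTI triplet into a SegCase.

    All three files must share one grid shape; masks must be binary and the
    organ mask non-empty and contained in the body mask (SegCase invariants).
    """
    image = read_volume(image_path)
    organ_mask = np.asanyarray(nib.load(str(organ_mask_path)).dataobj)
    body_mask = np.asanyarray(nib.load(str(body_mask_path)).dataobj)
    if organ_mask.shape != image.shape or body_mask.shape != image.shape:
        raise FormatError(
            f"grid shape mismatch: image {image.shape}, organ {organ_mask.shape}, "
            f"body {body_mask.shape}")
    if not case_id:
        case_id = os.path.basename(str(image_path)).split(".")[0]
    return SegCase(image=image, organ_mask=organ_mask, body_mask=body_mask,
                   organ=organ, laterality=laterality, case_id=case_id)


def write_case(case: SegCase, out_dir: str | os.PathLike, stem: str | None = None) -> dict:
    """Write a case as three NIfTI files; returns the paths used."""
    os.makedirs(out_dir, exist_ok=True)
    stem = stem or case.case_id or "case"
    paths = {
        "image": os.path.join(out_dir, f"{stem}_image.nii.gz"),
        "organ_mask": os.path.join(out_dir, f"{stem}_organ.nii.gz"),
        "body_mask": os.path.join(out_dir, f"{stem}_body.nii.gz"),
    }
    write_volume(case.image, paths["image"])
    sp = case.image.spacing
    write_volume(CTVolume(case.organ_mask.astype(np.float32), sp), paths["organ_mask"], dtype=np.uint8)
    write_volume(CTVolume(case.body_mask.astype(np.float32), sp), paths["body_mask"], dtype=np.uint8)
    return paths


def roi_spec_from_yaml(path_or_mapping) -> ROISpec:
    """Build an ROISpec from YAML with keys ``organ``, optional ``crop_shape``
    and ``hu_window`` ({center, width} or {lower, upper})."""
    if isinstance(path_or_mapping, Mapping):
        cfg = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    organ = str(cfg["organ"]).upper()
    crop_shape = tuple(cfg["crop_shape"]) if "crop_shape" in cfg else None
    window = None
    if "hu_window" in cfg:
        w = cfg["hu_window"]
        if "center" in w:
            window = HUWindow(center=float(w["center"]), width=float(w["width"]))
        elif "lower" in w:
            window = HUWindow.from_bounds(float(w["lower"]), float(w["upper"]))
        else:
            raise ValidationError("hu_window needs {center,width} or {lower,upper}")
    return default_roi_spec(organ, crop_shape=crop_shape, hu_window=window)
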