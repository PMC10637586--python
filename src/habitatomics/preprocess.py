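"""Loading, geometric resampling and grayscale normalisation.

Axis convention: arrays are indexed (x, y, z) with z the slice axis, all
physical quantities in mm. Images are resampled with a 3rd-order B-spline,
masks with nearest-neighbour (standard radiomics practice; preserves
labels). Grayscale is min-max rescaled to 0-255 over the VOI voxels only,
which keeps habitats comparable across patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Volume", "load_case", "resample", "normalize_grayscale"]


@dataclass
class Volume:
    """A 3D scalar array with spatial metadata (spacing in mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, spacing=tuple(float(z) for z in zooms))


def load_case(image_path: str | Path, mask_path: str | Path) -> tuple[Volume, Volume]:
    """Load an image/mask NIfTI pair and binarise the mask.

    The mask is resampled to the image grid (nearest-neighbour) if the
    grids disagree; any non-zero mask value counts as foreground.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
    image = _load_nifti(image_path)
    mask = _load_nifti(mask_path)
    if mask.data.shape != image.data.shape or not np.allclose(mask.spacing, image.spacing):
        mask = _resample_to(mask, image, nearest=True)
    values = np.unique(mask.data)
    if not np.all(np.isin(values, values.astype(int))):
        raise ValueError(f"mask is not integer-valued: values {values[:10]}")
    binary = (mask.data != 0).astype(np.uint8)
    if binary.sum() == 0:
        raise ValueError("empty VOI: mask contains no foreground voxels")
    mask = Volume(binary, image.spacing, image.origin, image.direction)
    return image, mask


def _sitk_from(vol: Volume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _sitk_to(img, template: Volume | None = None) -> Volume:
    import SimpleITK as sitk

    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(
        data=np.asarray(data, float),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def _resample_one(vol: Volume, target_spacing: Sequence[float], nearest: bool) -> Volume:
    import SimpleITK as sitk

    src = _sitk_from(vol)
    in_size = np.asarray(vol.data.shape, float)
    in_spacing = np.asarray(vol.spacing, float)
    out_spacing = np.asarray(target_spacing, float)
    out_size = np.maximum(1, np.round(in_size * in_spacing / out_spacing)).astype(int)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(out_spacing))
    res.SetSize([int(n) for n in out_size])
    res.SetOutputOrigin(src.GetOrigin())
    res.SetOutputDirection(src.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if nearest else sitk.sitkBSpline)
    return _sitk_to(res.Execute(src))


def _resample_to(vol: Volume, template: Volume, nearest: bool) -> Volume:
    import SimpleITK as sitk

    src = _sitk_from(vol)
    ref = _sitk_from(template)
    res = sitk.Resample(
        src, ref, sitk.Transform(), sitk.sitkNearestNeighbor if nearest else sitk.sitkBSpline
    )
    return _sitk_to(res)


def resample(
    volume: Volume,
    mask: Volume,
    target_spacing: Sequence[float] = (1.0, 1.0, 3.0),
) -> tuple[Volume, Volume]:
    """Resample an image/mask pair to ``target_spacing`` (mm).

    Image: 3rd-order B-spline; mask: nearest-neighbour. No-op when the
    input is already on the target grid. Raises if resampling empties the
    mask.
    """
    if np.allclose(volume.spacing, target_spacing) and np.allclose(
        mask.spacing, target_spacing
    ):
        return volume, mask
    out_vol = _resample_one(volume, target_spacing, nearest=False)
    out_mask = _resample_one(mask, target_spacing, nearest=True)
    out_mask.data = (out_mask.data != 0).astype(np.uint8)
    if out_mask.data.sum() == 0:
        raise ValueError("resampling emptied the mask; target spacing too coarse")
    return out_vol, out_mask


def normalize_grayscale(
    volume: Volume, mask: Volume, out_range: tuple[float, float] = (0.0, 255.0)
) -> Volume:
    """Min-max rescale VOI grayscale to ``out_range`` (default 0-255).

    The min/max are computed over mask voxels only and applied to the
    whole array inside the mask; voxels outside the mask are untouched.
    A constant region maps to the lower bound.
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty VOI: cannot normalise")
    vals = volume.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = volume.data.astype(float).copy()
    if hi == lo:
        out[m] = out_range[0]
    else:
        out[m] = out_range[0] + (out[m] - lo) * (out_range[1] - out_range[0]) / (hi - lo)
    return Volume(out, volume.spacing, volume.origin, volume.direction)
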