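"""Image filters producing the derived images features are extracted from.

Two filter banks: Laplacian-of-Gaussian at a set of mm scales (edge /
blob enhancement at increasing coarseness) and a single-level undecimated
3D wavelet decomposition (8 sub-bands, low/high-pass per axis).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["log_image", "wavelet_images", "filter_images"]


def log_image(data: np.ndarray, sigma_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Laplacian of Gaussian at scale ``sigma_mm`` (converted to voxels)."""
    if sigma_mm <= 0:
        raise ValueError("LoG sigma must be > 0")
    sigma_vox = [sigma_mm / s for s in spacing]
    return ndimage.gaussian_laplace(np.asarray(data, float), sigma=sigma_vox)


_SUBBAND = {"a": "L", "d": "H"}


def wavelet_images(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Level-1 stationary (undecimated) 3D wavelet transform: 8 sub-bands.

    Sub-bands are named LLL..HHH (low/high per axis). Input is edge-padded
    to even dimensions as required by the stationary transform and cropped
    back afterwards.
    """
    data = np.asarray(data, float)
    pad = [(0, s % 2) for s in data.shape]
    padded = np.pad(data, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out: dict[str, np.ndarray] = {}
    crop = tuple(slice(0, s) for s in data.shape)
    for key, band in coeffs.items():
        name = "".join(_SUBBAND[c] for c in key)
        out[f"wavelet-{name}"] = band[crop]
    return out


def filter_images(
    data: np.ndarray,
    spacing: Sequence[float],
    filters: Sequence[str] = ("original", "log", "wavelet"),
    log_sigmas: Sequence[float] = (1.0, 2.0, 3.0),
    wavelet: str = "coif1",
) -> dict[str, np.ndarray]:
    """All enabled filter images, keyed by their provenance name."""
    images: dict[str, np.ndarray] = {}
    if "original" in filters:
        images["original"] = np.asarray(data, float)
    if "log" in filters:
        for s in log_sigmas:
            images[f"log-sigma-{s:g}mm"] = log_image(data, s, spacing)
    if "wavelet" in filters:
        images.update(wavelet_images(data, wavelet))
    return images
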