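"""IBSI-style radiomics feature extraction from tumour regions.

A native engine computing seven feature families (first-order, shape,
GLCM, GLRLM, GLSZM, NGTDM, GLDM) on the original image and on
Laplacian-of-Gaussian and level-1 wavelet filtered images. Gray levels are
discretised with a fixed bin width anchored at the region minimum, so all
texture features are invariant to adding a constant to the image.

Feature names carry provenance: ``<filter>_<family>_<FeatureName>``, e.g.
``original_glcm_Contrast`` or ``wavelet-HLL_firstorder_Mean``; shape
features are computed once per region on the unfiltered mask geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..clustering import HabitatMap
from ..preprocess import Volume
from ._filters import filter_images, log_image, wavelet_images
from ._firstorder import firstorder_features
from ._shape import shape_features
from ._texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "discretise",
    "extract_region",
    "extract_cohort",
    "filter_images",
    "log_image",
    "wavelet_images",
]

ALL_FAMILIES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

_TEXTURE_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """What to extract: families, filters and discretisation.

    ``bin_width`` is in grayscale units of the normalised 0-255 image
    (default 25, ~10 bins over the VOI range); ``log_sigmas`` in mm.
    """

    bin_width: float = 25.0
    log_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet: str = "coif1"
    families: tuple[str, ...] = ALL_FAMILIES
    filters: tuple[str, ...] = ("original", "log", "wavelet")
    min_region_voxels: int = 10
    habitat_shape: bool = True  # extract shape features for habitat sub-regions too

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if any(s <= 0 for s in self.log_sigmas):
            raise ValueError("log_sigmas must be > 0")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")


def discretise(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width gray levels 1..Ng anchored at the region minimum."""
    levels = np.floor((values - values.min()) / bin_width).astype(np.int32) + 1
    return levels, int(levels.max())


def extract_region(
    volume: Volume,
    region_mask: np.ndarray,
    config: ExtractionConfig | None = None,
    images: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """All enabled features of one region of one patient.

    ``images`` may carry precomputed filter images of the full volume (as
    produced by :func:`filter_images`) so they can be shared between the
    whole-tumour and habitat regions of the same patient.
    """
    config = config or ExtractionConfig()
    region = np.asarray(region_mask).astype(bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    if n < config.min_region_voxels:
        raise ValueError(
            f"region has {n} voxels < min_region_voxels={config.min_region_voxels}"
        )
    if images is None:
        images = filter_images(
            volume.data, volume.spacing, config.filters, config.log_sigmas, config.wavelet
        )

    out: dict[str, float] = {}
    if "shape" in config.families:
        for name, value in shape_features(region, volume.spacing).items():
            out[f"original_shape_{name}"] = value

    bbox = tuple(
        slice(int(ax.min()), int(ax.max()) + 1) for ax in np.nonzero(region)
    )
    region_c = region[bbox]
    for image_name, image in images.items():
        if image.shape != region.shape:
            raise ValueError("filter image grid does not match the mask grid")
        vals = image[region]
        levels, n_levels = discretise(vals, config.bin_width)
        if "firstorder" in config.families:
            for name, value in firstorder_features(vals, levels, volume.voxel_volume).items():
                out[f"{image_name}_firstorder_{name}"] = value
        # cropping preserves the C-order enumeration of region voxels, so the
        # levels vector lines up with the cropped boolean mask
        g = np.zeros(region_c.shape, dtype=np.int32)
        g[region_c] = levels
        if n_levels == 1:
            logger.info(
                "region has a single gray level on %s; texture features take their "
                "degenerate conventional values",
                image_name,
            )
        for family in config.families:
            func = _TEXTURE_FUNCS.get(family)
            if func is None:
                continue
            for name, value in func(g, n_levels).items():
                out[f"{image_name}_{family}_{name}"] = value
    return out


def extract_cohort(
    cases: Sequence,
    habitat_maps: Mapping[str, HabitatMap],
    config: ExtractionConfig | None = None,
    volumes: Mapping[str, Volume] | None = None,
    masks: Mapping[str, Volume] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-region feature matrices (patients x features) for a cohort.

    ``cases`` is a sequence of objects with ``patient_id`` attributes (e.g.
    :class:`~habitatomics.phantom.PatientCase`); ``volumes``/``masks`` map
    patient id to the preprocessed image and VOI mask (defaults to the raw
    case arrays). Returns one DataFrame per region: ``whole`` plus
    ``habitat1..k``. Patients whose habitat region is missing or smaller
    than the configured minimum are dropped from that region's matrix (and
    logged).
    """
    config = config or ExtractionConfig()
    k = max(hm.n_habitats for hm in habitat_maps.values())
    regions = ["whole"] + [f"habitat{h}" for h in range(1, k + 1)]
    rows: dict[str, dict[str, dict[str, float]]] = {r: {} for r in regions}

    for case in cases:
        pid = case.patient_id
        vol = volumes[pid] if volumes else Volume(case.volume, case.spacing)
        mask = masks[pid] if masks else Volume(case.mask, case.spacing)
        hmap = habitat_maps[pid]
        images = filter_images(
            vol.data, vol.spacing, config.filters, config.log_sigmas, config.wavelet
        )
        region_masks = {"whole": mask.data.astype(bool)}
        for h in range(1, k + 1):
            region_masks[f"habitat{h}"] = hmap.labels.data == h
        for region, rmask in region_masks.items():
            cfg = config
            if region != "whole" and not config.habitat_shape:
                cfg = ExtractionConfig(
                    **{**_cfg_dict(config), "families": tuple(
                        f for f in config.families if f != "shape"
                    )}
                )
            try:
                rows[region][pid] = extract_region(vol, rmask, cfg, images=images)
            except ValueError as exc:
                logger.warning("patient %s region %s skipped: %s", pid, region, exc)
    out = {}
    for region in regions:
        df = pd.DataFrame.from_dict(rows[region], orient="index")
        df.index.name = "patient_id"
        out[region] = df
    return out


def _cfg_dict(config: ExtractionConfig) -> dict:
    return {
        "bin_width": config.bin_width,
        "log_sigmas": config.log_sigmas,
        "wavelet": config.wavelet,
        "families": config.families,
        "filters": config.filters,
        "min_region_voxels": config.min_region_voxels,
        "habitat_shape": config.habitat_shape,
    }
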