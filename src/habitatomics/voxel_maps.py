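"""Per-voxel intensity and slice-wise local-entropy maps.

These are the two features that drive habitat clustering. Local entropy is
the Shannon entropy (bits) of the N_g-bin grayscale histogram inside a 2D
in-plane window centred on each voxel, computed layer by layer; windows
are clipped at image borders, and the histogram counts every window voxel
regardless of mask membership. The stabilised form
H = -sum_i p_i * log2(p_i + eps) is used so empty bins are safe and
H -> Shannon entropy as eps -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Volume

__all__ = ["EntropyConfig", "entropy_map", "build_voxel_table", "VoxelScaler"]


@dataclass(frozen=True)
class EntropyConfig:
    window_radius: int = 2
    n_bins: int = 32
    epsilon: float = 1e-12
    slicewise: bool = True
    value_range: tuple[float, float] | None = (0.0, 255.0)  # None: use data range

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins (N_g) must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _window_counts_2d(bins: np.ndarray, n_bins: int, radius: int) -> np.ndarray:
    """Clipped-window histogram counts per bin via 2D summed-area tables.

    Returns array (n_bins, H, W) of counts of each bin inside the
    (2r+1)^2 window around each pixel, clipped at the borders.
    """
    h, w = bins.shape
    onehot = np.zeros((n_bins, h, w), dtype=np.int32)
    ii, jj = np.indices(bins.shape)
    onehot[bins.ravel(), ii.ravel(), jj.ravel()] = 1
    # summed-area table with a zero border row/col
    sat = np.zeros((n_bins, h + 1, w + 1), dtype=np.int64)
    sat[:, 1:, 1:] = onehot.cumsum(axis=1).cumsum(axis=2)
    r = radius
    i0 = np.clip(np.arange(h) - r, 0, h)
    i1 = np.clip(np.arange(h) + r + 1, 0, h)
    j0 = np.clip(np.arange(w) - r, 0, w)
    j1 = np.clip(np.arange(w) + r + 1, 0, w)
    a = sat[:, i1[:, None], j1[None, :]]
    b = sat[:, i0[:, None], j1[None, :]]
    c = sat[:, i1[:, None], j0[None, :]]
    d = sat[:, i0[:, None], j0[None, :]]
    return a - b - c + d


def entropy_map(volume: Volume, mask: Volume, config: EntropyConfig | None = None) -> Volume:
    """Slice-wise local-entropy map of a (normalised) grayscale volume.

    For every voxel, the grayscale values inside the in-plane square window
    of the configured radius are binned into ``n_bins`` equal-width bins
    and H = -sum p_i log2(p_i + eps) is returned (bits).
    """
    config = config or EntropyConfig()
    if not mask.data.any():
        raise ValueError("empty VOI")
    data = volume.data
    if config.value_range is None:
        lo, hi = float(data.min()), float(data.max())
    else:
        lo, hi = config.value_range
    width = (hi - lo) / config.n_bins if hi > lo else 1.0
    bins = np.clip(((data - lo) / width).astype(np.int64), 0, config.n_bins - 1)

    out = np.zeros(data.shape, dtype=float)
    for z in range(data.shape[2]):
        counts = _window_counts_2d(bins[:, :, z], config.n_bins, config.window_radius)
        total = counts.sum(axis=0)
        p = counts / total
        terms = np.where(p > 0, p * np.log2(p + config.epsilon), 0.0)
        out[:, :, z] = -terms.sum(axis=0)
    return Volume(out, volume.spacing, volume.origin, volume.direction)


def build_voxel_table(
    volume: Volume,
    entropy: Volume,
    mask: Volume,
    patient_id: str = "",
) -> pd.DataFrame:
    """One row per mask voxel: patient_id, i, j, k, intensity, entropy.

    The per-patient total intensity over the VOI (the V_voxel QC quantity)
    is stored in ``DataFrame.attrs['v_voxel']``.
    """
    if volume.data.shape != mask.data.shape or volume.data.shape != entropy.data.shape:
        raise ValueError(
            f"grid mismatch: volume {volume.data.shape}, entropy {entropy.data.shape}, "
            f"mask {mask.data.shape}"
        )
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty VOI")
    idx = np.argwhere(m)
    table = pd.DataFrame(
        {
            "patient_id": patient_id,
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
            "intensity": volume.data[m],
            "entropy": entropy.data[m],
        }
    )
    table.attrs["v_voxel"] = float(volume.data[m].sum())
    return table


class VoxelScaler:
    """Pool-and-standardise the (intensity, entropy) voxel features.

    Fit on voxel tables pooled across the training cohort so Euclidean
    distances in the clustering are scale-free; the stored transform is
    then applied unchanged to each patient (including unseen ones).
    """

    features = ("intensity", "entropy")

    def fit(self, tables: "list[pd.DataFrame] | pd.DataFrame") -> "VoxelScaler":
        pooled = pd.concat(tables) if isinstance(tables, list) else tables
        if len(pooled) < 2:
            raise ValueError("need at least 2 pooled voxels to fit the scaler")
        X = pooled[list(self.features)].to_numpy(float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # population SD (ddof=0)
        for name, s in zip(self.features, self.scale_):
            if s == 0:
                raise ValueError(f"zero-variance voxel feature: {name}")
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise RuntimeError("VoxelScaler is not fitted")
        X = table[list(self.features)].to_numpy(float)
        return (X - self.mean_) / self.scale_

    def fit_transform(self, tables) -> np.ndarray:
        self.fit(tables)
        pooled = pd.concat(tables) if isinstance(tables, list) else tables
        return self.transform(pooled)
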