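"""First-order (intensity histogram) features on the raw region values."""

from __future__ import annotations

import numpy as np

__all__ = ["firstorder_features"]


def firstorder_features(
    values: np.ndarray, discretised: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    """18 first-order features of a region.

    ``values`` are the (filtered-image) gray values of the region voxels;
    ``discretised`` their fixed-bin-width gray levels (1..Ng), used only
    for Entropy and Uniformity.
    """
    x = np.asarray(values, float)
    n = x.size
    counts = np.bincount(discretised)[1:]
    p = counts[counts > 0] / n
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    var = float(x.var())  # population variance, ddof=0
    sd = np.sqrt(var)
    if sd > 0:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())  # Pearson (not excess) kurtosis
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
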