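"""Texture-matrix feature families (GLCM, GLRLM, GLSZM, NGTDM, GLDM).

All families operate on a discretised gray-level volume ``g`` (int array,
0 outside the region, 1..Ng inside; fixed-bin-width discretisation is done
by the caller). Directional families (GLCM, GLRLM) use the 13 unique 3D
directions at distance 1 and average features over directions; the
neighbourhood families (NGTDM, GLDM) use the full 26-neighbourhood.

Degenerate regions (a single occupied gray level, or no valid voxel pairs)
fall back to the conventional values noted per feature (e.g. correlation
1, contrast 0) rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

_EPS = np.finfo(float).eps

# 13 unique direction offsets (positive lexicographic half of the 26-neighbourhood)
_DIRECTIONS: list[tuple[int, int, int]] = [
    o
    for o in (
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    )
    if o > (0, 0, 0)
]

_ALL_26 = [o for o in (
    (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
) if o != (0, 0, 0)]


def _shifted_slices(shape, offset):
    """(src, dst) index tuples such that src + offset == dst, both in bounds."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        src.append(slice(max(0, -o), n - max(0, o)))
        dst.append(slice(max(0, o), n - max(0, -o)))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- GLCM


def _glcm_matrix(g: np.ndarray, n_levels: int, offset) -> np.ndarray:
    src, dst = _shifted_slices(g.shape, offset)
    a, b = g[src].ravel(), g[dst].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    P = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).reshape(
        n_levels, n_levels
    ).astype(float)
    return P + P.T  # symmetric co-occurrences


def _glcm_one(p: np.ndarray, n_levels: int) -> dict[str, float]:
    i = np.arange(1, n_levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(ii - jj).astype(int)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=n_levels)
    kd = np.arange(n_levels, dtype=float)
    summ = (ii + jj).astype(int)
    p_sum = np.bincount(summ.ravel(), weights=p.ravel(), minlength=2 * n_levels + 1)[2:]
    ks = np.arange(2, 2 * n_levels + 1, dtype=float)

    da = float((kd * p_diff).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    pxy = np.outer(px, px)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if sigma > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0  # single gray level: perfectly correlated by convention

    # maximal correlation coefficient via the Q matrix (occupied levels only)
    occ = px > 0
    if occ.sum() > 1:
        psub = p[np.ix_(occ, occ)]
        pxs = px[occ]
        Q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        eig = np.sort(np.linalg.eigvals(Q).real)[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1]))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    off = np.abs(ii - jj) > 0
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum())

    cdev = ii + jj - 2 * mu
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((cdev**4 * p).sum()),
        "ClusterShade": float((cdev**3 * p).sum()),
        "ClusterTendency": float((cdev**2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "DifferenceVariance": float(((kd - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / n_levels) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / n_levels)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def glcm_features(g: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLCM features averaged over the 13 directions (distance 1)."""
    per_dir: list[dict[str, float]] = []
    for offset in _DIRECTIONS:
        P = _glcm_matrix(g, n_levels, offset)
        total = P.sum()
        if total == 0:
            continue
        per_dir.append(_glcm_one(P / total, n_levels))
    if not per_dir:
        raise ValueError("no voxel pairs in any direction; region too small for GLCM")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLRLM


def _runs_one_direction(g: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """(gray level, maximal run length) of every run along one direction."""
    region = g > 0
    cont = np.zeros(g.shape, bool)  # run continues from v to v+offset
    src, dst = _shifted_slices(g.shape, offset)
    cont[src] = region[src] & region[dst] & (g[src] == g[dst])
    continued_from = np.zeros(g.shape, bool)
    continued_from[dst] = cont[src]
    starts = region & ~continued_from

    coords = np.argwhere(starts)
    levels = g[starts]
    lengths = np.ones(len(coords), dtype=np.int64)
    off = np.asarray(offset)
    active = np.where(cont[tuple(coords.T)])[0]
    cur = coords.copy()
    while active.size:
        cur[active] += off
        lengths[active] += 1
        still = cont[tuple(cur[active].T)]
        active = active[still]
    return levels, lengths


def _sz_features(
    P: np.ndarray, n_voxels: int, prefix_small: str, prefix_large: str, axis_name: str
) -> dict[str, float]:
    """Shared size/length-type feature battery for GLRLM/GLSZM-style matrices.

    ``P[i-1, s-1]`` counts entities (runs or zones) of gray level i and
    size s; feature names follow the conventional family-specific wording
    supplied via the prefixes.
    """
    N = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / N
    mu_i = (i * p).sum()
    mu_s = (s * p).sum()
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    pnz = p[p > 0]
    return {
        f"{prefix_small}Emphasis": float((P / s**2).sum() / N),
        f"{prefix_large}Emphasis": float((P * s**2).sum() / N),
        "GrayLevelNonUniformity": float((pg**2).sum() / N),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / N**2),
        f"{axis_name}NonUniformity": float((ps**2).sum() / N),
        f"{axis_name}NonUniformityNormalized": float((ps**2).sum() / N**2),
        f"{axis_name}Percentage" if axis_name == "RunLength" else "ZonePercentage": float(
            N / n_voxels
        ),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        f"{axis_name}Variance": float(((s - mu_s) ** 2 * p).sum()),
        f"{axis_name}Entropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / N),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / N),
        f"{prefix_small}LowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / N),
        f"{prefix_small}HighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / N),
        f"{prefix_large}LowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / N),
        f"{prefix_large}HighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / N),
    }


def glrlm_features(g: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLRLM features averaged over the 13 directions."""
    n_voxels = int((g > 0).sum())
    per_dir = []
    for offset in _DIRECTIONS:
        levels, lengths = _runs_one_direction(g, offset)
        if levels.size == 0:
            continue
        P = np.zeros((n_levels, int(lengths.max())), dtype=float)
        np.add.at(P, (levels - 1, lengths - 1), 1.0)
        feats = _sz_features(P, n_voxels, "ShortRun", "LongRun", "RunLength")
        per_dir.append(feats)
    if not per_dir:
        raise ValueError("empty region; no runs")
    out = {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    # conventional GLRLM naming for the run-length axis entropy/percentage
    out["RunEntropy"] = out.pop("RunLengthEntropy")
    out["RunPercentage"] = out.pop("RunLengthPercentage")
    out["RunVariance"] = out.pop("RunLengthVariance")
    out["RunLengthNonUniformity"] = out.pop("RunLengthNonUniformity")
    out["LowGrayLevelRunEmphasis"] = out.pop("LowGrayLevelEmphasis")
    out["HighGrayLevelRunEmphasis"] = out.pop("HighGrayLevelEmphasis")
    return out


# ---------------------------------------------------------------- GLSZM


def glszm_features(g: np.ndarray, n_levels: int) -> dict[str, float]:
    """Gray-level size-zone features (26-connected zones, direction-free)."""
    n_voxels = int((g > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty region")
    structure = np.ones((3, 3, 3), dtype=int)
    sizes: list[tuple[int, int]] = []  # (level, zone size)
    for level in range(1, n_levels + 1):
        binary = g == level
        if not binary.any():
            continue
        labelled, n_zones = ndimage.label(binary, structure=structure)
        zone_sizes = np.bincount(labelled.ravel())[1:]
        sizes.extend((level, int(z)) for z in zone_sizes)
    max_size = max(s for _, s in sizes)
    P = np.zeros((n_levels, max_size), dtype=float)
    for level, size in sizes:
        P[level - 1, size - 1] += 1.0
    feats = _sz_features(P, n_voxels, "SmallArea", "LargeArea", "Zone")
    feats["SmallAreaEmphasis"] = feats.pop("SmallAreaEmphasis")
    feats["LowGrayLevelZoneEmphasis"] = feats.pop("LowGrayLevelEmphasis")
    feats["HighGrayLevelZoneEmphasis"] = feats.pop("HighGrayLevelEmphasis")
    feats["SizeZoneNonUniformity"] = feats.pop("ZoneNonUniformity")
    feats["SizeZoneNonUniformityNormalized"] = feats.pop("ZoneNonUniformityNormalized")
    return feats


# ---------------------------------------------------------------- NGTDM


def _neighbour_sums(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of in-region 26-neighbour gray levels per voxel."""
    region = g > 0
    nsum = np.zeros(g.shape, dtype=float)
    ncnt = np.zeros(g.shape, dtype=np.int32)
    vals = g.astype(float)
    for offset in _ALL_26:
        src, dst = _shifted_slices(g.shape, offset)
        nsum[src] += np.where(region[dst], vals[dst], 0.0)
        ncnt[src] += region[dst]
    return nsum, ncnt


def ngtdm_features(g: np.ndarray, n_levels: int) -> dict[str, float]:
    """Neighbouring gray-tone difference features (5)."""
    region = g > 0
    nsum, ncnt = _neighbour_sums(g)
    valid = region & (ncnt > 0)
    if not valid.any():
        raise ValueError("region has no voxels with in-region neighbours")
    levels = g[valid].astype(float)
    abar = nsum[valid] / ncnt[valid]
    absdiff = np.abs(levels - abar)

    n_i = np.bincount(g[valid], minlength=n_levels + 1)[1:].astype(float)
    s_i = np.bincount(g[valid], weights=absdiff, minlength=n_levels + 1)[1:]
    Nvp = n_i.sum()
    p_i = n_i / Nvp
    occupied = p_i > 0
    i = np.arange(1, n_levels + 1, dtype=float)
    Ngp = int(occupied.sum())

    coarseness = 1.0 / max((p_i * s_i).sum(), _EPS)
    coarseness = min(coarseness, 1e6)  # cap the degenerate flat-region case
    if Ngp > 1:
        io, po, so = i[occupied], p_i[occupied], s_i[occupied]
        pij = np.outer(po, po)
        dij2 = (io[:, None] - io[None, :]) ** 2
        contrast = (pij * dij2).sum() / (Ngp * (Ngp - 1)) * (absdiff.sum() / Nvp)
        denom_busy = np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum()
        busyness = (po * so).sum() / denom_busy if denom_busy > 0 else 0.0
        complexity = (
            np.abs(io[:, None] - io[None, :])
            * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
            / (po[:, None] + po[None, :])
        ).sum() / Nvp
        s_total = so.sum()
        strength = (
            ((po[:, None] + po[None, :]) * dij2).sum() / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------- GLDM


def gldm_features(g: np.ndarray, n_levels: int, alpha: float = 0.0) -> dict[str, float]:
    """Gray-level dependence features (14).

    A neighbour is "dependent" when its gray level differs from the centre
    by at most ``alpha``; the dependence size j of a voxel is 1 + its
    dependent-neighbour count (the +1 keeps j >= 1, mirroring the centre
    voxel itself).
    """
    region = g > 0
    if not region.any():
        raise ValueError("empty region")
    dep = np.zeros(g.shape, dtype=np.int32)
    for offset in _ALL_26:
        src, dst = _shifted_slices(g.shape, offset)
        dep[src] += region[dst] & (np.abs(g[src] - g[dst]) <= alpha)
    levels = g[region]
    sizes = dep[region] + 1
    P = np.zeros((n_levels, int(sizes.max())), dtype=float)
    np.add.at(P, (levels - 1, sizes - 1), 1.0)

    N = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / N
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    pnz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((P / j**2).sum() / N),
        "LargeDependenceEmphasis": float((P * j**2).sum() / N),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / N),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / N),
        "DependenceNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / N**2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((j - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / N),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / N),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / N),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / N),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / N),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / N),
    }
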