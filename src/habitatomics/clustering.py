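"""Habitat clustering: consensus k selection and per-patient segmentation.

The number of habitats k is chosen at the cohort level by consensus
clustering of voxels pooled across training patients: k-means is run on
many random item subsamples, co-assignment frequencies form a consensus
matrix per k, and the relative change in the area under the consensus CDF
("delta area") locates the smallest k beyond which the clustering stops
becoming more stable. Each patient is then segmented with k-means at k*
on the (intensity, entropy) features, and clusters are relabelled so the
habitat index increases with cluster-centroid intensity — a deterministic
rule that makes "habitat h" comparable across patients.

k-means itself is a purpose-built Lloyd's implementation (k-means++
seeding, restarts, assignment-stability stopping): the consensus step runs
tens of thousands of small fits, where per-call overhead of a generic
library estimator dominates the actual arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Volume
from .voxel_maps import VoxelScaler

__all__ = [
    "kmeans_voxels",
    "ConsensusKSelector",
    "consensus_select_k",
    "HabitatSegmenter",
    "segment_patient",
    "HabitatMap",
]


def _kmeans_pp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (one candidate per step)."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[c:] = X[rng.integers(n, size=k - c)]
            break
        centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from a k-means++ start; stops when assignments stabilise."""
    n = X.shape[0]
    centers = _kmeans_pp(X, k, rng)
    x2 = (X**2).sum(axis=1)
    labels = np.full(n, -1, dtype=np.int32)
    ones = np.ones(n)
    for _ in range(max_iter):
        D = x2[:, None] - 2.0 * (X @ centers.T) + (centers**2).sum(axis=1)[None, :]
        new = D.argmin(axis=1).astype(np.int32)
        if np.array_equal(new, labels):
            break
        labels = new
        counts = np.bincount(labels, minlength=k).astype(float)
        empty = counts == 0
        if empty.any():
            # re-seed empty clusters at the points farthest from their center
            far = D[np.arange(n), labels].argsort()[::-1]
            for c, p in zip(np.where(empty)[0], far):
                centers[c] = X[p]
            continue
        for d in range(X.shape[1]):
            centers[:, d] = np.bincount(labels, weights=X[:, d], minlength=k) / counts
    wcss = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, wcss


def kmeans_voxels(
    features: np.ndarray, k: int, seed: int | None = None, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's k-means with k-means++ seeding and ``n_init`` restarts.

    Returns (labels, centroids, within-cluster sum of squares) of the best
    restart.
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(max(1, n_init)):
        labels, centers, wcss = _lloyd(X, k, rng)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    return best


@dataclass
class HabitatMap:
    """Integer-labelled habitat volume: 0 background, 1..k habitats."""

    labels: Volume
    counts: dict[int, int]
    centroids: dict[int, np.ndarray]  # original-scale (intensity, entropy) means

    @property
    def n_habitats(self) -> int:
        return len(self.counts)

    def region_mask(self, habitat: int) -> np.ndarray:
        return (self.labels.data == habitat).astype(np.uint8)


class ConsensusKSelector:
    """Choose the number of clusters by resampled consensus clustering.

    ``n_reps`` item subsamples at ``item_fraction`` are clustered for each
    k in ``k_range``; consensus(i, j) = co-clustered count / co-sampled
    count. Two summaries are computed per k:

    * the empirical CDF of upper-triangle consensus values, its area A(k)
      and the relative delta-area series (the classic consensus-clustering
      display);
    * PAC(k), the proportion of ambiguous clustering — the fraction of
      consensus values strictly between ``pac_bounds`` — which directly
      measures assignment stability.

    The default decision rule (``selection_rule='pac'``) returns the
    largest k whose PAC is at or below ``pac_threshold``, i.e. the finest
    clustering that is still stable under resampling (falling back to the
    smallest k when no k qualifies). The delta-area elbow (largest k whose successor's
    relative area gain drops below ``delta_area_threshold``) is available
    as ``selection_rule='delta_area'``; note the CDF area is dominated by
    cluster-size combinatorics (splitting one of k equal stable clusters
    gains about 1/(k^2-1) in relative area regardless of any structure),
    so the PAC rule is the more reliable automation of the visual
    criterion of keeping the finest clustering that is both well separated
    and reproducible.

    Fitted attributes: ``consensus_``, ``cdfs_``, ``areas_``,
    ``delta_areas_``, ``pac_`` (dicts keyed by k) and the chosen ``k_``.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 10),
        n_reps: int = 1000,
        item_fraction: float = 0.8,
        selection_rule: str = "pac",
        pac_threshold: float = 0.08,
        pac_bounds: tuple[float, float] = (0.1, 0.9),
        delta_area_threshold: float = 0.05,
        max_items: int = 5000,
        n_init: int = 1,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.n_reps = n_reps
        self.item_fraction = item_fraction
        self.selection_rule = selection_rule
        self.pac_threshold = pac_threshold
        self.pac_bounds = pac_bounds
        self.delta_area_threshold = delta_area_threshold
        self.max_items = max_items
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k_range": self.k_range,
            "n_reps": self.n_reps,
            "item_fraction": self.item_fraction,
            "selection_rule": self.selection_rule,
            "pac_threshold": self.pac_threshold,
            "pac_bounds": self.pac_bounds,
            "delta_area_threshold": self.delta_area_threshold,
            "max_items": self.max_items,
            "n_init": self.n_init,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ConsensusKSelector":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: np.ndarray) -> "ConsensusKSelector":
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        if n > self.max_items:
            keep = rng.choice(n, size=self.max_items, replace=False)
            X = X[keep]
            n = self.max_items
        m = max(2, int(round(self.item_fraction * n)))

        ks = list(range(self.k_range[0], self.k_range[1] + 1))
        # one subsample schedule shared across k so matrices are comparable
        samples = [rng.choice(n, size=m, replace=False) for _ in range(self.n_reps)]
        S = np.zeros((n, self.n_reps), dtype=np.float32)
        for r, idx in enumerate(samples):
            S[idx, r] = 1.0
        cosampled = S @ S.T  # co-sample counts

        never = cosampled == 0
        if never[np.triu_indices(n, 1)].any():
            warnings.warn(
                "some item pairs were never co-sampled; their consensus entries "
                "are undefined and excluded from the CDF",
                stacklevel=2,
            )

        self.consensus_: dict[int, np.ndarray] = {}
        self.cdfs_: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.areas_: dict[int, float] = {}
        self.pac_: dict[int, float] = {}
        lo_b, hi_b = self.pac_bounds
        triu = np.triu_indices(n, 1)
        for k in ks:
            # one-hot cluster indicators for every rep, co-clustering by GEMM
            Z = np.zeros((n, self.n_reps * k), dtype=np.float32)
            for r, idx in enumerate(samples):
                sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
                best = None
                for _ in range(max(1, self.n_init)):
                    labels, _, wcss = _lloyd(X[idx], k, sub_rng, max_iter=self.max_iter)
                    if best is None or wcss < best[1]:
                        best = (labels, wcss)
                Z[idx, r * k + best[0]] = 1.0
            coclustered = Z @ Z.T
            with np.errstate(invalid="ignore", divide="ignore"):
                consensus = coclustered / cosampled
            consensus[never] = np.nan
            self.consensus_[k] = consensus
            vals = consensus[triu]
            vals = np.sort(vals[np.isfinite(vals)])
            # empirical CDF over [0, 1] and the area under it
            xs = np.concatenate([[0.0], vals, [1.0]])
            cdf = np.concatenate([[0.0], np.arange(1, len(vals) + 1) / len(vals), [1.0]])
            self.cdfs_[k] = (xs, cdf)
            self.areas_[k] = float(np.sum(np.diff(xs) * cdf[:-1]))
            self.pac_[k] = float(((vals > lo_b) & (vals < hi_b)).mean())

        self.delta_areas_: dict[int, float] = {ks[0]: self.areas_[ks[0]]}
        for prev, k in zip(ks[:-1], ks[1:]):
            denom = self.areas_[prev] if self.areas_[prev] > 0 else 1.0
            self.delta_areas_[k] = (self.areas_[k] - self.areas_[prev]) / denom
        if self.selection_rule == "pac":
            self.k_ = self._pac_rule(ks)
        elif self.selection_rule == "delta_area":
            self.k_ = self._elbow(ks)
        else:
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        return self

    def _pac_rule(self, ks: list[int]) -> int:
        # finest clustering that is still stable under resampling; note a
        # coarser k can itself be unstable (e.g. two equally good merges of
        # three clusters), so the scan must not stop at the first unstable k
        stable = [k for k in ks if self.pac_[k] <= self.pac_threshold]
        return max(stable) if stable else ks[0]

    def _elbow(self, ks: list[int]) -> int:
        # scan upward; stop at the k whose successor's relative gain drops
        # below threshold (the "sharp decrease" of the delta-area curve)
        for k in ks[:-1]:
            if self.delta_areas_[k + 1] < self.delta_area_threshold:
                return k
        return ks[-1]


def consensus_select_k(
    features: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    reps: int = 1000,
    item_fraction: float = 0.8,
    seed: int | None = None,
    **kwargs,
) -> ConsensusKSelector:
    """Functional wrapper over :class:`ConsensusKSelector`."""
    sel = ConsensusKSelector(
        k_range=k_range, n_reps=reps, item_fraction=item_fraction, random_state=seed, **kwargs
    )
    return sel.fit(features)


class HabitatSegmenter:
    """Per-patient k-means segmentation at a fixed k with label alignment.

    Habitat labels 1..k are assigned in order of increasing cluster-centroid
    intensity (original grayscale), so habitat indices are comparable across
    patients.
    """

    def __init__(self, n_habitats: int, scaler: VoxelScaler, random_state: int | None = None):
        self.n_habitats = n_habitats
        self.scaler = scaler
        self.random_state = random_state

    def segment(self, table: pd.DataFrame, mask: Volume) -> HabitatMap:
        if len(table) < self.n_habitats:
            raise ValueError(
                f"patient has {len(table)} voxels < k={self.n_habitats}; excluded"
            )
        Xz = self.scaler.transform(table)
        labels, _, _ = kmeans_voxels(Xz, self.n_habitats, seed=self.random_state, n_init=10)
        # relabel by ascending mean intensity on the original scale
        raw_intensity = table["intensity"].to_numpy(float)
        raw_entropy = table["entropy"].to_numpy(float)
        order = np.argsort(
            [raw_intensity[labels == c].mean() for c in range(self.n_habitats)]
        )
        remap = np.empty(self.n_habitats, dtype=int)
        remap[order] = np.arange(1, self.n_habitats + 1)
        new_labels = remap[labels]

        out = np.zeros(mask.data.shape, dtype=np.int16)
        idx = table[["i", "j", "k"]].to_numpy(int)
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = new_labels
        counts = {h: int((new_labels == h).sum()) for h in range(1, self.n_habitats + 1)}
        cents = {
            h: np.array(
                [raw_intensity[new_labels == h].mean(), raw_entropy[new_labels == h].mean()]
            )
            for h in range(1, self.n_habitats + 1)
        }
        return HabitatMap(
            labels=Volume(out, mask.spacing, mask.origin, mask.direction),
            counts=counts,
            centroids=cents,
        )


def segment_patient(
    table: pd.DataFrame,
    mask: Volume,
    k: int,
    scaler: VoxelScaler,
    seed: int | None = None,
) -> HabitatMap:
    """Segment one patient's VOI into k habitats (see HabitatSegmenter)."""
    return HabitatSegmenter(k, scaler, random_state=seed).segment(table, mask)
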