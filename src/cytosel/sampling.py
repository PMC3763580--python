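"""Hybrid resampling for extreme class imbalance.

The minority class is grown with SMOTE (synthetic points interpolated
between a real minority sample and one of its k nearest minority
neighbours) while the majority class is shrunk by K-means cluster
undersampling (K = target size; one real representative per cluster).
Together they rebuild a near-balanced training set without either
flooding it with synthetic noise or discarding whole regions of the
majority distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class ResamplingPlan:
    """Targets and knobs for :func:`hybrid_resample`.

    ``undersample_fraction`` is the initial-cluster-count fraction λ: when
    ``majority_target`` is None it defaults to ``ceil(λ * n_majority)``.
    """

    minority_target: Optional[int] = 2000
    majority_target: Optional[int] = 2000
    smote_neighbors: int = 5
    kmeans_max_iterations: int = 50
    undersample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.undersample_fraction <= 1.0):
            raise ValueError("undersample_fraction must lie in (0, 1]")
        if self.smote_neighbors < 1:
            raise ValueError("smote_neighbors must be positive")
        if self.kmeans_max_iterations < 1:
            raise ValueError("kmeans_max_iterations must be positive")


@dataclass(frozen=True)
class ResampledSet:
    """Rebalanced training set with per-row provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # "original" | "synthetic" per row

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def smote_oversample(
    minority_rows: np.ndarray,
    minority_target: int,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Grow the minority class to ``minority_target`` rows with SMOTE.

    Each synthetic row is ``x + u * (x_nn - x)`` for a uniform u in [0, 1],
    where x is a randomly chosen original minority row and x_nn one of its
    k nearest minority neighbours (Euclidean, self excluded). The original
    rows are returned first, followed by the synthetic rows.
    """
    X = np.asarray(minority_rows, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    if k >= n:
        raise ValueError(f"smote_neighbors k={k} must be < minority count {n}")
    if minority_target < n:
        raise ValueError(
            f"minority_target {minority_target} is below the current count {n}"
        )
    n_new = minority_target - n
    if n_new == 0:
        return X.copy()

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    # column 0 is the point itself (distance 0)
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    parents = rng.integers(0, n, size=n_new)
    picks = rng.integers(0, k, size=n_new)
    u = rng.random(size=n_new)
    neighbors = neighbor_idx[parents, picks]
    synthetic = X[parents] + u[:, None] * (X[neighbors] - X[parents])
    return np.vstack([X, synthetic])


def _lloyd(
    X: np.ndarray, n_clusters: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's K-means with squared-Euclidean assignment.

    Initial centroids are a seeded, squared-distance-weighted draw of K
    distinct input rows (k-means++ seeding, which keeps representatives
    spread across the data and so preserves coverage of well-separated
    clusters); assignment ties break toward the lowest cluster index
    (argmin); an empty cluster is re-seeded with the point farthest from
    its current centroid. Returns (centroids, labels).
    """
    n = X.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    d2_min = cdist(X, X[first : first + 1], metric="sqeuclidean")[:, 0]
    for _ in range(n_clusters - 1):
        total = d2_min.sum()
        if total > 0:
            nxt = int(rng.choice(n, p=d2_min / total))
        else:  # all remaining points coincide with a centroid
            unchosen = np.setdiff1d(np.arange(n), chosen)
            nxt = int(rng.choice(unchosen))
        chosen.append(nxt)
        d2_min = np.minimum(
            d2_min, cdist(X, X[nxt : nxt + 1], metric="sqeuclidean")[:, 0]
        )
    centroids = X[chosen].copy()
    labels = np.zeros(n, dtype=np.int64)
    for it in range(max_iter):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        # re-seed empty clusters with the farthest point from its centroid
        counts = np.bincount(new_labels, minlength=n_clusters)
        for ci in np.flatnonzero(counts == 0):
            far = int(np.argmax(d2[np.arange(n), new_labels]))
            centroids[ci] = X[far]
            new_labels[far] = ci
            d2[:, ci] = cdist(X, centroids[ci : ci + 1], metric="sqeuclidean")[:, 0]
            counts = np.bincount(new_labels, minlength=n_clusters)
        if it > 0 and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for ci in range(n_clusters):
            members = X[labels == ci]
            if members.size:
                centroids[ci] = members.mean(axis=0)
    return centroids, labels


def kmeans_undersample(
    majority_rows: np.ndarray,
    majority_target: int,
    t: int = 50,
    seed: int = 0,
    return_indices: bool = False,
) -> np.ndarray:
    """Shrink the majority class to ``majority_target`` real rows.

    K-means with K = majority_target clusters is run on the majority rows;
    for each cluster the member closest to the cluster centroid is kept.
    The output is a verbatim subset of the input, one representative per
    cluster, preserving coverage of the majority distribution.
    """
    X = np.asarray(majority_rows, dtype=float)
    n = X.shape[0]
    if majority_target <= 0:
        raise ValueError("majority_target must be positive")
    if majority_target > n:
        raise ValueError(
            f"majority_target {majority_target} exceeds the current count {n}"
        )
    if majority_target == n:
        idx = np.arange(n)
        return (X.copy(), idx) if return_indices else X.copy()

    rng = np.random.default_rng(seed)
    centroids, labels = _lloyd(X, majority_target, t, rng)

    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for ci in range(majority_target):
        members = np.flatnonzero((labels == ci) & ~taken)
        if members.size == 0:
            continue
        d2 = np.sum((X[members] - centroids[ci]) ** 2, axis=1)
        pick = members[int(np.argmin(d2))]
        chosen.append(pick)
        taken[pick] = True
    # duplicate input rows can starve a cluster; fill from unchosen rows
    # nearest to any centroid so the output size is exact
    if len(chosen) < majority_target:
        remaining = np.flatnonzero(~taken)
        d2 = cdist(X[remaining], centroids, metric="sqeuclidean").min(axis=1)
        order = remaining[np.argsort(d2, kind="stable")]
        for pick in order[: majority_target - len(chosen)]:
            chosen.append(int(pick))
    idx = np.array(chosen)
    return (X[idx], idx) if return_indices else X[idx]


def hybrid_resample(X: np.ndarray, y: np.ndarray, plan: ResamplingPlan) -> ResampledSet:
    """SMOTE the minority class up and cluster-undersample the majority
    class down, then shuffle.

    The rarer of the two label values is the minority class. Majority rows
    in the output are always verbatim input rows; synthetic rows are
    flagged in ``provenance``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 classes, found {labels.size}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    minority_label = labels[int(np.argmin(counts))]
    majority_label = labels[int(np.argmax(counts))]
    if counts[0] == counts[1]:
        minority_label, majority_label = labels[0], labels[1]

    X_min = X[y == minority_label]
    X_maj = X[y == majority_label]
    n_min, n_maj = X_min.shape[0], X_maj.shape[0]

    minority_target = plan.minority_target if plan.minority_target is not None else n_min
    majority_target = (
        plan.majority_target
        if plan.majority_target is not None
        else math.ceil(plan.undersample_fraction * n_maj)
    )

    seeds = np.random.SeedSequence(plan.seed).spawn(3)
    smote_seed, kmeans_seed, shuffle_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )

    k = min(plan.smote_neighbors, n_min - 1)
    min_rows = smote_oversample(X_min, minority_target, k=k, seed=smote_seed)
    maj_rows = kmeans_undersample(
        X_maj, majority_target, t=plan.kmeans_max_iterations, seed=kmeans_seed
    )

    X_out = np.vstack([min_rows, maj_rows])
    y_out = np.concatenate(
        [
            np.full(min_rows.shape[0], minority_label),
            np.full(maj_rows.shape[0], majority_label),
        ]
    )
    prov = np.concatenate(
        [
            np.array(["original"] * n_min + ["synthetic"] * (min_rows.shape[0] - n_min)),
            np.array(["original"] * maj_rows.shape[0]),
        ]
    )
    order = np.random.default_rng(shuffle_seed).permutation(X_out.shape[0])
    return ResampledSet(X=X_out[order], y=y_out[order], provenance=prov[order])
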