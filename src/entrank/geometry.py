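"""Internal (geometry-based) cluster validity indices.

These need only the feature matrix, no ground truth.  Both are implemented
for city-block (l1) and Euclidean (l2) distances, since the clustering battery
runs under either metric and the index should see the same geometry the
algorithm did.

* Davies-Bouldin (lower = better):
  DB = (1/n) sum_i max_{j != i} (sigma_i + sigma_j) / d(c_i, c_j),
  where c_x is the coordinate-wise mean (centroid) of cluster x and sigma_x
  the mean distance of its members to c_x.
* Silhouette (higher = better): per point, s = (b - a) / max(a, b) with a the
  mean distance to co-members and b the smallest mean distance to another
  cluster; the overall score is the mean over points.  A point alone in its
  cluster scores 0, as does the degenerate all-identical case (0/0 -> 0).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, ValidationError
from .partition_io import FeatureMatrix, Partition

__all__ = ["METRICS", "davies_bouldin", "silhouette"]

METRICS = {"l1": "cityblock", "l2": "euclidean"}


def _resolve(features: FeatureMatrix, partition: Partition, metric: str):
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {set(METRICS)}")
    index = features.row_index()
    missing = [p for p in partition.assignment if p not in index]
    if missing:
        raise ValidationError(
            f"{len(missing)} partition ids missing from feature matrix, e.g. {missing[0]!r}"
        )
    ids = sorted(partition.assignment)
    X = features.values[[index[p] for p in ids]]
    labels = [partition.assignment[p] for p in ids]
    order = sorted(set(labels), key=str)
    groups = [np.array([i for i, lab in enumerate(labels) if lab == o]) for o in order]
    if len(groups) < 2:
        raise DegenerateInputError("internal indices need at least 2 clusters")
    return X, order, groups, METRICS[metric]


def davies_bouldin(
    features: FeatureMatrix, partition: Partition, metric: str = "l2"
) -> float:
    """Davies-Bouldin index of a partition; nonnegative, lower is better."""
    X, order, groups, dist = _resolve(features, partition, metric)
    centroids = np.vstack([X[g].mean(axis=0) for g in groups])
    scatter = np.array(
        [cdist(X[g], c[None, :], metric=dist).mean() for g, c in zip(groups, centroids)]
    )
    gaps = cdist(centroids, centroids, metric=dist)
    n = len(groups)
    ratios = np.empty(n)
    for i in range(n):
        worst = -np.inf
        for j in range(n):
            if j == i:
                continue
            if gaps[i, j] == 0.0:
                raise DegenerateInputError(
                    f"coincident centroids for clusters {order[i]!r} and {order[j]!r}"
                )
            worst = max(worst, (scatter[i] + scatter[j]) / gaps[i, j])
        ratios[i] = worst
    return float(ratios.mean())


def silhouette(
    features: FeatureMatrix, partition: Partition, metric: str = "l2"
) -> float:
    """Mean silhouette score of a partition; in [-1, 1], higher is better."""
    X, order, groups, dist = _resolve(features, partition, metric)
    D = cdist(X, X, metric=dist)
    member_of = np.empty(X.shape[0], dtype=int)
    for g_idx, g in enumerate(groups):
        member_of[g] = g_idx
    sizes = np.array([len(g) for g in groups])
    # mean distance from every point to every cluster
    to_cluster = np.stack([D[:, g].mean(axis=1) for g in groups], axis=1)
    scores = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        g = member_of[i]
        if sizes[g] == 1:
            continue  # singleton convention: s = 0
        a = to_cluster[i, g] * sizes[g] / (sizes[g] - 1)  # exclude self-distance
        b = min(to_cluster[i, h] for h in range(len(groups)) if h != g)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())
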