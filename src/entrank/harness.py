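"""Battery runner: execute partitioning algorithms and assemble a scoreboard.

The battery mirrors a standard comparison set: single / average / complete
linkage under l1 and l2 distances, k-means (l2, and an l1 variant via
k-medians), BIRCH, affinity propagation and spectral clustering.  The
algorithms themselves are the subjects under evaluation, not contributions of
this package, so execution delegates to scikit-learn wherever an
implementation exists; only the l1 k-means (k-medians) loop is written here,
because scikit-learn's KMeans is Euclidean-only.

All algorithms except affinity propagation accept a target cluster count S
directly; affinity propagation only exposes a ``preference`` scalar, which is
searched by bisection toward the target and the closest achieved S is kept
(with a warning when it differs — the entropy comparison is stated for a
fixed S).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import (
    AffinityPropagation,
    AgglomerativeClustering,
    Birch,
    KMeans,
    SpectralClustering,
)

from . import agreement, geometry, infomax
from .errors import AlgorithmFailure, DegenerateInputError, ValidationError
from .partition_io import FeatureMatrix, GroundTruth, Partition
from .ranking import Scoreboard

logger = logging.getLogger(__name__)

__all__ = ["ALGORITHM_CODES", "AlgorithmSpec", "RunRecord", "run_algorithm", "run_battery"]

#: code -> (family, distance metric or None)
ALGORITHM_CODES: dict[str, tuple[str, str | None]] = {
    "l1SI": ("linkage-single", "l1"),
    "l2SI": ("linkage-single", "l2"),
    "l1AV": ("linkage-average", "l1"),
    "l2AV": ("linkage-average", "l2"),
    "l1CO": ("linkage-complete", "l1"),
    "l2CO": ("linkage-complete", "l2"),
    "l1KM": ("kmeans", "l1"),
    "l2KM": ("kmeans", "l2"),
    "AP": ("affinity", None),
    "BI": ("birch", None),
    "SP": ("spectral", None),
}

_SKLEARN_METRIC = {"l1": "manhattan", "l2": "euclidean"}


@dataclass(frozen=True)
class AlgorithmSpec:
    """One battery entry: algorithm code, target cluster count, seed."""

    code: str
    target_S: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.code not in ALGORITHM_CODES:
            raise ValidationError(
                f"unknown algorithm code {self.code!r}; known: {sorted(ALGORITHM_CODES)}"
            )
        if self.target_S < 2:
            raise ValidationError("target_S must be >= 2")

    @property
    def family(self) -> str:
        return ALGORITHM_CODES[self.code][0]

    @property
    def metric(self) -> str | None:
        return ALGORITHM_CODES[self.code][1]


@dataclass(frozen=True)
class RunRecord:
    """Outcome of one clustering run."""

    spec: AlgorithmSpec
    partition: Partition
    achieved_S: int
    warnings: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)


def _kmedians(X: np.ndarray, S: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Lloyd-style k-medians: l1 assignment, coordinate-wise median update.

    Initialization is ++-style (distance-proportional seeding) under l1.
    An emptied cluster is re-seeded at the point farthest from its centroid.
    """
    rng = np.random.default_rng(seed)
    M = X.shape[0]
    centers = np.empty((S, X.shape[1]))
    centers[0] = X[rng.integers(M)]
    closest = cdist(X, centers[:1], metric="cityblock").ravel()
    for k in range(1, S):
        weights = closest / closest.sum() if closest.sum() > 0 else None
        centers[k] = X[rng.choice(M, p=weights)]
        closest = np.minimum(closest, cdist(X, centers[k : k + 1], metric="cityblock").ravel())
    labels = np.zeros(M, dtype=int)
    for _ in range(max_iter):
        dist = cdist(X, centers, metric="cityblock")
        new_labels = dist.argmin(axis=1)
        for k in range(S):
            members = new_labels == k
            if not members.any():
                farthest = dist[np.arange(M), new_labels].argmax()
                centers[k] = X[farthest]
                new_labels[farthest] = k
                members = new_labels == k
            centers[k] = np.median(X[members], axis=0)
        if (new_labels == labels).all():
            break
        labels = new_labels
    return labels


def _affinity_bisection(
    X: np.ndarray, target_S: int, seed: int, max_probes: int = 12
) -> tuple[np.ndarray, int, float]:
    """Search affinity propagation's preference toward a target cluster count.

    Preference is bisected between the minimum pairwise similarity (few
    clusters) and the maximum (many clusters); the probe achieving the S
    closest to the target wins, ties broken toward fewer clusters.
    """
    similarity = -cdist(X, X, metric="sqeuclidean")
    off_diag = similarity[~np.eye(len(X), dtype=bool)]
    lo, hi = 2.0 * float(off_diag.min()), float(off_diag.max())

    def probe(preference: float) -> tuple[np.ndarray, int]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # AP convergence warnings handled below
            model = AffinityPropagation(
                preference=preference, random_state=seed, damping=0.9, max_iter=400
            ).fit(X)
        labels = model.labels_
        n = len(set(labels))
        if n == 0 or (labels < 0).any():  # did not converge to any exemplar
            return np.zeros(len(X), dtype=int), 1
        return labels, n

    best: tuple[int, np.ndarray, float] | None = None
    for _ in range(max_probes):
        mid = (lo + hi) / 2.0
        labels, achieved = probe(mid)
        gap = abs(achieved - target_S)
        if best is None or gap < best[0]:
            best = (gap, labels, mid)
        if achieved == target_S:
            break
        if achieved < target_S:
            lo = mid
        else:
            hi = mid
    assert best is not None
    _, labels, preference = best
    return labels, len(set(labels)), preference


def run_algorithm(features: FeatureMatrix, spec: AlgorithmSpec) -> RunRecord:
    """Run one algorithm at its target S; deterministic given the seed."""
    X = features.values
    if features.M < spec.target_S:
        raise ValidationError(
            f"cannot form {spec.target_S} clusters from {features.M} points"
        )
    if features.M == spec.target_S:
        # forced partition: every point its own cluster, no algorithmic freedom
        partition = Partition({p: i for i, p in enumerate(features.point_ids)})
        return RunRecord(spec=spec, partition=partition, achieved_S=features.M)
    run_warnings: list[str] = []
    params: dict = {}
    family, metric = ALGORITHM_CODES[spec.code]
    try:
        if family.startswith("linkage-"):
            linkage = family.split("-", 1)[1]
            model = AgglomerativeClustering(
                n_clusters=spec.target_S,
                metric=_SKLEARN_METRIC[metric],
                linkage=linkage,
            )
            labels = model.fit_predict(X)
        elif family == "kmeans" and metric == "l2":
            for attempt in range(3):
                model = KMeans(
                    n_clusters=spec.target_S,
                    random_state=spec.seed + attempt,
                    n_init=10,
                )
                labels = model.fit_predict(X)
                if len(set(labels)) == spec.target_S:
                    break
            else:
                raise AlgorithmFailure(f"{spec.code}: empty clusters after 3 seeds")
        elif family == "kmeans":  # l1 -> k-medians
            for attempt in range(3):
                labels = _kmedians(X, spec.target_S, seed=spec.seed + attempt)
                if len(set(labels)) == spec.target_S:
                    break
            else:
                raise AlgorithmFailure(f"{spec.code}: empty clusters after 3 seeds")
        elif family == "affinity":
            labels, achieved, preference = _affinity_bisection(
                X, spec.target_S, seed=spec.seed
            )
            params["preference"] = preference
            if achieved != spec.target_S:
                run_warnings.append(
                    f"affinity propagation reached S={achieved}, target was {spec.target_S}"
                )
        elif family == "birch":
            model = Birch(n_clusters=spec.target_S)  # default threshold
            params["threshold"] = model.threshold
            labels = model.fit_predict(X)
        elif family == "spectral":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = SpectralClustering(
                    n_clusters=spec.target_S,
                    random_state=spec.seed,
                    assign_labels="kmeans",
                )
                labels = model.fit_predict(X)
        else:  # pragma: no cover - exhaustive over ALGORITHM_CODES
            raise AlgorithmFailure(f"unhandled family {family!r}")
    except AlgorithmFailure:
        raise
    except Exception as exc:
        raise AlgorithmFailure(f"{spec.code} failed: {exc}") from exc

    partition = Partition(dict(zip(features.point_ids, [int(l) for l in labels])))
    return RunRecord(
        spec=spec,
        partition=partition,
        achieved_S=partition.S,
        warnings=tuple(run_warnings),
        params=params,
    )


def run_battery(
    features: FeatureMatrix,
    specs: list[AlgorithmSpec],
    truth: GroundTruth | None = None,
    entropy_base: float = 2.0,
) -> tuple[Scoreboard, list[RunRecord]]:
    """Run every spec and score each resulting partition.

    Every run is scored by partition entropy; by purity/NMI/ARI when a ground
    truth is supplied; and by silhouette / Davies-Bouldin on the features,
    under the run's own distance metric (l2 for metric-free algorithms).
    Failed runs are excluded with a logged reason, never silently scored.
    """
    if not specs:
        raise ValidationError("empty battery")
    rows: dict[str, dict[str, float]] = {}
    records: list[RunRecord] = []
    for spec in specs:
        try:
            record = run_algorithm(features, spec)
            geo_metric = spec.metric or "l2"
            row = {
                "entropy": infomax.score_partition(
                    record.partition, base=entropy_base
                ).value,
                "sh": geometry.silhouette(features, record.partition, geo_metric),
                "db": geometry.davies_bouldin(features, record.partition, geo_metric),
            }
            if truth is not None:
                table = agreement.contingency(record.partition, truth)
                row["purity"] = agreement.purity(table)
                row["nmi"] = agreement.nmi(table)
                row["ari"] = agreement.ari(table)
        except (AlgorithmFailure, DegenerateInputError) as exc:
            logger.warning("excluding %s from scoreboard: %s", spec.code, exc)
            continue
        records.append(record)
        rows[spec.code] = row
        for message in record.warnings:
            logger.warning("%s: %s", spec.code, message)
    if not rows:
        raise AlgorithmFailure("all battery runs failed")
    columns = ["entropy"]
    if truth is not None:
        columns += ["purity", "nmi", "ari"]
    columns += ["sh", "db"]
    board = Scoreboard(pd.DataFrame(rows).T[columns])
    return board, records
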