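"""Seeded synthetic datasets spanning the ground-truth structures of interest.

Two generators:

* :func:`gaussian_mixture` — M points in R^d drawn from S isotropic
  unit-variance Gaussian components whose nearest centroids are ``separation``
  standard deviations apart.  Cluster sizes follow a profile: ``equal``
  (Leaf-like: S clusters of near-identical size), ``zipf:a`` (skewed,
  Protein-like), or an explicit size list.  The default profile is
  ``zipf:1.2``, emulating a skewed ground truth.
* :func:`planted_partition_graph` — a stochastic block model with
  within-community edge probability ``p_in`` above the between-community
  ``p_out`` (Football/Railway-like community structure).

Graph vertices carry no intrinsic features, so two featurizations turn a
graph into a feature matrix: the binary neighborhood indicator vector and the
unweighted shortest-path-length vector of each vertex (self entry 0 in both).

Every generator is a pure function of its config, seed included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import DegenerateInputError, ValidationError
from .partition_io import FeatureMatrix, GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureConfig",
    "PlantedGraphConfig",
    "gaussian_mixture",
    "planted_partition_graph",
    "neighborhood_features",
    "shortest_path_features",
]


@dataclass(frozen=True)
class MixtureConfig:
    """Configuration of a Gaussian-mixture benchmark dataset.

    ``separation`` is the nearest-centroid spacing in units of the component
    standard deviation (components are isotropic with unit variance).
    """

    M: int
    S: int
    d: int = 10
    size_profile: str | Sequence[int] = "zipf:1.2"
    separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S > self.M:
            raise ValidationError("more clusters than points")
        if self.S < 1 or self.M < 1 or self.d < 1:
            raise ValidationError("M, S, d must be positive")
        if self.separation <= 0:
            raise ValidationError("separation must be positive")

    def sizes(self) -> list[int]:
        """Cluster sizes implied by the profile; sum to M, each >= 1."""
        profile = self.size_profile
        if not isinstance(profile, str):
            sizes = [int(k) for k in profile]
            if any(k < 1 for k in sizes):
                raise ValidationError("explicit sizes must be >= 1")
            if sum(sizes) != self.M or len(sizes) != self.S:
                raise ValidationError("explicit sizes must sum to M with S entries")
            return sizes
        if profile == "equal":
            weights = np.ones(self.S)
        elif profile.startswith("zipf"):
            exponent = float(profile.split(":", 1)[1]) if ":" in profile else 1.0
            weights = 1.0 / np.arange(1, self.S + 1) ** exponent
        else:
            raise ValidationError(f"unknown size profile {profile!r}")
        return _apportion(self.M, weights)


def _apportion(M: int, weights: np.ndarray) -> list[int]:
    """Largest-remainder allocation of M points to weights, minimum 1 each."""
    S = len(weights)
    if M < S:
        raise ValidationError("cannot give every cluster at least one point")
    quota = weights / weights.sum() * (M - S)  # reserve one point per cluster
    sizes = np.floor(quota).astype(int) + 1
    remainder = M - sizes.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    for i in range(remainder):
        sizes[order[i % S]] += 1
    return [int(k) for k in sizes]


def _simplex_centroids(S: int, d: int, separation: float) -> np.ndarray:
    """Vertices of a regular (S-1)-simplex with edge length = separation."""
    # Regular simplex from the identity, centered; pairwise distance sqrt(2).
    V = np.eye(S) - 1.0 / S
    # Reduce to its intrinsic S-1 dimensions.
    _, _, vt = np.linalg.svd(V, full_matrices=False)
    coords = V @ vt[: S - 1].T if S > 1 else np.zeros((1, 1))
    coords *= separation / np.sqrt(2.0)
    out = np.zeros((S, d))
    out[:, : coords.shape[1]] = coords
    return out


def _rejection_centroids(
    S: int, d: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Random centroids with enforced minimum spacing, grown box on failure."""
    box = separation * max(2.0, S ** (1.0 / d))
    while True:
        accepted: list[np.ndarray] = []
        for _ in range(200 * S):
            candidate = rng.uniform(-box, box, size=d)
            if all(np.linalg.norm(candidate - c) >= separation for c in accepted):
                accepted.append(candidate)
                if len(accepted) == S:
                    return np.vstack(accepted)
        box *= 1.5  # too crowded; retry in a larger box


def gaussian_mixture(config: MixtureConfig) -> tuple[FeatureMatrix, GroundTruth]:
    """Sample a seeded Gaussian-mixture dataset with planted labels.

    Centroids sit on a regular simplex (exact spacing) when ``S <= d + 1``,
    otherwise at rejection-sampled positions at least ``separation`` apart.
    Components are isotropic Gaussians of unit standard deviation.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes()
    if config.S <= config.d + 1:
        centroids = _simplex_centroids(config.S, config.d, config.separation)
    else:
        centroids = _rejection_centroids(config.S, config.d, config.separation, rng)
    width = len(str(config.M - 1))
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: dict[str, str] = {}
    point = 0
    for cluster, size in enumerate(sizes):
        samples = rng.normal(loc=centroids[cluster], scale=1.0, size=(size, config.d))
        for row in samples:
            pid = f"p{point:0{width}d}"
            ids.append(pid)
            rows.append(row)
            labels[pid] = f"c{cluster}"
            point += 1
    return FeatureMatrix(tuple(ids), np.vstack(rows)), GroundTruth(labels)


@dataclass(frozen=True)
class PlantedGraphConfig:
    """Configuration of a planted-partition (stochastic block model) graph."""

    community_sizes: Sequence[int]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.community_sizes or any(s < 1 for s in self.community_sizes):
            raise ValidationError("community sizes must be positive")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValidationError("need 0 <= p_out < p_in <= 1")


def planted_partition_graph(
    config: PlantedGraphConfig,
) -> tuple[nx.Graph, GroundTruth]:
    """Sample a planted-partition graph with its community ground truth.

    Each within-community vertex pair is joined with probability ``p_in``,
    each between-community pair with ``p_out``; no self-loops.
    """
    sizes = [int(s) for s in config.community_sizes]
    B = len(sizes)
    p = np.full((B, B), config.p_out)
    np.fill_diagonal(p, config.p_in)
    raw = nx.stochastic_block_model(sizes, p.tolist(), seed=int(config.seed))
    n = sum(sizes)
    width = len(str(n - 1))
    rename = {node: f"v{node:0{width}d}" for node in raw.nodes}
    graph = nx.relabel_nodes(nx.Graph(raw.edges), rename)
    graph.add_nodes_from(rename.values())  # keep isolated vertices
    truth = {
        rename[node]: f"c{block}" for node, block in raw.nodes(data="block")
    }
    return graph, GroundTruth(truth)


def _canonical_order(graph: nx.Graph) -> list:
    return sorted(graph.nodes, key=str)


def neighborhood_features(graph: nx.Graph) -> FeatureMatrix:
    """Binary adjacency-indicator vector per vertex (self entry 0)."""
    if graph.number_of_nodes() < 2:
        raise ValidationError("need at least 2 vertices to featurize")
    order = _canonical_order(graph)
    A = nx.to_numpy_array(graph, nodelist=order, weight=None)
    np.fill_diagonal(A, 0.0)
    return FeatureMatrix(tuple(str(v) for v in order), (A > 0).astype(float))


def shortest_path_features(
    graph: nx.Graph, impute_diameter_plus_one: bool = False
) -> FeatureMatrix:
    """Unweighted shortest-path-length vector per vertex (self entry 0).

    Edge weights are ignored (hop counts).  A disconnected graph is an error
    unless ``impute_diameter_plus_one`` is set, in which case unreachable
    entries take the value (largest finite eccentricity) + 1.
    """
    if graph.number_of_nodes() < 2:
        raise ValidationError("need at least 2 vertices to featurize")
    order = _canonical_order(graph)
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, hops in lengths.items():
            D[index[source], index[target]] = hops
    if np.isinf(D).any():
        if not impute_diameter_plus_one:
            raise DegenerateInputError(
                "graph is disconnected; shortest-path features undefined "
                "(enable diameter+1 imputation to proceed)"
            )
        finite = D[np.isfinite(D)]
        fill = float(finite.max()) + 1.0
        D[np.isinf(D)] = fill
        logger.warning(
            "disconnected graph: unreachable distances imputed as %.0f", fill
        )
    return FeatureMatrix(tuple(str(v) for v in order), D)
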