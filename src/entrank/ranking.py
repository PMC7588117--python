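"""Rank aggregation and ranking comparison.

A :class:`Scoreboard` holds one value per (algorithm, metric) for a single
dataset at a fixed target cluster count.  Each metric induces a ranking of
the algorithms (rank 1 = best, exact ties averaged); the direction tag on the
metric decides whether larger or smaller values are better, so Davies-Bouldin
correlates positively with the external indices after direction handling.

The *majority ranking* aggregates the three external indices (purity, NMI,
ARI) pairwise: algorithm A precedes B when a strict majority (>= 2 of 3)
scores A strictly higher; a metric scoring the pair equal abstains; a pair
with no 2-vote winner is a tie.  The strict-win digraph can be intransitive
(a Condorcet cycle), in which case no proper ranking exists — cycles are
enumerated and aggregation refuses unless the Copeland override is forced.
With a transitive relation the Copeland count (wins + half-ties) reproduces
the unique topological order.

Rankings are compared by tie-corrected Kendall tau-b and Spearman rho.  Both
are implemented directly from their definitions so an external library can
act as an independent check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CyclicRelationError, DegenerateInputError, ValidationError

__all__ = [
    "DEFAULT_DIRECTIONS",
    "EXTERNAL_METRICS",
    "Scoreboard",
    "RankVector",
    "MajorityRelation",
    "CorrelationReport",
    "RegressionResult",
    "rank_by_metric",
    "majority_relation",
    "majority_ranking",
    "kendall_tau",
    "spearman_rho",
    "correlation_matrix",
    "complexity_regression",
]

#: Direction tags for the metrics the toolkit produces.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "entropy": "higher",
    "purity": "higher",
    "nmi": "higher",
    "ari": "higher",
    "sh": "higher",
    "db": "lower",
}

EXTERNAL_METRICS = ("purity", "nmi", "ari")


@dataclass(frozen=True)
class Scoreboard:
    """Per-algorithm metric values on one dataset at fixed S."""

    values: pd.DataFrame  # index: algorithms, columns: metrics
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = pd.DataFrame(self.values).astype(float)
        if values.empty:
            raise ValidationError("empty scoreboard")
        if values.isna().any().any():
            raise ValidationError("scoreboard has missing cells")
        if not np.isfinite(values.to_numpy()).all():
            raise ValidationError("scoreboard has non-finite values")
        directions = dict(self.directions)
        for metric in values.columns:
            directions.setdefault(metric, DEFAULT_DIRECTIONS.get(metric, ""))
            if directions[metric] not in ("higher", "lower"):
                raise ValidationError(
                    f"metric {metric!r} needs a direction tag ('higher' or 'lower')"
                )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "directions", directions)

    @property
    def algorithms(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass(frozen=True)
class RankVector:
    """A tie-averaged ranking of algorithms; rank 1 is best."""

    ranks: Mapping[str, float]

    def __post_init__(self) -> None:
        ranks = {str(k): float(v) for k, v in dict(self.ranks).items()}
        if not ranks:
            raise ValidationError("empty rank vector")
        n = len(ranks)
        if abs(sum(ranks.values()) - n * (n + 1) / 2) > 1e-9:
            raise ValidationError("ranks are not a tie-averaged permutation of 1..n")
        object.__setattr__(self, "ranks", ranks)

    @property
    def algorithms(self) -> frozenset[str]:
        return frozenset(self.ranks)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.ranks[a] for a in order], dtype=float)


def rank_by_metric(board: Scoreboard, metric: str) -> RankVector:
    """Ranking induced by one metric; direction-aware, ties averaged."""
    if metric not in board.values.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    column = board.values[metric].to_numpy()
    keys = -column if board.directions[metric] == "higher" else column
    ranks = rankdata(keys, method="average")
    return RankVector(dict(zip(board.algorithms, ranks)))


@dataclass(frozen=True)
class MajorityRelation:
    """Pairwise majority outcomes over the external indices.

    ``wins[(a, b)]`` (one entry per unordered pair, a before b in board
    order) is ``a``, ``b`` or ``None`` (tie).  ``cycles`` lists directed
    cycles of the strict-win digraph; the relation is transitive iff empty.
    """

    algorithms: tuple[str, ...]
    wins: Mapping[tuple[str, str], str | None]
    cycles: tuple[tuple[str, ...], ...]

    @property
    def transitive(self) -> bool:
        return not self.cycles

    def winner(self, a: str, b: str) -> str | None:
        if (a, b) in self.wins:
            return self.wins[(a, b)]
        return self.wins[(b, a)]

    def copeland_scores(self) -> dict[str, float]:
        """Pairwise wins, counting a tie as half a point for each side."""
        scores = {a: 0.0 for a in self.algorithms}
        for (a, b), winner in self.wins.items():
            if winner is None:
                scores[a] += 0.5
                scores[b] += 0.5
            else:
                scores[winner] += 1.0
        return scores


def majority_relation(board: Scoreboard) -> MajorityRelation:
    """Pairwise majority over {purity, NMI, ARI}.

    For each pair, each external metric votes for the algorithm it scores
    strictly higher (equal scores: abstain).  An algorithm needs >= 2 votes
    to win the pair; otherwise the pair is a tie.
    """
    missing = [m for m in EXTERNAL_METRICS if m not in board.values.columns]
    if missing:
        raise ValidationError(f"majority relation needs external metrics {missing}")
    algorithms = board.algorithms
    wins: dict[tuple[str, str], str | None] = {}
    digraph = nx.DiGraph()
    digraph.add_nodes_from(algorithms)
    for a, b in itertools.combinations(algorithms, 2):
        votes_a = votes_b = 0
        for metric in EXTERNAL_METRICS:
            va = board.values.at[a, metric]
            vb = board.values.at[b, metric]
            if va > vb:
                votes_a += 1
            elif vb > va:
                votes_b += 1
        if votes_a >= 2:
            wins[(a, b)] = a
            digraph.add_edge(a, b)
        elif votes_b >= 2:
            wins[(a, b)] = b
            digraph.add_edge(b, a)
        else:
            wins[(a, b)] = None
    cycles = tuple(tuple(c) for c in nx.simple_cycles(digraph))
    return MajorityRelation(algorithms=algorithms, wins=wins, cycles=cycles)


def majority_ranking(
    relation: MajorityRelation, force_copeland: bool = False
) -> RankVector:
    """Materialize the majority relation as a ranking via Copeland counts.

    Refuses intransitive relations (cycles listed in the error) unless
    ``force_copeland`` is set, in which case the Copeland order is returned
    with a warning — a cyclic relation admits no proper ranking.
    """
    if not relation.transitive:
        if not force_copeland:
            raise CyclicRelationError(relation.cycles)
        warnings.warn(
            f"majority relation has {len(relation.cycles)} Condorcet cycle(s); "
            "Copeland order is a forced tie-break, not a proper ranking",
            UserWarning,
            stacklevel=2,
        )
    scores = relation.copeland_scores()
    order = list(relation.algorithms)
    ranks = rankdata([-scores[a] for a in order], method="average")
    return RankVector(dict(zip(order, ranks)))


def _paired(r1: RankVector, r2: RankVector) -> tuple[np.ndarray, np.ndarray]:
    if r1.algorithms != r2.algorithms:
        raise ValidationError("rank vectors cover different algorithm sets")
    if len(r1.ranks) < 2:
        raise DegenerateInputError("rank correlation needs at least 2 items")
    order = sorted(r1.algorithms)
    return r1.as_array(order), r2.as_array(order)


def kendall_tau(r1: RankVector, r2: RankVector) -> float:
    """Tie-corrected Kendall tau-b between two rankings; in [-1, 1].

    tau_b = (C - D) / sqrt((n0 - t1)(n0 - t2)) with C/D the concordant and
    discordant pair counts, n0 = n(n-1)/2 and t1, t2 the pairs tied within
    each ranking.  Undefined (error) when either ranking is fully tied.
    """
    x, y = _paired(r1, r2)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        raise DegenerateInputError("tau-b undefined: a ranking is fully tied")
    return (concordant - discordant) / denom


def spearman_rho(r1: RankVector, r2: RankVector) -> float:
    """Spearman rho: Pearson correlation of the tie-averaged ranks."""
    x, y = _paired(r1, r2)
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        raise DegenerateInputError("rho undefined: a ranking has zero variance")
    return float((sx * sy).sum() / denom)


@dataclass(frozen=True)
class CorrelationReport:
    """(tau, rho) for every pair of ranking criteria; symmetric, unit diagonal."""

    criteria: tuple[str, ...]
    tau: pd.DataFrame
    rho: pd.DataFrame

    def pair(self, c1: str, c2: str) -> tuple[float, float]:
        return float(self.tau.at[c1, c2]), float(self.rho.at[c1, c2])

    def to_frame(self) -> pd.DataFrame:
        """Human-readable 'tau,rho' table in the 2-decimal table convention."""
        data = {
            c2: [f"{self.tau.at[c1, c2]:.2f},{self.rho.at[c1, c2]:.2f}" for c1 in self.criteria]
            for c2 in self.criteria
        }
        return pd.DataFrame(data, index=list(self.criteria))


def correlation_matrix(
    board: Scoreboard, force_copeland: bool = False
) -> CorrelationReport:
    """Pairwise (tau, rho) among every metric ranking plus the majority ranking."""
    rankings: dict[str, RankVector] = {
        metric: rank_by_metric(board, metric) for metric in board.metrics
    }
    rankings["majority"] = majority_ranking(
        majority_relation(board), force_copeland=force_copeland
    )
    criteria = tuple(rankings)
    tau = pd.DataFrame(np.eye(len(criteria)), index=criteria, columns=criteria)
    rho = pd.DataFrame(np.eye(len(criteria)), index=criteria, columns=criteria)
    for c1, c2 in itertools.combinations(criteria, 2):
        try:
            t = kendall_tau(rankings[c1], rankings[c2])
            r = spearman_rho(rankings[c1], rankings[c2])
        except DegenerateInputError:
            # a fully tied ranking (e.g. every algorithm scored equal) leaves
            # the correlation undefined; reported as NaN, not an error
            t = r = float("nan")
        tau.loc[c1, c2] = tau.loc[c2, c1] = t
        rho.loc[c1, c2] = rho.loc[c2, c1] = r
    return CorrelationReport(criteria=criteria, tau=tau, rho=rho)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a performance number on the complexity pair (q1, q2)."""

    intercept: float
    coef_q1: float
    coef_q2: float
    r_squared: float
    collinear: bool

    def predict(self, q1: float, q2: float) -> float:
        return self.intercept + self.coef_q1 * q1 + self.coef_q2 * q2


def complexity_regression(
    points: Iterable[tuple[float, float, float]]
) -> RegressionResult:
    """Ordinary least squares of performance on (q1, q2) with intercept.

    ``points`` are (q1, q2, performance) triples, one per dataset.  Collinear
    design matrices are flagged and solved by the minimum-norm least-squares
    solution.  R^2 = 1 - SS_res / SS_tot, with the convention R^2 = 0 for a
    constant response.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValidationError("need at least 3 (q1, q2, performance) points")
    X = np.column_stack([np.ones(len(pts)), pts[:, 0], pts[:, 1]])
    y = pts[:, 2]
    collinear = np.linalg.matrix_rank(X) < 3
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ beta
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionResult(
        intercept=float(beta[0]),
        coef_q1=float(beta[1]),
        coef_q2=float(beta[2]),
        r_squared=r_squared,
        collinear=bool(collinear),
    )
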