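"""External (supervised) cluster validity indices on a contingency table.

Given a clustering Omega = (w_1..w_K) and a reference classification
C = (c_1..c_J) of the same N points, all four indices here are functions of
the contingency counts n_kj = |w_k ∩ c_j| with margins a_k (cluster sizes)
and b_j (class sizes):

* purity  = (1/N) sum_k max_j n_kj
* I(Omega, C) = sum_kj (n_kj/N) log( N n_kj / (a_k b_j) )
* NMI = 2 I / (H(Omega) + H(C))           (arithmetic-mean normalization)
* ARI = adjusted Rand index, the pair-counting Rand index corrected for
  chance via the hypergeometric expectation; computed in exact integer /
  rational arithmetic to avoid cancellation on near-random tables.

A brute-force pair-counting oracle over all C(N,2) point pairs is included
for testing the closed-form ARI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .partition_io import GroundTruth, Partition, align

__all__ = [
    "ContingencyTable",
    "contingency",
    "purity",
    "mutual_information",
    "nmi",
    "ari",
    "pair_counting_oracle",
    "PairCounts",
]


@dataclass(frozen=True)
class ContingencyTable:
    """K x J overlap counts between clusters (rows) and classes (columns)."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValidationError("contingency counts must be 2-D")
        if (counts < 0).any():
            raise ValidationError("contingency counts must be nonnegative")
        if counts.sum() < 1:
            raise ValidationError("contingency table is empty")
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            raise ValidationError("empty row or column in contingency table")
        object.__setattr__(self, "counts", counts)

    @property
    def row_margins(self) -> np.ndarray:
        """Cluster sizes a_k."""
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """Class sizes b_j."""
        return self.counts.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def contingency(partition: Partition, truth: GroundTruth) -> ContingencyTable:
    """Contingency table of a partition against a ground truth.

    Point sets are aligned on shared ids first (see :func:`partition_io.align`).
    """
    aligned = align(partition, truth)
    row_labels = tuple(sorted(set(aligned.partition_labels), key=str))
    col_labels = tuple(sorted(set(aligned.truth_labels), key=str))
    r_index = {lab: i for i, lab in enumerate(row_labels)}
    c_index = {lab: j for j, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for p_lab, t_lab in zip(aligned.partition_labels, aligned.truth_labels):
        counts[r_index[p_lab], c_index[t_lab]] += 1
    return ContingencyTable(counts, row_labels, col_labels)


def purity(table: ContingencyTable) -> float:
    """Fraction of points in the majority class of their cluster; in (0, 1]."""
    return float(table.counts.max(axis=1).sum() / table.N)


def _margin_entropy(margin: np.ndarray, N: int, base: float) -> float:
    p = margin[margin > 0] / N
    return float(-(p * (np.log(p) / math.log(base))).sum())


def mutual_information(table: ContingencyTable, base: float = 2.0) -> float:
    """Mutual information between cluster and class labels.

    Terms with ``n_kj = 0`` contribute 0 (the 0 log 0 convention).
    """
    N = table.N
    a = table.row_margins
    b = table.col_margins
    total = 0.0
    for k, j in zip(*np.nonzero(table.counts)):
        n_kj = table.counts[k, j]
        total += (n_kj / N) * math.log(N * n_kj / (a[k] * b[j]), base)
    # floating round-off can leave a tiny negative residue on product tables
    return max(total, 0.0) if total > -1e-12 else total


def nmi(table: ContingencyTable) -> float:
    """Normalized mutual information, 2 I / (H(Omega) + H(C)); in [0, 1].

    The log base cancels.  Undefined (error) when both marginal entropies are
    zero, i.e. a 1 x 1 table.
    """
    h_rows = _margin_entropy(table.row_margins, table.N, 2.0)
    h_cols = _margin_entropy(table.col_margins, table.N, 2.0)
    if h_rows + h_cols == 0.0:
        raise DegenerateInputError(
            "NMI undefined: both partitions have a single block"
        )
    return 2.0 * mutual_information(table, base=2.0) / (h_rows + h_cols)


def _is_diagonal_equivalent(counts: np.ndarray) -> bool:
    """True when every row and every column has exactly one nonzero entry."""
    return bool(
        ((counts > 0).sum(axis=1) == 1).all() and ((counts > 0).sum(axis=0) == 1).all()
    )


def ari(table: ContingencyTable) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 for random ones.

    Evaluated in exact rational arithmetic:

        ARI = [ sum_kj C(n_kj,2) - E ] / [ (sum_k C(a_k,2) + sum_j C(b_j,2))/2 - E ]

    with ``E = sum_k C(a_k,2) sum_j C(b_j,2) / C(N,2)``.  When the denominator
    vanishes (both partitions all-singletons or all-one-cluster) the value is
    1 if the two partitions are identical, otherwise undefined (error).
    """
    N = table.N
    if N < 2:
        raise DegenerateInputError("ARI undefined for fewer than 2 points")
    index = sum(math.comb(int(n), 2) for n in table.counts.ravel())
    sum_a = sum(math.comb(int(x), 2) for x in table.row_margins)
    sum_b = sum(math.comb(int(x), 2) for x in table.col_margins)
    expected = Fraction(sum_a * sum_b, math.comb(N, 2))
    denominator = Fraction(sum_a + sum_b, 2) - expected
    if denominator == 0:
        if _is_diagonal_equivalent(table.counts):
            return 1.0
        raise DegenerateInputError(
            "ARI undefined: degenerate margins and partitions not identical"
        )
    return float(Fraction(index) - expected) / float(denominator)


class PairCounts(NamedTuple):
    together_both: int
    apart_both: int
    disagreements: int
    ari_value: float


def pair_counting_oracle(partition: Partition, truth: GroundTruth) -> PairCounts:
    """Brute-force ARI by iterating every pair of points (test oracle).

    O(N^2); intended for N up to ~10^3.  ``ari_value`` must match
    :func:`ari` on the corresponding contingency table to ~1e-12.
    """
    aligned = align(partition, truth)
    p = aligned.partition_labels
    t = aligned.truth_labels
    n = len(p)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_p = p[i] == p[j]
            same_t = t[i] == t[j]
            if same_p and same_t:
                n11 += 1
            elif not same_p and not same_t:
                n00 += 1
            elif same_p:
                n10 += 1
            else:
                n01 += 1
    numerator = 2 * (n11 * n00 - n10 * n01)
    denominator = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denominator == 0:
        value = 1.0 if (n10 + n01) == 0 else float("nan")
    else:
        value = numerator / denominator
    return PairCounts(n11, n00, n10 + n01, value)
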