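"""Partition entropy (the Infomax score) and dataset-complexity summaries.

A hard partition of ``M`` points into clusters of sizes ``K_s`` can be read as
a message over an alphabet of ``S`` symbols with frequencies ``K_s / M``.  Its
Shannon entropy

    H[s] = -sum_s (K_s / M) log(K_s / M)

measures how much information the labelling retains about the data: for hard
clustering the conditional entropy H[s|x] vanishes, so the mutual information
between data and labels reduces to H[s].  The Infomax principle then says:
among algorithms producing the same number of clusters on the same data,
prefer the one with the larger H[s].  That rule needs no ground truth, which
is the whole point.

Two normalized complexity summaries of a ground-truth classification are also
provided: ``q1 = H / log M`` and ``q2 = H / log S``; both are base-free and in
[0, 1], with q2 = 1 exactly for equally sized clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import entropy as _shannon_entropy

from .errors import DegenerateInputError, ValidationError
from .partition_io import Partition

__all__ = [
    "EntropyScore",
    "ComplexitySummary",
    "partition_entropy",
    "score_partition",
    "complexity",
    "infomax_rank",
]


@dataclass(frozen=True)
class EntropyScore:
    """Entropy of a cluster-size distribution, in the requested log base."""

    value: float
    base: float
    S_effective: int
    M: int

    def in_base(self, base: float) -> float:
        """The same entropy converted to another log base."""
        return self.value * math.log(self.base) / math.log(base)


@dataclass(frozen=True)
class ComplexitySummary:
    """Base-free normalizations of a ground-truth entropy.

    q1 = H / log M (concentration relative to the number of points),
    q2 = H / log S (concentration relative to the number of clusters).
    """

    q1: float
    q2: float


def partition_entropy(sizes: Iterable[int], base: float = 2.0) -> EntropyScore:
    """Shannon entropy of the cluster-size distribution ``{K_s}``.

    Parameters
    ----------
    sizes
        Multiset of positive integer cluster sizes.
    base
        Logarithm base; 2 (bits) by default.

    Returns
    -------
    EntropyScore
        With ``0 <= value <= log_base(S)``, and 0 iff a single cluster.
    """
    sizes = [int(k) for k in sizes]
    if not sizes:
        raise ValidationError("empty size multiset")
    if any(k <= 0 for k in sizes):
        raise ValidationError(f"cluster sizes must be positive, got {sizes}")
    value = float(_shannon_entropy(sizes, base=base))
    return EntropyScore(value=value, base=base, S_effective=len(sizes), M=sum(sizes))


def score_partition(partition: Partition, base: float = 2.0) -> EntropyScore:
    """Convenience wrapper: entropy of a :class:`Partition`'s size multiset."""
    return partition_entropy(partition.sizes().values(), base=base)


def complexity(score: EntropyScore) -> ComplexitySummary:
    """Normalized complexity (q1, q2) of an entropy score.

    Undefined when ``M = 1`` (q1 denominator) or ``S = 1`` (q2 denominator).
    The log base cancels, so the result does not depend on ``score.base``.
    """
    if score.M < 2:
        raise DegenerateInputError("q1 undefined for M < 2 (log M = 0)")
    if score.S_effective < 2:
        raise DegenerateInputError("q2 undefined for S < 2 (log S = 0)")
    h_nats = score.value * math.log(score.base)
    return ComplexitySummary(
        q1=h_nats / math.log(score.M),
        q2=h_nats / math.log(score.S_effective),
    )


def infomax_rank(
    partitions: Mapping[str, Partition], base: float = 2.0
) -> list[tuple[str, EntropyScore]]:
    """Rank algorithms by partition entropy, highest first.

    All partitions must cover the same point set.  The comparison is stated
    for a fixed number of clusters; when the partitions' S values differ a
    ``UserWarning`` is emitted (the ordering is still returned).  Exact ties
    are kept adjacent in input order and share a rank implicitly (equal
    entropy values).
    """
    if not partitions:
        raise ValidationError("no partitions to rank")
    names = list(partitions)
    ids0 = partitions[names[0]].point_ids
    for name in names[1:]:
        if partitions[name].point_ids != ids0:
            raise ValidationError(
                f"partition {name!r} covers a different point set than {names[0]!r}"
            )
    s_values = {name: partitions[name].S for name in names}
    if len(set(s_values.values())) > 1:
        warnings.warn(
            "partitions have differing cluster counts "
            f"{s_values}; the entropy comparison is stated for a fixed S",
            UserWarning,
            stacklevel=2,
        )
    scored = [(name, score_partition(partitions[name], base=base)) for name in names]
    scored.sort(key=lambda item: -item[1].value)
    return scored
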