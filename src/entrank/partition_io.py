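"""Domain containers and delimited-text I/O.

The toolkit manipulates three kinds of objects: a feature matrix (``M`` points
in ``R^d``), hard partitions of those points (cluster labels), and undirected
graphs (for the network use case, where vertices are later featurized).  All
on-disk formats are plain UTF-8 delimited text; graphs live in
:class:`networkx.Graph` containers.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "Partition",
    "GroundTruth",
    "AlignedLabels",
    "read_feature_matrix",
    "read_labels",
    "read_ground_truth",
    "write_labels",
    "read_edge_list",
    "align",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """``M`` points with ``d`` real-valued features each.

    ``point_ids`` are opaque strings used to join against label tables; when a
    file carries no id column they default to 0-based row indices.
    """

    point_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("feature values must be a 2-D array")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "point_ids", tuple(str(p) for p in self.point_ids))
        if len(self.point_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.point_ids)} ids for {values.shape[0]} rows"
            )
        if len(set(self.point_ids)) != len(self.point_ids):
            raise ValidationError("point ids must be unique")
        if values.shape[0] < 1:
            raise ValidationError("need at least one point")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite feature value at row {bad[0]}, column {bad[1]}"
            )

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.point_ids)}


@dataclass(frozen=True)
class Partition:
    """A hard assignment of point ids to cluster labels.

    Labels are opaque and hashable; every downstream metric is invariant to
    relabeling.  Cluster sizes ``K_s`` are all >= 1 by construction (a label
    is only "present" if some point carries it).
    """

    assignment: Mapping[str, object]

    def __post_init__(self) -> None:
        mapping = {str(k): v for k, v in dict(self.assignment).items()}
        if not mapping:
            raise ValidationError("a partition must cover at least one point")
        object.__setattr__(self, "assignment", mapping)

    @property
    def M(self) -> int:
        return len(self.assignment)

    @property
    def S(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def point_ids(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def sizes(self) -> Counter:
        """Multiset of cluster sizes ``{label: K_s}``."""
        return Counter(self.assignment.values())

    def labels_for(self, ids: Sequence[str]) -> list:
        return [self.assignment[i] for i in ids]


class GroundTruth(Partition):
    """A reference classification; structurally identical to a partition."""


class AlignedLabels(NamedTuple):
    """Paired label sequences over the shared ids, in canonical (sorted) order."""

    ids: tuple[str, ...]
    partition_labels: tuple
    truth_labels: tuple
    missing_from_partition: tuple[str, ...]
    missing_from_truth: tuple[str, ...]


def read_feature_matrix(
    path,
    delimiter: str = ",",
    header: bool = False,
    id_column: str | None = None,
) -> FeatureMatrix:
    """Read a delimited numeric table, one row per point.

    ``id_column`` names the column holding point ids (requires ``header``);
    otherwise ids are 0-based row indices.  Ragged rows and non-numeric or
    non-finite cells are rejected with the offending row/column named.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]  # drop blank lines
    if not rows:
        raise FormatError(f"{path}: empty file")

    colnames: list[str] | None = None
    if header:
        colnames = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: header but no data rows")
    if id_column is not None:
        if colnames is None:
            raise FormatError("id_column requires header=True")
        if id_column not in colnames:
            raise FormatError(f"{path}: no column named {id_column!r}")

    width = len(rows[0])
    id_pos = colnames.index(id_column) if id_column is not None else None
    ids: list[str] = []
    data: list[list[float]] = []
    for r, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {r}: {len(row)} fields, expected {width}"
            )
        vec = []
        for c, cell in enumerate(row):
            if c == id_pos:
                continue
            try:
                x = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
            if not math.isfinite(x):
                raise FormatError(
                    f"{path}: non-finite cell at row {r}, column {c}: {cell!r}"
                )
            vec.append(x)
        ids.append(row[id_pos] if id_pos is not None else str(r))
        data.append(vec)
    return FeatureMatrix(tuple(ids), np.asarray(data, dtype=float))


def _read_two_columns(path, delimiter: str) -> dict[str, str]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r]
    if not rows:
        raise FormatError(f"{path}: empty label file")
    assignment: dict[str, str] = {}
    for r, row in enumerate(rows):
        if len(row) != 2:
            raise FormatError(
                f"{path}: row {r} has {len(row)} fields, expected 2 (id, label)"
            )
        pid, label = row
        if pid in assignment:
            raise FormatError(f"{path}: duplicate point id {pid!r} at row {r}")
        assignment[pid] = label
    return assignment


def read_labels(path, delimiter: str = "\t") -> Partition:
    """Read a two-column (id, label) table as a :class:`Partition`."""
    return Partition(_read_two_columns(path, delimiter))


def read_ground_truth(path, delimiter: str = "\t") -> GroundTruth:
    """Read a two-column (id, label) table as a :class:`GroundTruth`."""
    return GroundTruth(_read_two_columns(path, delimiter))


def write_labels(partition: Partition, path, delimiter: str = "\t") -> None:
    """Write a partition as a two-column table; round-trips exactly.

    Labels containing the delimiter are quoted (csv minimal quoting), so the
    read side always recovers the original strings.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for pid in sorted(partition.assignment):
            writer.writerow([pid, str(partition.assignment[pid])])


def read_edge_list(path) -> nx.Graph:
    """Read a whitespace-separated ``u v [w]`` edge list as an undirected graph.

    Repeated edges collapse with weights summed; self-loops are dropped with a
    warning; negative weights are rejected.  Loading is order-independent.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}: line {lineno}: expected 'u v [w]', got {line!r}"
                )
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) == 3 else 1.0
            if w < 0:
                raise FormatError(f"{path}: line {lineno}: negative weight {w}")
            if u == v:
                logger.warning("%s: line %d: dropping self-loop on %r", path, lineno, u)
                graph.add_node(u)
                continue
            if graph.has_edge(u, v):
                graph[u][v]["weight"] += w
            else:
                graph.add_edge(u, v, weight=w)
    return graph


def align(partition: Partition, truth: GroundTruth) -> AlignedLabels:
    """Pair up labels over the ids shared by a partition and a ground truth.

    The pairing order is the sorted shared-id order (canonical), so repeated
    calls are deterministic.  Ids present on one side only are reported, not
    silently dropped; zero overlap is an error.
    """
    p_ids = set(partition.assignment)
    t_ids = set(truth.assignment)
    shared = sorted(p_ids & t_ids)
    if not shared:
        raise ValidationError("partition and ground truth share no point ids")
    return AlignedLabels(
        ids=tuple(shared),
        partition_labels=tuple(partition.assignment[i] for i in shared),
        truth_labels=tuple(truth.assignment[i] for i in shared),
        missing_from_partition=tuple(sorted(t_ids - p_ids)),
        missing_from_truth=tuple(sorted(p_ids - t_ids)),
    )
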