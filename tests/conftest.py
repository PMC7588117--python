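import numpy as np
import pytest

from entrank import FeatureMatrix, GroundTruth, Partition


@pytest.fixture
def toy_partitions():
    """The 5-point pair of partitions behind the worked contingency table.

    omega = {{1,2,3},{4,5}} against classes c = {{1,2,4},{3,5}}; the
    contingency counts are [[2,1],[1,1]].
    """
    omega = Partition({"1": "A", "2": "A", "3": "A", "4": "B", "5": "B"})
    classes = GroundTruth({"1": "x", "2": "x", "4": "x", "3": "y", "5": "y"})
    return omega, classes


@pytest.fixture
def line_features():
    """Four 1-D points in two well-separated pairs: {0, 2} and {6, 8}."""
    X = np.array([[0.0], [2.0], [6.0], [8.0]])
    matrix = FeatureMatrix(("a", "b", "c", "d"), X)
    partition = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
    return matrix, partition


def random_partition_pair(rng, n_points, max_labels=6):
    """Two random hard partitions of the same points, as label strings."""
    ids = [str(i) for i in range(n_points)]
    p = Partition(dict(zip(ids, rng.integers(0, max_labels, size=n_points))))
    t = GroundTruth(dict(zip(ids, rng.integers(0, max_labels, size=n_points))))
    return p, t
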