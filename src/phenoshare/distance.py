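"""Overlap-coefficient distances between gene sets.

The pairwise distance between two gene sets is one minus the overlap
coefficient::

    d(A, B) = 1 - |A ∩ B| / min(|A|, |B|)

so identical (or nested) sets are at distance 0 and disjoint sets at
distance 1.  Because the denominator is the smaller set, the triangle
inequality can fail on subset chains: the quantity is a dissimilarity, not a
metric, which is all the downstream tree and clustering methods require.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import PreconditionError
from .genesets import GeneSet, GeneSetCollection

_METHODS = ("overlap", "jaccard", "dice")


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise distances with labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric (within 1e-12)")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Return the same matrix with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def allclose(self, other: "DistanceMatrix", atol: float = 1e-9) -> bool:
        if set(self.labels) != set(other.labels):
            return False
        return np.allclose(self.values, other.reorder(self.labels).values, atol=atol)


def set_distance(a: GeneSet, b: GeneSet, method: str = "overlap") -> float:
    """Distance between two gene sets under the chosen coefficient.

    ``overlap`` (the default) divides the shared-gene count by the smaller
    set; ``jaccard`` and ``dice`` are provided as explicit alternatives only.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    if not a.members or not b.members:
        raise PreconditionError("set distance is undefined for empty gene sets")
    shared = len(a.members & b.members)
    if method == "overlap":
        return 1.0 - shared / min(len(a.members), len(b.members))
    if method == "jaccard":
        return 1.0 - shared / len(a.members | b.members)
    return 1.0 - 2.0 * shared / (len(a.members) + len(b.members))


def overlap_distance(a: GeneSet, b: GeneSet) -> float:
    """1 - |A ∩ B| / min(|A|, |B|): 0 iff the smaller set is nested, 1 iff disjoint."""
    return set_distance(a, b, method="overlap")


def distance_matrix(collection: GeneSetCollection, method: str = "overlap") -> DistanceMatrix:
    """Assemble the full symmetric pairwise distance matrix of a collection.

    Label order follows the collection order.  Distinct labels at distance
    zero (duplicate or nested sets) are legal outputs.
    """
    labels = collection.labels
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    sets = collection.sets
    for i, j in combinations(range(n), 2):
        d = set_distance(sets[i], sets[j], method=method)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
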