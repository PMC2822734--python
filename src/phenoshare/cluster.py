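"""Ward minimum-variance hierarchical clustering of gene-set membership vectors.

Gene sets are vectorized as binary membership vectors over the union gene
universe; agglomerative merging then proceeds under Ward's criterion, where
the distance between clusters K and L is the between-cluster ANOVA sum of
squares

    D_KL = ||xbar_K - xbar_L||^2 / (1/N_K + 1/N_L)

(the JMP-manual form), which equals the increase in within-cluster sum of
squares caused by merging K and L.  At each step the pair with minimal D_KL
merges, so the within-cluster sum of squares is minimized over all
partitions obtainable by merging two clusters of the previous generation.

Internally the merge loop updates distances with the Lance-Williams
recurrence for Ward's method (O(n^2) memory, no centroid recomputation);
this is algebraically identical to the direct centroid formula above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import PreconditionError
from .genesets import GeneSetCollection


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters ``a`` and ``b`` (a < b) merge at
    height ``height`` into a cluster of ``size`` observations."""

    a: int
    b: int
    height: float
    size: int


@dataclass
class Dendrogram:
    """Ward merge history over ``n_leaves`` observations.

    Node ids follow the scipy linkage convention: leaves are 0..n-1 and the
    cluster created by merge step m (0-based) has id n + m.  ``labels``
    optionally names the leaves (gene-set labels).
    """

    n_leaves: int
    merges: list[Merge]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError(
                f"expected {self.n_leaves - 1} merges for {self.n_leaves} leaves, "
                f"got {len(self.merges)}"
            )

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """Scipy-style linkage matrix (columns: a, b, height, size)."""
        return np.array(
            [[m.a, m.b, m.height, m.size] for m in self.merges], dtype=float
        )


def membership_matrix(collection: GeneSetCollection) -> tuple[np.ndarray, list[str]]:
    """Binary sets x genes membership matrix with sorted-universe columns.

    Returns the matrix and the gene column order; row order follows the
    collection order, so row sums equal set sizes.
    """
    if len(collection) == 0:
        raise PreconditionError("cannot vectorize an empty collection")
    genes = sorted(collection.universe)
    index = {g: k for k, g in enumerate(genes)}
    M = np.zeros((len(collection), len(genes)), dtype=np.int8)
    for i, s in enumerate(collection):
        for g in s.members:
            M[i, index[g]] = 1
    return M, genes


def ward_cluster(
    matrix: np.ndarray,
    labels: list[str] | None = None,
    allow_nonbinary: bool = False,
) -> Dendrogram:
    """Agglomerative Ward clustering of row vectors.

    By contract this clusters binary membership vectors; pass
    ``allow_nonbinary=True`` for the count-weighted variant where rows carry
    real-valued co-occurrence weights.  Equal-height ties merge the pair
    with the smallest (min node id, max node id), making the merge sequence
    deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise PreconditionError("ward_cluster needs a 2-D matrix with >= 2 rows")
    if not allow_nonbinary and not np.isin(X, (0.0, 1.0)).all():
        raise PreconditionError(
            "membership matrix must be binary (use allow_nonbinary=True for "
            "count-weighted vectors)"
        )
    n = X.shape[0]
    if labels is not None and len(labels) != n:
        raise PreconditionError("labels length must match the number of rows")

    # D_KL for singletons is ||x - y||^2 / 2; Lance-Williams keeps it exact.
    D = squareform(pdist(X, metric="sqeuclidean")) / 2.0
    np.fill_diagonal(D, np.inf)
    ids = list(range(n))           # current cluster id at each active slot
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    merges: list[Merge] = []

    for step in range(n - 1):
        sub = np.where(active)[0]
        Dsub = D[np.ix_(sub, sub)]
        h = Dsub.min()
        # mathematically equal heights may differ in the last float bits
        # after repeated Lance-Williams updates; treat them as tied
        ties = np.argwhere(np.isclose(Dsub, h, rtol=1e-9, atol=1e-12))
        # tie-break: smallest (min id, max id) among tied pairs
        best = min(
            (
                tuple(sorted((ids[sub[i]], ids[sub[j]])))
                for i, j in ties
                if i < j
            ),
        )
        a_id, b_id = best
        ia = sub[[ids[s] for s in sub].index(a_id)]
        ib = sub[[ids[s] for s in sub].index(b_id)]
        new_size = sizes[ia] + sizes[ib]
        merges.append(Merge(a=a_id, b=b_id, height=float(h), size=int(new_size)))
        # Lance-Williams update for Ward on the D_KL scale, written into slot ia
        others = sub[(sub != ia) & (sub != ib)]
        if len(others):
            nj = sizes[others]
            D_new = (
                (nj + sizes[ia]) * D[ia, others]
                + (nj + sizes[ib]) * D[ib, others]
                - nj * D[ia, ib]
            ) / (nj + new_size)
            D[ia, others] = D[others, ia] = D_new
        sizes[ia] = new_size
        ids[ia] = n + step
        active[ib] = False

    return Dendrogram(n_leaves=n, merges=merges, labels=list(labels) if labels else None)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> list[int]:
    """Partition the leaves into exactly ``k`` clusters.

    Undoes the last k-1 merges: replaying the first n-k merges and taking
    connected components gives the k-cluster partition.  Cluster ids are
    0..k-1 in order of each cluster's smallest leaf.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise PreconditionError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, m in enumerate(dendrogram.merges[: n - k]):
        new = n + step
        parent[find(m.a)] = new
        parent[find(m.b)] = new

    roots: dict[int, int] = {}
    assignment = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        assignment.append(roots[r])
    return assignment
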