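"""Dendrograms over gene sets: neighbor-joining, least-squares branch
lengths, and the Fitch-Margoliash goodness-of-fit criterion.

The tree methods treat disease/phenotype gene sets exactly as phylogenetics
treats taxa: an observed distance matrix D (here the overlap-coefficient
distances) is summarised by an unrooted tree whose leaf-to-leaf path
distances d approximate D.  The fit of a tree is scored by the weighted
least-squares criterion

    sum over unordered pairs of  n * (D - d)^2 / D^P

with P = 2 for the Fitch-Margoliash weighting and P = 0 for the unweighted
(neighbor-joining style) variant, and n the number of replicate
measurements per pair (1 in the simple case).  A full topology search under
this criterion is combinatorially explosive; the package instead evaluates
the criterion and fits optimal branch lengths on topologies proposed by
neighbor-joining (or supplied by the user), and assesses stability by
re-running NJ under randomized input orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .distance import DistanceMatrix
from .errors import PhenoshareError, PreconditionError
from .genesets import GeneSetCollection


@dataclass
class FMConfig:
    """Weighting configuration for the least-squares tree criterion.

    power_P: exponent on the observed distance in the denominator; 2.0 gives
        the Fitch-Margoliash weighting, 0.0 the unweighted variant.
    replicates_n: number of replicate measurements behind each pairwise
        distance (a uniform n; 1 in the simple case).
    denom_epsilon: floor applied to D before raising to power_P, so that
        duplicate gene sets (observed distance exactly 0) do not divide by
        zero under P = 2.
    """

    power_P: float = 2.0
    replicates_n: int = 1
    denom_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.replicates_n < 1:
            raise ValueError("replicates_n must be >= 1")
        if self.denom_epsilon <= 0:
            raise ValueError("denom_epsilon must be positive")
        if self.power_P not in (0.0, 2.0):
            warnings.warn(
                f"power_P={self.power_P} is neither 0.0 (unweighted) nor 2.0 "
                "(Fitch-Margoliash); proceeding with the given exponent",
                stacklevel=2,
            )

    def weights(self, observed: np.ndarray) -> np.ndarray:
        """Per-pair least-squares weights n / max(D, eps)^P."""
        floored = np.maximum(np.asarray(observed, dtype=float), self.denom_epsilon)
        return self.replicates_n / floored**self.power_P


class PhyloTree:
    """An unrooted tree with labeled leaves and real branch lengths.

    Backed by an undirected ``networkx`` graph whose leaf nodes carry a
    ``label`` attribute and whose edges carry a ``length``.  Negative branch
    lengths are permitted (standard neighbor-joining behaviour) and flagged
    with a warning at serialization time.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        labels = self.leaf_labels
        if len(labels) < 3:
            raise ValueError("a tree needs at least 3 leaves")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for _, _, data in graph.edges(data=True):
            if not np.isfinite(data.get("length", np.nan)):
                raise ValueError("every branch must carry a finite length")

    # -- structure ---------------------------------------------------------

    @property
    def leaves(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 1]

    @property
    def leaf_labels(self) -> list[str]:
        out = []
        for n in self.leaves:
            label = self.graph.nodes[n].get("label")
            if not label:
                raise ValueError(f"leaf node {n!r} is unlabeled")
            out.append(label)
        return out

    def leaf_node(self, label: str):
        for n in self.leaves:
            if self.graph.nodes[n].get("label") == label:
                return n
        raise KeyError(label)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.graph.copy())

    # -- distances ---------------------------------------------------------

    def path_distance(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the unique path between two leaves."""
        path = nx.shortest_path(self.graph, self.leaf_node(label_a), self.leaf_node(label_b))
        return float(
            sum(self.graph.edges[u, v]["length"] for u, v in zip(path, path[1:]))
        )

    def path_distance_matrix(self, labels: list[str] | None = None) -> DistanceMatrix:
        """All pairwise leaf-to-leaf path distances as a DistanceMatrix."""
        if labels is None:
            labels = sorted(self.leaf_labels)
        nodes = {l: self.leaf_node(l) for l in labels}
        n = len(labels)
        values = np.zeros((n, n))
        for i, la in enumerate(labels):
            # one traversal per source leaf; trees have unique paths so a
            # DFS accumulating lengths is exact even with negative branches
            dist = {nodes[la]: 0.0}
            stack = [nodes[la]]
            while stack:
                u = stack.pop()
                for v in self.graph.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + self.graph.edges[u, v]["length"]
                        stack.append(v)
            for j, lb in enumerate(labels):
                if i != j:
                    values[i, j] = dist[nodes[lb]]
        values = (values + values.T) / 2.0  # exact halves; symmetrize fp noise
        return DistanceMatrix(list(labels), values)

    # -- topology ----------------------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits of the leaf-label set, one per internal edge.

        Each split is represented canonically by the side that does not
        contain the alphabetically smallest leaf label.
        """
        all_labels = set(self.leaf_labels)
        anchor = min(all_labels)
        splits: set[frozenset[str]] = set()
        for u, v in self.graph.edges:
            side = self._leafset_beyond(u, v)
            if 1 < len(side) < len(all_labels) - 1:
                if anchor in side:
                    side = all_labels - side
                splits.add(frozenset(side))
        return frozenset(splits)

    def _leafset_beyond(self, u, v) -> set[str]:
        """Leaf labels reachable from v when the edge (u, v) is removed."""
        seen = {u, v}
        stack = [v]
        out: set[str] = set()
        if self.graph.degree(v) == 1:
            out.add(self.graph.nodes[v]["label"])
        while stack:
            x = stack.pop()
            for y in self.graph.neighbors(x):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
                    if self.graph.degree(y) == 1:
                        out.add(self.graph.nodes[y]["label"])
        return out

    def same_topology(self, other: "PhyloTree") -> bool:
        return (
            set(self.leaf_labels) == set(other.leaf_labels)
            and self.bipartitions() == other.bipartitions()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree(leaves={sorted(self.leaf_labels)})"


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: |symmetric difference of non-trivial splits|."""
    if set(t1.leaf_labels) != set(t2.leaf_labels):
        raise PreconditionError("trees have different leaf label sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def _validate_matrix(matrix: DistanceMatrix) -> np.ndarray:
    # DistanceMatrix already guarantees symmetry / zero diagonal / no NaN
    if len(matrix) < 3:
        raise PreconditionError("tree building needs at least 3 labels")
    return np.array(matrix.values, dtype=float)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Standard neighbor-joining (Saitou-Nei) on a distance matrix.

    Agglomerates by the Q criterion with the classic branch-length updates.
    On an additive matrix the returned tree reproduces every pairwise
    distance exactly.  Ties in the Q minimum are broken by joining the pair
    whose clusters contain the lexicographically smallest leaf labels
    (deterministic output for symmetric inputs).
    """
    D = _validate_matrix(matrix)
    n0 = len(matrix)
    graph = nx.Graph()
    for i, label in enumerate(matrix.labels):
        graph.add_node(i, label=label)
    # sort key of a cluster = smallest leaf label beneath it
    active: list[int] = list(range(n0))
    keys: dict[int, str] = {i: matrix.labels[i] for i in range(n0)}
    next_id = n0

    while len(active) > 3:
        m = len(active)
        row_sums = D.sum(axis=1)
        Q = (m - 2) * D - row_sums[:, None] - row_sums[None, :]
        Q = np.minimum(Q, Q.T)  # summation order can leave an ulp asymmetry
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        best = min(
            ((i, j) for i, j in ties if i < j),
            key=lambda ij: tuple(sorted((keys[active[ij[0]]], keys[active[ij[1]]]))),
        )
        i, j = best
        dij = D[i, j]
        limb_i = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        node_i, node_j = active[i], active[j]
        new = next_id
        next_id += 1
        graph.add_edge(node_i, new, length=float(limb_i))
        graph.add_edge(node_j, new, length=float(limb_j))
        keys[new] = min(keys[node_i], keys[node_j])
        # reduce the matrix
        rest = [k for k in range(m) if k not in (i, j)]
        d_new = 0.5 * (D[i, rest] + D[j, rest] - dij)
        D_next = np.empty((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(rest, rest)]
        D_next[:-1, -1] = d_new
        D_next[-1, :-1] = d_new
        D_next[-1, -1] = 0.0
        D = D_next
        active = [active[k] for k in rest] + [new]

    # closed-form star join of the last three clusters
    (a, b, c) = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = next_id
    graph.add_edge(a, center, length=float(0.5 * (dab + dac - dbc)))
    graph.add_edge(b, center, length=float(0.5 * (dab + dbc - dac)))
    graph.add_edge(c, center, length=float(0.5 * (dac + dbc - dab)))
    return PhyloTree(graph)


def _pair_path_incidence(tree: PhyloTree, labels: list[str]):
    """Incidence of leaf pairs on edges: A[p, e] = 1 iff edge e lies on pair p's path."""
    edges = list(tree.graph.edges)
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    pairs = list(combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    for p, (la, lb) in enumerate(pairs):
        path = nx.shortest_path(tree.graph, tree.leaf_node(la), tree.leaf_node(lb))
        for u, v in zip(path, path[1:]):
            A[p, edge_index[frozenset((u, v))]] = 1.0
    return A, edges, pairs


def fit_branch_lengths_ls(
    topology: PhyloTree, matrix: DistanceMatrix, config: FMConfig | None = None
) -> PhyloTree:
    """Weighted least-squares branch lengths on a fixed topology.

    Minimizes sum of n (D - d)^2 / max(D, eps)^P over unordered leaf pairs,
    where d is the tree path distance, by solving the weighted linear system
    on the pair-path incidence matrix.  The topology is preserved; only
    branch lengths change.
    """
    config = config or FMConfig()
    if set(topology.leaf_labels) != set(matrix.labels):
        raise PreconditionError("topology leaves do not match matrix labels")
    labels = sorted(matrix.labels)
    A, edges, pairs = _pair_path_incidence(topology, labels)
    reordered = matrix.reorder(labels)
    D = np.array([reordered.get(a, b) for a, b in pairs])
    w = config.weights(D)
    sw = np.sqrt(w)
    lengths, _, rank, _ = np.linalg.lstsq(sw[:, None] * A, sw * D, rcond=None)
    if rank < len(edges):
        raise PhenoshareError(
            "degenerate topology: branch lengths are not identifiable"
        )
    fitted = topology.graph.copy()
    for (u, v), length in zip(edges, lengths):
        fitted.edges[u, v]["length"] = float(length)
    return PhyloTree(fitted)


def fm_criterion(
    tree: PhyloTree, matrix: DistanceMatrix, config: FMConfig | None = None
) -> float:
    """Evaluate the weighted least-squares fit of a tree to observed distances.

    Returns sum over unordered pairs of n (D - d)^2 / max(D, eps)^P with d
    the tree path distance; 0 iff the tree reproduces every observed
    distance exactly.
    """
    config = config or FMConfig()
    if set(tree.leaf_labels) != set(matrix.labels):
        raise PreconditionError("tree leaves do not match matrix labels")
    labels = sorted(matrix.labels)
    observed = matrix.reorder(labels).values
    expected = tree.path_distance_matrix(labels).values
    iu = np.triu_indices(len(labels), k=1)
    D, d = observed[iu], expected[iu]
    return float(np.sum(config.weights(D) * (D - d) ** 2))


def nj_replicates(
    matrix: DistanceMatrix,
    n_reps: int,
    seed: int,
    permutations: list[list[int]] | None = None,
) -> list[PhyloTree]:
    """Neighbor-joining under randomized label input orders.

    Each replicate permutes the matrix rows/columns with a seeded generator
    and reruns NJ; trees keep the original labels.  Identical seeds give
    identical replicate lists.  Explicit ``permutations`` override the
    generator (e.g. the identity order for comparisons).
    """
    if n_reps < 1:
        raise PreconditionError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    trees = []
    for rep in range(n_reps):
        if permutations is not None:
            perm = list(permutations[rep])
        else:
            perm = list(rng.permutation(len(matrix)))
        labels = [matrix.labels[p] for p in perm]
        trees.append(nj_tree(matrix.reorder(labels)))
    return trees


def randomized_replicates(
    collection: GeneSetCollection,
    n_reps: int,
    seed: int,
    method: str = "overlap",
    permutations: list[list[int]] | None = None,
) -> list[PhyloTree]:
    """Randomized-input-order NJ replicates straight from a gene set collection.

    Permutes the collection order, recomputes the distance matrix in
    permuted order and runs :func:`nj_tree`, once per replicate.
    """
    from .distance import distance_matrix

    matrix = distance_matrix(collection, method=method)
    return nj_replicates(matrix, n_reps=n_reps, seed=seed, permutations=permutations)
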