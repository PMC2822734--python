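"""Neighbor-joining, least-squares branch fitting, criterion, replicates, RF."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from phenoshare import (
    DistanceMatrix,
    FMConfig,
    PhyloTree,
    PreconditionError,
    fit_branch_lengths_ls,
    fm_criterion,
    nj_replicates,
    nj_tree,
    random_binary_tree,
    randomized_replicates,
    rf_distance,
)
from phenoshare.io_formats import newick_string


def quartet(split_pair, labels=("A", "B", "C", "D")):
    """The unrooted 4-leaf topology grouping `split_pair` (unit lengths)."""
    g = nx.Graph()
    left = [l for l in labels if l in split_pair]
    right = [l for l in labels if l not in split_pair]
    for l in labels:
        g.add_node(l, label=l)
    g.add_edge(left[0], "u", length=1.0)
    g.add_edge(left[1], "u", length=1.0)
    g.add_edge(right[0], "v", length=1.0)
    g.add_edge(right[1], "v", length=1.0)
    g.add_edge("u", "v", length=1.0)
    return PhyloTree(g)


def normal_equations_fit(tree, matrix, config):
    """Independent oracle: explicit weighted normal equations on leaf paths."""
    labels = sorted(matrix.labels)
    nodes = {tree.graph.nodes[n].get("label"): n for n in tree.graph.nodes}
    edges = list(tree.graph.edges)
    eidx = {frozenset(e): k for k, e in enumerate(edges)}
    pairs = list(combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    for p, (la, lb) in enumerate(pairs):
        # parent-pointer BFS path reconstruction, independent of the package
        parents = {nodes[la]: None}
        queue = [nodes[la]]
        while queue:
            u = queue.pop(0)
            for v in tree.graph.neighbors(u):
                if v not in parents:
                    parents[v] = u
                    queue.append(v)
        node = nodes[lb]
        while parents[node] is not None:
            A[p, eidx[frozenset((node, parents[node]))]] = 1.0
            node = parents[node]
    D = np.array([matrix.get(a, b) for a, b in pairs])
    W = np.diag(config.weights(D))
    x = np.linalg.solve(A.T @ W @ A, A.T @ W @ D)
    return {frozenset(e): x[k] for k, e in enumerate(edges)}


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = nj_tree(m)
        center = next(n for n in tree.graph.nodes if tree.graph.degree(n) == 3)
        lengths = {
            tree.graph.nodes[n]["label"]: tree.graph.edges[n, center]["length"]
            for n in tree.leaves
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_topology_recovered_by_enumeration_oracle(self):
        # matrix generated from the AB|CD quartet with all branches 1
        truth = quartet(("A", "B"))
        m = truth.path_distance_matrix()
        tree = nj_tree(m)
        # oracle: LS-fit all three quartet topologies; only one has zero residual
        residuals = {
            pair: fm_criterion(
                fit_branch_lengths_ls(quartet(pair), m, FMConfig(power_P=0.0)),
                m,
                FMConfig(power_P=0.0),
            )
            for pair in (("A", "B"), ("A", "C"), ("A", "D"))
        }
        zero = [pair for pair, r in residuals.items() if r < 1e-18]
        assert zero == [("A", "B")]
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert np.allclose(tree.path_distance_matrix(m.labels).values, m.values)

    def test_q_matrix_tie_joins_lexicographically_smallest_pair(self):
        # four mutually equidistant taxa: every Q entry ties
        v = np.ones((4, 4)) - np.eye(4)
        m = DistanceMatrix(["D", "C", "B", "A"], v)
        tree = nj_tree(m)
        # joining {A, B} first yields the AB|CD split, stored canonically
        # as the side without the anchor leaf A
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_nan_and_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))
        with pytest.raises(PreconditionError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additive_matrices_recovered_exactly(self, rng, n_leaves):
        for _ in range(10):
            truth = random_binary_tree(n_leaves, rng)
            m = truth.path_distance_matrix()
            tree = nj_tree(m)
            assert rf_distance(truth, tree) == 0
            err = np.abs(tree.path_distance_matrix(m.labels).values - m.values).max()
            assert err < 1e-9

    def test_agrees_with_dendropy_on_random_input(self, rng):
        import dendropy

        n = 7
        v = rng.uniform(0.2, 1.0, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        labels = [f"T{i}" for i in range(n)]
        m = DistanceMatrix(labels, v)
        ours = nj_tree(m)

        csv_rows = ["," + ",".join(labels)]
        for i, l in enumerate(labels):
            csv_rows.append(l + "," + ",".join(f"{x:.12f}" for x in v[i]))
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO("\n".join(csv_rows)), delimiter=","
        )
        theirs_newick = pdm.nj_tree().as_string(schema="newick")
        from phenoshare.io_formats import read_newick

        theirs = read_newick(data=theirs_newick)
        assert rf_distance(ours, theirs) == 0


class TestLeastSquaresFit:
    def test_three_taxon_fit_matches_closed_form(self):
        m = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        fitted = fit_branch_lengths_ls(nj_tree(m), m)
        assert np.allclose(fitted.path_distance_matrix(m.labels).values, m.values)

    def test_additive_five_taxon_matrix_refits_generating_lengths(self, rng):
        truth = random_binary_tree(5, rng)
        m = truth.path_distance_matrix()
        fitted = fit_branch_lengths_ls(truth, m, FMConfig())
        assert fm_criterion(fitted, m) < 1e-18
        for u, v in truth.graph.edges:
            assert fitted.graph.edges[u, v]["length"] == pytest.approx(
                truth.graph.edges[u, v]["length"], abs=1e-8
            )

    def test_weighted_and_unweighted_fits_differ_on_noisy_matrix(self, rng):
        truth = random_binary_tree(6, rng)
        m = truth.path_distance_matrix()
        noisy = m.values + rng.normal(0, 0.15, size=m.values.shape)
        noisy = np.abs((noisy + noisy.T) / 2)
        np.fill_diagonal(noisy, 0)
        noisy_m = DistanceMatrix(m.labels, noisy)
        fm = fit_branch_lengths_ls(truth, noisy_m, FMConfig(power_P=2.0))
        ols = fit_branch_lengths_ls(truth, noisy_m, FMConfig(power_P=0.0))
        lengths = lambda t: sorted(  # noqa: E731
            l for _, _, l in t.graph.edges(data="length")
        )
        assert not np.allclose(lengths(fm), lengths(ols))

    @pytest.mark.parametrize("power", [0.0, 2.0])
    def test_matches_normal_equations_oracle(self, rng, power):
        for _ in range(10):
            topology = random_binary_tree(int(rng.integers(4, 9)), rng)
            m = topology.path_distance_matrix()
            noisy = np.abs(m.values + rng.normal(0, 0.1, size=m.values.shape))
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            noisy_m = DistanceMatrix(m.labels, noisy)
            config = FMConfig(power_P=power)
            fitted = fit_branch_lengths_ls(topology, noisy_m, config)
            expected = normal_equations_fit(topology, noisy_m, config)
            for (u, v), length in expected.items():
                u, v = tuple((u, v))
                assert fitted.graph.edges[tuple((u, v))]["length"] == pytest.approx(
                    length, abs=1e-8
                )


class TestCriterion:
    def test_perfect_fit_scores_zero(self, rng):
        truth = random_binary_tree(6, rng)
        assert fm_criterion(truth, truth.path_distance_matrix()) < 1e-18

    def test_single_pair_formula(self):
        # one deviating pair D=2, d=1: (2-1)^2/2^2 = 0.25 under P=2, 1.0 under P=0
        g = nx.Graph()
        for l in "ABC":
            g.add_node(l, label=l)
        g.add_node("x")
        g.add_edge("A", "x", length=0.5)
        g.add_edge("B", "x", length=0.5)
        g.add_edge("C", "x", length=0.5)
        tree = PhyloTree(g)
        observed = tree.path_distance_matrix()
        values = observed.values.copy()
        ij = (observed.labels.index("A"), observed.labels.index("B"))
        values[ij] = values[ij[::-1]] = 2.0  # d stays 1.0
        matrix = DistanceMatrix(observed.labels, values)
        assert fm_criterion(tree, matrix, FMConfig(power_P=2.0)) == pytest.approx(0.25)
        assert fm_criterion(tree, matrix, FMConfig(power_P=0.0)) == pytest.approx(1.0)

    def test_label_mismatch_rejected(self, rng):
        tree = random_binary_tree(4, rng)
        other = DistanceMatrix(["X", "Y", "Z"], np.zeros((3, 3)))
        with pytest.raises(PreconditionError):
            fm_criterion(tree, other)

    def test_unusual_power_warns(self):
        with pytest.warns(UserWarning):
            FMConfig(power_P=1.0)


class TestReplicates:
    def test_identity_permutation_reproduces_plain_nj(self, simple_collection):
        from phenoshare import distance_matrix

        m = distance_matrix(simple_collection)
        (replicate,) = randomized_replicates(
            simple_collection, n_reps=1, seed=0, permutations=[list(range(len(m)))]
        )
        assert rf_distance(replicate, nj_tree(m)) == 0
        assert replicate.path_distance_matrix().allclose(
            nj_tree(m).path_distance_matrix()
        )

    def test_additive_matrix_gives_one_topology_across_replicates(self, rng):
        truth = random_binary_tree(8, rng)
        m = truth.path_distance_matrix()
        replicates = nj_replicates(m, n_reps=10, seed=3)
        for t in replicates:
            assert rf_distance(t, replicates[0]) == 0

    def test_fixed_seed_gives_byte_identical_newick(self, rng):
        truth = random_binary_tree(6, rng)
        m = truth.path_distance_matrix()
        run1 = [newick_string(t) for t in nj_replicates(m, n_reps=5, seed=11)]
        run2 = [newick_string(t) for t in nj_replicates(m, n_reps=5, seed=11)]
        assert run1 == run2


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self, rng):
        t = random_binary_tree(6, rng)
        assert rf_distance(t, t.copy()) == 0

    def test_alternative_quartets_distance_two(self):
        assert rf_distance(quartet(("A", "B")), quartet(("A", "C"))) == 2

    def test_star_versus_resolved_quartet_distance_one(self):
        g = nx.Graph()
        g.add_node("hub")
        for l in "ABCD":
            g.add_node(l, label=l)
            g.add_edge(l, "hub", length=1.0)
        star = PhyloTree(g)
        assert rf_distance(star, quartet(("A", "B"))) == 1

    def test_mismatched_leaves_rejected(self, rng):
        with pytest.raises(PreconditionError):
            rf_distance(
                random_binary_tree(4, rng),
                random_binary_tree(4, rng, labels=["W", "X", "Y", "Z"]),
            )

    def test_permutation_equivariance(self, rng):
        truth = random_binary_tree(7, rng)
        m = truth.path_distance_matrix()
        perm = list(rng.permutation(len(m)))
        permuted = m.reorder([m.labels[p] for p in perm])
        assert rf_distance(nj_tree(m), nj_tree(permuted)) == 0
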