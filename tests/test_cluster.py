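"""Ward clustering: formula checks, brute-force oracle, cutting."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phenoshare import (
    GeneSet,
    GeneSetCollection,
    PreconditionError,
    cut_dendrogram,
    membership_matrix,
    ward_cluster,
)


def bruteforce_ward(X):
    """First-principles oracle: merge the pair minimizing the increase in
    within-cluster sum of squares, computed directly from the definition.

    Uses the same tie rule as the implementation (numerically equal
    increases -> smallest (min id, max id) pair) but shares no code with it:
    cluster means and sums of squares are recomputed from scratch each step.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}

    def wss(rows):
        sub = X[rows]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    merges = []
    next_id = n
    for _ in range(n - 1):
        candidates = []
        for a, b in combinations(sorted(clusters), 2):
            increase = wss(clusters[a] + clusters[b]) - wss(clusters[a]) - wss(clusters[b])
            candidates.append((increase, a, b))
        best_increase = min(c[0] for c in candidates)
        tied = [
            (a, b)
            for increase, a, b in candidates
            if np.isclose(increase, best_increase, rtol=1e-9, atol=1e-12)
        ]
        a, b = min(tied)
        merges.append((a, b, best_increase, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestWardFormula:
    def test_two_singletons_merge_at_half_squared_distance(self):
        x = np.array([[1, 0, 0, 1]], dtype=float)
        y = np.array([[0, 1, 0, 1]], dtype=float)
        dend = ward_cluster(np.vstack([x, y]))
        (merge,) = dend.merges
        assert merge.height == pytest.approx(np.sum((x - y) ** 2) / 2)

    def test_identical_rows_merge_first_at_zero(self):
        M = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        dend = ward_cluster(M)
        assert dend.merges[0].height == 0.0 and dend.merges[0].a == 0 and dend.merges[0].b == 1

    def test_planted_pairs_merge_before_crossing(self):
        # two tight planted pairs; oracle = brute force over merge sequences
        M = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0, 0],
                [0, 0, 0, 1, 1, 1],
                [0, 0, 0, 1, 1, 0],
            ]
        )
        dend = ward_cluster(M)
        first_two = {(m.a, m.b) for m in dend.merges[:2]}
        assert first_two == {(0, 1), (2, 3)}
        assert [(m.a, m.b) for m in dend.merges] == [m[:2] for m in bruteforce_ward(M)]

    def test_nonbinary_rejected_without_flag(self):
        M = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(PreconditionError):
            ward_cluster(M)
        assert len(ward_cluster(M, allow_nonbinary=True).merges) == 1

    def test_heights_match_direct_centroid_formula(self, rng):
        # replay the merge sequence computing D_KL = ||xK-xL||^2/(1/NK+1/NL)
        # directly from centroids, never via Lance-Williams
        X = (rng.random((9, 12)) < 0.4).astype(float)
        dend = ward_cluster(X)
        members = {i: [i] for i in range(9)}
        for step, m in enumerate(dend.merges):
            ka, kb = members[m.a], members[m.b]
            xa, xb = X[ka].mean(axis=0), X[kb].mean(axis=0)
            direct = np.sum((xa - xb) ** 2) / (1 / len(ka) + 1 / len(kb))
            assert m.height == pytest.approx(direct, rel=1e-9, abs=1e-12)
            members[9 + step] = ka + kb


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_merge_sequence_matches_bruteforce(self, trial):
        rand = np.random.default_rng(1000 + trial)
        n = int(rand.integers(3, 8))
        X = (rand.random((n, int(rand.integers(3, 10)))) < 0.5).astype(float)
        ours = [(m.a, m.b) for m in ward_cluster(X).merges]
        oracle = [m[:2] for m in bruteforce_ward(X)]
        assert ours == oracle

    @given(st.integers(0, 10_000))
    def test_merge_heights_nondecreasing(self, seed):
        rand = np.random.default_rng(seed)
        n = int(rand.integers(2, 12))
        X = (rand.random((n, int(rand.integers(2, 15)))) < 0.5).astype(float)
        heights = ward_cluster(X).heights
        assert (np.diff(heights) >= -1e-9).all()


class TestMembershipMatrix:
    def test_rows_follow_collection_and_columns_sorted_universe(self):
        collection = GeneSetCollection(
            [GeneSet("S1", frozenset({"g1", "g2"})), GeneSet("S2", frozenset({"g2"}))]
        )
        M, genes = membership_matrix(collection)
        assert genes == ["g1", "g2"]
        assert M.tolist() == [[1, 1], [0, 1]]

    def test_disjoint_sets_give_orthogonal_rows(self):
        collection = GeneSetCollection(
            [GeneSet("A", frozenset({"a"})), GeneSet("B", frozenset({"b"}))]
        )
        M, _ = membership_matrix(collection)
        assert M[0] @ M[1] == 0

    def test_row_sums_equal_set_sizes(self, simple_collection):
        M, _ = membership_matrix(simple_collection)
        assert list(M.sum(axis=1)) == [s.size for s in simple_collection]


class TestCut:
    def test_extreme_cuts(self, rng):
        X = (rng.random((6, 8)) < 0.5).astype(float)
        dend = ward_cluster(X)
        assert len(set(cut_dendrogram(dend, 1))) == 1
        assert cut_dendrogram(dend, 6) == list(range(6))
        with pytest.raises(PreconditionError):
            cut_dendrogram(dend, 0)
        with pytest.raises(PreconditionError):
            cut_dendrogram(dend, 7)

    def test_planted_two_groups_recovered(self):
        M = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0, 0],
                [1, 0, 1, 0, 0, 0],
                [0, 0, 0, 1, 1, 1],
                [0, 0, 0, 1, 1, 0],
                [0, 0, 0, 0, 1, 1],
            ]
        )
        assignment = cut_dendrogram(ward_cluster(M), 2)
        assert assignment == [0, 0, 0, 1, 1, 1]

    def test_row_permutation_permutes_assignment(self, rng):
        X = (rng.random((7, 10)) < 0.4).astype(float)
        base = cut_dendrogram(ward_cluster(X), 3)
        perm = list(rng.permutation(7))
        permuted = cut_dendrogram(ward_cluster(X[perm]), 3)
        # same partition up to label renaming
        from collections import defaultdict

        def groups(assign):
            g = defaultdict(frozenset)
            out = defaultdict(set)
            for i, c in enumerate(assign):
                out[c].add(i)
            return {frozenset(v) for v in out.values()}

        base_groups = groups(base)
        permuted_groups = {
            frozenset(perm[i] for i in grp) for grp in groups(permuted)
        }
        assert base_groups == permuted_groups
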