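import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from edafs import (
    PairCounts,
    build_edge_set,
    build_forest,
    chi2_pair,
    compute_stats,
    marginal_entropy,
    mi_pair,
    pair_counts,
    sim_pair,
)
from edafs.dependency import all_entropies, maximum_spanning_edges


def brute_force_max_forest_weight(edges, n_nodes):
    """Oracle: enumerate all acyclic edge subsets, return the max total weight."""
    best = 0.0
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            parent = list(range(n_nodes))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            ok = True
            for i, j, _ in subset:
                ri, rj = find(i), find(j)
                if ri == rj:
                    ok = False
                    break
                parent[rj] = ri
            if ok:
                best = max(best, sum(s for _, _, s in subset))
    return best


class TestPairCounts:
    def test_direct_count(self):
        pc = pair_counts([(1, 1), (1, 0)], 0, 1)
        assert (pc.n11, pc.n10, pc.n01, pc.n00) == (1, 1, 0, 0)

    def test_identical_pool_single_cell(self):
        pool = [(1, 0)] * 10
        pc = pair_counts(pool, 0, 1)
        assert pc.n10 == 10
        assert pc.n00 == pc.n01 == pc.n11 == 0

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=50))
    def test_counts_conserve_pool_size(self, pool):
        assert pair_counts(pool, 0, 1).N == len(pool)

    def test_equal_indices_rejected(self):
        with pytest.raises(ValueError):
            pair_counts([(0, 1)], 1, 1)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pair_counts([], 0, 1)


class TestChi2:
    def test_exact_independence(self):
        assert chi2_pair(PairCounts(4, 4, 4, 4)) == 0.0

    def test_perfect_association(self):
        # frozen from direct evaluation of sum (o-e)^2/e on [[5,0],[0,5]]
        assert chi2_pair(PairCounts(5, 0, 0, 5)) == pytest.approx(10.0)

    def test_degenerate_margin_contributes_zero(self):
        assert chi2_pair(PairCounts(10, 0, 0, 0)) == 0.0

    @given(st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0))
    def test_nonnegative(self, t):
        assert chi2_pair(PairCounts(*t)) >= 0.0

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            tab = rng.integers(1, 40, size=4)
            obs = tab.reshape(2, 2)
            expected = sps.chi2_contingency(obs, correction=False)[0]
            ours = chi2_pair(PairCounts(*tab))
            assert ours == pytest.approx(expected, abs=1e-9)
            checked += 1


class TestMI:
    def test_independence_zero(self):
        assert mi_pair(PairCounts(4, 4, 4, 4)) == 0.0

    def test_deterministic_relation_one_bit(self):
        assert mi_pair(PairCounts(5, 0, 0, 5)) == pytest.approx(1.0)

    def test_frozen_value(self):
        # direct evaluation of the plug-in sum on [[2,1],[1,2]]
        assert mi_pair(PairCounts(2, 1, 1, 2)) == pytest.approx(0.08170416594551044)

    def test_matches_textbook_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tab = rng.integers(0, 40, size=4)
            if tab.sum() == 0:
                tab[0] = 1
            n = tab.sum()
            p = tab.reshape(2, 2) / n
            expected = 0.0
            for a in range(2):
                for b in range(2):
                    if p[a, b] > 0:
                        expected += p[a, b] * np.log2(
                            p[a, b] / (p[a].sum() * p[:, b].sum())
                        )
            assert mi_pair(PairCounts(*tab)) == pytest.approx(expected, abs=1e-9)


class TestSIM:
    def test_fires_on_strong_association(self):
        assert sim_pair(PairCounts(5, 0, 0, 5)) == 1

    def test_silent_on_independence(self):
        assert sim_pair(PairCounts(4, 4, 4, 4)) == 0

    @given(st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0))
    def test_sim_implies_chi2_criterion(self, t):
        pc = PairCounts(*t)
        if sim_pair(pc):
            assert chi2_pair(pc) >= 3.84


class TestEntropy:
    def test_fair_bit(self):
        assert marginal_entropy([(0,), (1,)], 0) == pytest.approx(1.0)

    def test_constant_bit(self):
        assert marginal_entropy([(1,)] * 5, 0) == pytest.approx(0.0)

    def test_quarter_frequency(self):
        pool = [(1,), (0,), (0,), (0,)]
        assert marginal_entropy(pool, 0) == pytest.approx(0.8112781244591328)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        pool = rng.integers(0, 2, size=(30, 4))
        flipped = 1 - pool
        for i in range(4):
            assert marginal_entropy(pool, i) == pytest.approx(
                marginal_entropy(flipped, i))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        pool = rng.integers(0, 2, size=(25, 6))
        vec = all_entropies(pool)
        for i in range(6):
            assert vec[i] == pytest.approx(marginal_entropy(pool, i))


class TestEdgeSet:
    def test_duplicated_column_detected(self):
        rng = np.random.default_rng(4)
        col = np.array([0, 1] * 10)
        pool = np.column_stack([col, col])
        edges = build_edge_set(pool, "chi2")
        assert [(i, j) for i, j, _ in edges] == [(0, 1)]
        assert edges[0][2] == pytest.approx(20.0)

    def test_balanced_independent_columns_empty(self):
        # cell counts exactly at expectation: chi2 = 0 for every pair
        pool = np.array(list(itertools.product([0, 1], repeat=3)))
        assert build_edge_set(pool, "chi2") == []

    def test_mi_keeps_at_least_as_many_as_sim(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pool = rng.integers(0, 2, size=(12, 5))
            mi_edges = {(i, j) for i, j, _ in build_edge_set(pool, "mi")}
            sim_edges = {(i, j) for i, j, _ in build_edge_set(pool, "sim")}
            assert sim_edges <= mi_edges

    def test_none_criterion_is_empty(self):
        rng = np.random.default_rng(6)
        pool = rng.integers(0, 2, size=(10, 4))
        assert build_edge_set(pool, "none") == []


class TestForest:
    def test_triangle_keeps_two_strongest(self):
        edges = [(0, 1, 10.0), (1, 2, 8.0), (0, 2, 5.0)]
        forest = build_forest(edges, 3, entropies=np.ones(3))
        assert forest.undirected_edges() == {(0, 1), (1, 2)}

    def test_empty_edges_all_singleton_roots(self):
        forest = build_forest([], 4, entropies=np.ones(4))
        assert forest.roots == {0, 1, 2, 3}
        assert forest.edges == []
        assert len(forest.components) == 4

    def test_min_entropy_root(self):
        forest = build_forest([(0, 1, 1.0)], 2, entropies=np.array([1.0, 0.5]))
        assert forest.roots == {1}
        assert forest.edges == [(1, 0)]
        assert forest.parent == {0: 1}

    def test_root_tie_breaks_to_lowest_index(self):
        forest = build_forest([(0, 1, 1.0)], 2, entropies=np.array([0.7, 0.7]))
        assert forest.roots == {0}

    def test_random_root_deterministic_under_seed(self):
        edges = [(0, 1, 2.0), (1, 2, 1.0)]
        a = build_forest(edges, 3, root_rule="random", seed=5)
        b = build_forest(edges, 3, root_rule="random", seed=5)
        assert a.roots == b.roots

    def test_every_nonroot_has_one_parent(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(3, 8)
            edges = [
                (i, j, float(rng.uniform(0.1, 5)))
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.4
            ]
            forest = build_forest(edges, int(n), entropies=rng.uniform(0, 1, int(n)))
            nodes = {v for comp in forest.components for v in comp}
            assert nodes == set(range(n))
            for v in range(n):
                assert (v in forest.roots) != (v in forest.parent)

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n = int(rng.integers(2, 8))
            edges = [
                (i, j, float(rng.uniform(0.1, 10)))
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.5
            ]
            if len(edges) > 12:
                edges = edges[:12]
            kept = maximum_spanning_edges(edges, n)
            assert sum(s for _, _, s in kept) == pytest.approx(
                brute_force_max_forest_weight(edges, n))

    def test_edge_order_invariance(self):
        rng = np.random.default_rng(9)
        edges = [(0, 1, 3.0), (1, 2, 3.0), (0, 2, 3.0), (2, 3, 1.0)]
        base = build_forest(edges, 4, entropies=np.ones(4))
        for _ in range(5):
            perm = list(edges)
            rng.shuffle(perm)
            assert build_forest(perm, 4, entropies=np.ones(4)).undirected_edges() \
                == base.undirected_edges()

    def test_out_of_range_endpoint(self):
        with pytest.raises(ValueError, match="out of range"):
            build_forest([(0, 5, 1.0)], 3, entropies=np.ones(3))


class TestComputeStats:
    def test_matrices_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(10)
        pool = rng.integers(0, 2, size=(15, 5))
        s = compute_stats(pool)
        for m in (s.chi2, s.mi, s.sim):
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 0)
        assert (s.chi2 >= 0).all() and (s.mi >= 0).all()
        assert ((s.entropy >= 0) & (s.entropy <= 1)).all()
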