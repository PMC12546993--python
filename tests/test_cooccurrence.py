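import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from microst.cooccurrence import (
    bh_adjust,
    build_cooccurrence,
    build_network,
    network_summary,
    normalize_adjacency,
    permutation_pvalue,
    spearman_rho,
)
from microst.tables_io import AbundanceTable


def shortcut_rho(x, y):
    """Tie-free Spearman shortcut: 1 - 6*sum(d^2) / (n(n^2-1))."""
    n = len(x)
    d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
    return 1 - 6 * float(d @ d) / (n * (n**2 - 1))


def brute_force_exhaustive_p(x, y):
    """Proportion of all n! permutations with |rho| >= |rho_obs| (scipy rho)."""
    rho_obs = abs(spearmanr(x, y).statistic)
    y = np.asarray(y)
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(spearmanr(x, y[list(perm)]).statistic) >= rho_obs - 1e-12:
            count += 1
    return count / total


def step_up_oracle(p):
    """Textbook BH step-up, coded independently of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


class TestSpearman:
    def test_monotone_increasing(self):
        rho, flag = spearman_rho([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0) and not flag

    def test_monotone_decreasing(self):
        rho, _ = spearman_rho([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # ranks differ by d = (-2, 1, -1, 2): sum d^2 = 10, 1 - 60/60 = 0
        rho, _ = spearman_rho([1, 2, 3, 4], [3, 1, 4, 2])
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_matches_shortcut_formula_on_tie_free_inputs(self, rng):
        for _ in range(50):
            x = rng.permutation(9).astype(float)
            y = rng.permutation(9).astype(float)
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(shortcut_rho(x, y), abs=1e-12)

    def test_constant_vector_flagged(self):
        rho, flag = spearman_rho([1, 1, 1], [1, 2, 3])
        assert rho == 0.0 and flag

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestPermutationP:
    def test_exhaustive_n3_perfect_correlation(self):
        # identity and full reversal both reach |rho| = 1: p = 2/6
        p, _ = permutation_pvalue([1, 2, 3], [4, 5, 6], mode="exhaustive")
        assert p == pytest.approx(2 / 6)

    def test_exhaustive_matches_brute_force_oracle(self, rng):
        for n in (4, 5, 6):
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            p, _ = permutation_pvalue(x, y, mode="exhaustive")
            assert p == pytest.approx(brute_force_exhaustive_p(x, y), abs=1e-12)

    def test_montecarlo_seeded_and_add_one(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        p1, _ = permutation_pvalue(x, y, n_perm=200, seed=7)
        p2, _ = permutation_pvalue(x, y, n_perm=200, seed=7)
        assert p1 == p2
        assert 0 < p1 <= 1
        # add-one estimator: p is a multiple of 1/(n_perm + 1) and never 0
        assert (p1 * 201) == pytest.approx(round(p1 * 201))

    def test_constant_input_degenerate(self):
        p, flag = permutation_pvalue([1.0, 1.0, 1.0], [1, 2, 3])
        assert p == 1.0 and flag

    def test_exhaustive_size_limit(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalue(
                rng.normal(size=8), rng.normal(size=8), mode="exhaustive"
            )


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                bh_adjust(p), step_up_oracle(p), atol=1e-12
            )

    def test_order_equivariance(self, rng):
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(30)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBuildNetwork:
    def _mats(self):
        rho = np.array([[1.0, 0.8, -0.5], [0.8, 1.0, 0.1], [-0.5, 0.1, 1.0]])
        padj = np.array([[0.0, 0.05, 0.06], [0.05, 0.0, 0.9], [0.06, 0.9, 0.0]])
        return rho, padj

    def test_threshold_boundary(self):
        rho, padj = self._mats()
        net = build_network(rho, padj, alpha=0.05)
        assert net.adjacency[0, 1] == pytest.approx(0.8)  # padj exactly alpha
        assert net.adjacency[0, 2] == 0.0  # padj 0.06 > alpha
        assert net.n_edges == 1

    def test_diagonal_forced_zero(self):
        rho, padj = self._mats()
        net = build_network(rho, padj)
        np.testing.assert_array_equal(np.diag(net.adjacency), 0.0)

    def test_empty_network_flagged(self):
        rho, _ = self._mats()
        net = build_network(rho, np.ones((3, 3)) - np.eye(3) * 0)
        assert net.empty and net.n_edges == 0

    def test_asymmetric_rejected(self):
        rho, padj = self._mats()
        rho[0, 1] = 0.3
        with pytest.raises(ValueError):
            build_network(rho, padj)


class TestNormalizeAdjacency:
    def test_zero_matrix_gives_identity(self):
        np.testing.assert_allclose(
            normalize_adjacency(np.zeros((2, 2))), np.eye(2)
        )

    def test_two_node_unit_edge(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(a), np.full((2, 2), 0.5))

    def test_signs_dropped_and_nonnegative_symmetric(self, rng):
        a = rng.normal(size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        ahat = normalize_adjacency(a)
        assert np.all(ahat >= 0)
        np.testing.assert_allclose(ahat, ahat.T, atol=1e-12)
        np.testing.assert_allclose(
            normalize_adjacency(np.abs(a)), ahat, atol=1e-12
        )

    def test_ring_graph_constant_row_sums(self):
        # regular unit-weight graph: symmetric normalization gives equal rows
        n = 6
        a = np.zeros((n, n))
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1.0
        rows = normalize_adjacency(a).sum(axis=1)
        np.testing.assert_allclose(rows, rows[0])


class TestSummary:
    def _net(self, adjacency, ids=None):
        d = adjacency.shape[0]
        return build_network(
            np.eye(d) + adjacency,
            np.where(adjacency != 0, 0.0, 1.0) - np.eye(d),
            taxon_ids=ids,
        )

    def test_hand_counts(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        net = self._net(adj)
        summary = network_summary(net, ["P1", "P1", "P2"])
        assert summary["internal_edges"] == 1
        assert summary["external_edges"] == 2
        assert summary["n_nodes"] == 3

    def test_empty_network_all_zero(self):
        net = self._net(np.zeros((3, 3)))
        summary = network_summary(net, ["P1", "P1", "P2"])
        assert summary["n_nodes"] == 0
        assert summary["n_edges"] == 0

    def test_partition_invariant(self, rng):
        d = 10
        adj = (rng.random((d, d)) < 0.3).astype(float)
        adj = np.triu(adj, 1) + np.triu(adj, 1).T
        net = self._net(adj)
        labels = [f"P{i % 3}" for i in range(d)]
        summary = network_summary(net, labels)
        assert (
            summary["internal_edges"] + summary["external_edges"]
            == summary["n_edges"]
        )

    def test_missing_labels(self):
        net = self._net(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            network_summary(net, ["P1"])


class TestBuildCooccurrence:
    def _table(self, values):
        values = np.asarray(values, dtype=float)
        return AbundanceTable(
            taxon_ids=[f"t{i}" for i in range(values.shape[0])],
            sample_ids=[f"s{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_correlated_pair_is_only_edge(self, rng):
        n = 7
        base = np.arange(1.0, n + 1)
        noise = rng.permutation(n).astype(float)
        table = self._table([base, base * 2, noise])
        net = build_cooccurrence(table, alpha=0.05, mode="exhaustive")
        assert net.n_edges == 1
        assert net.adjacency[0, 1] != 0

    def test_determinism(self, rng):
        table = self._table(rng.random((4, 12)))
        a = build_cooccurrence(table, n_perm=100, seed=5)
        b = build_cooccurrence(table, n_perm=100, seed=5)
        np.testing.assert_array_equal(a.pvals, b.pvals)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_unique_pairs_counted(self, rng):
        table = self._table(rng.random((5, 10)))
        net = build_cooccurrence(table, n_perm=50, seed=0)
        iu = np.triu_indices(5, k=1)
        assert len(iu[0]) == 10
        assert np.all((net.pvals[iu] > 0) & (net.pvals[iu] <= 1))

    def test_edge_list_round_trip(self, rng, tmp_path):
        table = self._table(rng.random((4, 15)))
        net = build_cooccurrence(table, n_perm=200, seed=1, alpha=0.9)
        files = net.save(tmp_path)
        assert all(f.exists() for f in files)
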