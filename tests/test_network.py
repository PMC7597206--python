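"""Hemispheric graph construction and topological metrics.

Brute-force oracles (pure-Python BFS distances and direct triangle
enumeration) are kept independent of the implementation under test.
"""

import itertools
from collections import deque

import numpy as np
import pytest

from hemisym.exceptions import ValidationError
from hemisym.network import (DisconnectedGraphWarning, characteristic_path_length,
                             clustering_coefficient, edge_count,
                             global_efficiency, global_metrics,
                             local_efficiency, nodal_efficiency, random_rewire,
                             small_world_sigma, sparsity_threshold,
                             split_hemispheres, weighted_global_metrics,
                             weighted_nodal_efficiency)

# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def bfs_distances(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


def oracle_metrics(adj):
    """Direct transcription of the binary metric definitions."""
    n = adj.shape[0]
    d = bfs_distances(adj)
    # clustering: count edges among neighbours explicitly
    cp_nodes = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            cp_nodes.append(0.0)
            continue
        e = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
        cp_nodes.append(e / (len(nb) * (len(nb) - 1) / 2))
    finite = [d[i, j] for i in range(n) for j in range(n)
              if i != j and np.isfinite(d[i, j])]
    lp = float(np.mean(finite)) if finite else float("nan")
    inv = [1 / d[i, j] if np.isfinite(d[i, j]) else 0.0
           for i in range(n) for j in range(n) if i != j]
    eg = float(np.sum(inv) / (n * (n - 1)))
    enodal = np.array([
        sum((1 / d[i, j] if np.isfinite(d[i, j]) else 0.0)
            for j in range(n) if j != i) / (n - 1)
        for i in range(n)
    ])
    eloc_nodes = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            eloc_nodes.append(0.0)
            continue
        sub = adj[np.ix_(nb, nb)]
        ds = bfs_distances(sub)
        m = len(nb)
        vals = [1 / ds[a, b] if np.isfinite(ds[a, b]) else 0.0
                for a in range(m) for b in range(m) if a != b]
        eloc_nodes.append(np.sum(vals) / (m * (m - 1)))
    return (float(np.mean(cp_nodes)), lp, eg, float(np.mean(eloc_nodes)),
            enodal)


def graph(n, edges):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return a


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

class TestSplitHemispheres:
    def test_both_networks_have_18_nodes(self, montage, rng):
        m = rng.uniform(0, 1, (32, 32))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        left, right = split_hemispheres(m, montage)
        assert left.shape == (18, 18) and right.shape == (18, 18)

    def test_midline_submatrix_shared(self, montage, rng):
        m = rng.uniform(0, 1, (32, 32))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        left, right = split_hemispheres(m, montage)
        # midline nodes occupy the last 4 positions of both networks
        assert np.array_equal(left[14:, 14:], right[14:, 14:])
        mid_ix = montage.indices(montage.midline)
        assert np.array_equal(left[14:, 14:], m[np.ix_(mid_ix, mid_ix)])

    def test_interhemispheric_lateral_entries_absent(self, montage):
        m = np.zeros((32, 32))
        i, j = montage.index("Fp1"), montage.index("Fp2")
        m[i, j] = m[j, i] = 0.99
        left, right = split_hemispheres(m, montage)
        assert left.max() == 0 and right.max() == 0

    def test_wrong_size_rejected(self, montage):
        with pytest.raises(ValidationError):
            split_hemispheres(np.zeros((30, 30)), montage)


class TestSparsityThreshold:
    def test_ten_percent_keeps_15_edges(self, rng):
        raw = rng.uniform(0, 1, (18, 18))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0)
        assert edge_count(10, 18) == 15
        adj = sparsity_threshold(raw, 10)
        assert adj.n_edges == 15
        assert set(np.unique(adj.adjacency)) <= {0.0, 1.0}

    def test_full_threshold_gives_complete_graph(self):
        raw = np.ones((18, 18)) - np.eye(18)
        adj = sparsity_threshold(raw, 100)
        assert adj.n_edges == 153
        assert clustering_coefficient(adj) == 1.0

    def test_tie_break_follows_row_column_order(self):
        raw = np.ones((18, 18)) - np.eye(18)
        adj = sparsity_threshold(raw, 10)
        # oracle: first 15 upper-triangle slots in ascending (i, j) order
        expected = list(itertools.combinations(range(18), 2))[:15]
        got = list(zip(*np.nonzero(np.triu(adj.adjacency, 1))))
        assert got == expected

    def test_invalid_threshold_rejected(self, rng):
        raw = np.zeros((18, 18))
        for bad in (0, -5, 101):
            with pytest.raises(ValidationError):
                sparsity_threshold(raw, bad)


# ---------------------------------------------------------------------------
# Metric values on worked examples
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    def test_complete_graph(self):
        k18 = np.ones((18, 18)) - np.eye(18)
        assert clustering_coefficient(k18) == 1.0
        assert characteristic_path_length(k18) == 1.0
        assert global_efficiency(k18) == 1.0
        assert local_efficiency(k18) == 1.0
        assert np.allclose(nodal_efficiency(k18), 1.0)

    def test_star_graph_has_no_triangles(self):
        star = graph(6, [(0, k) for k in range(1, 6)])
        assert clustering_coefficient(star) == 0.0
        assert local_efficiency(star) == 0.0

    def test_triangle_plus_pendant(self):
        g = graph(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        assert clustering_coefficient(g) == pytest.approx(7 / 12, abs=1e-15)
        assert local_efficiency(g) == pytest.approx(7 / 12, abs=1e-15)

    def test_path_graph_p4(self):
        p4 = graph(4, [(0, 1), (1, 2), (2, 3)])
        assert characteristic_path_length(p4) == pytest.approx(10 / 6, abs=1e-15)
        assert global_efficiency(p4) == pytest.approx(13 / 18, abs=1e-15)

    def test_star4_nodal_efficiency(self):
        star = graph(4, [(0, 1), (0, 2), (0, 3)])
        e = nodal_efficiency(star)
        assert e[0] == pytest.approx(1.0)
        assert np.allclose(e[1:], 2 / 3)

    def test_empty_graph_degenerate_values(self):
        empty = np.zeros((5, 5))
        assert global_efficiency(empty) == 0.0
        with pytest.warns(DisconnectedGraphWarning):
            assert np.isnan(characteristic_path_length(empty))

    def test_disconnected_pairs_excluded_with_warning(self):
        two = graph(4, [(0, 1), (2, 3)])
        with pytest.warns(DisconnectedGraphWarning):
            assert characteristic_path_length(two) == 1.0


# ---------------------------------------------------------------------------
# Properties and oracle equivalence
# ---------------------------------------------------------------------------

def random_thresholded(rng, sparsity):
    raw = rng.uniform(0, 1, (18, 18))
    raw = (raw + raw.T) / 2
    np.fill_diagonal(raw, 0)
    return sparsity_threshold(raw, sparsity).adjacency


class TestOracleEquivalence:
    def test_metrics_match_bruteforce_on_random_graphs(self, rng):
        for k in range(40):
            adj = random_thresholded(rng, 5 + (35 * k) // 39)
            cp, lp, eg, eloc, enodal = oracle_metrics(adj)
            assert clustering_coefficient(adj) == pytest.approx(cp, abs=1e-12)
            with pytest.warns(DisconnectedGraphWarning) if np.isinf(
                    bfs_distances(adj)).any() else np.errstate():
                assert characteristic_path_length(adj) == pytest.approx(
                    lp, abs=1e-12, nan_ok=True)
            assert global_efficiency(adj) == pytest.approx(eg, abs=1e-12)
            assert local_efficiency(adj) == pytest.approx(eloc, abs=1e-12)
            assert np.allclose(nodal_efficiency(adj), enodal, atol=1e-12)

    def test_mean_nodal_efficiency_equals_global(self, rng):
        for _ in range(10):
            adj = random_thresholded(rng, 20)
            assert nodal_efficiency(adj).mean() == pytest.approx(
                global_efficiency(adj), abs=1e-12)

    def test_efficiency_at_least_inverse_path_length(self, rng):
        # harmonic-arithmetic mean inequality on connected graphs
        for _ in range(20):
            adj = random_thresholded(rng, 35)
            if np.isinf(bfs_distances(adj)).any():
                continue
            assert global_efficiency(adj) >= 1.0 / characteristic_path_length(adj) - 1e-12

    def test_adding_edges_never_decreases_efficiency(self, rng):
        raw = rng.uniform(0, 1, (18, 18))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0)
        prev = 0.0
        for s in range(5, 45, 5):
            eg = global_efficiency(sparsity_threshold(raw, s).adjacency)
            assert eg >= prev - 1e-12
            prev = eg

    def test_permutation_equivariance(self, rng):
        adj = random_thresholded(rng, 20)
        perm = rng.permutation(18)
        padj = adj[np.ix_(perm, perm)]
        assert clustering_coefficient(padj) == pytest.approx(
            clustering_coefficient(adj), abs=1e-12)
        assert global_efficiency(padj) == pytest.approx(
            global_efficiency(adj), abs=1e-12)
        assert local_efficiency(padj) == pytest.approx(
            local_efficiency(adj), abs=1e-12)
        assert np.allclose(nodal_efficiency(padj),
                           nodal_efficiency(adj)[perm], atol=1e-12)

    def test_weighted_metrics_reduce_to_binary_on_01_matrices(self, rng):
        adj = random_thresholded(rng, 25)
        wm = weighted_global_metrics(adj)
        with pytest.warns(DisconnectedGraphWarning) if np.isinf(
                bfs_distances(adj)).any() else np.errstate():
            lp = characteristic_path_length(adj)
        assert wm.cp == pytest.approx(clustering_coefficient(adj), abs=1e-12)
        assert wm.lp == pytest.approx(lp, abs=1e-12, nan_ok=True)
        assert wm.eg == pytest.approx(global_efficiency(adj), abs=1e-12)
        assert wm.eloc == pytest.approx(local_efficiency(adj), abs=1e-12)
        assert np.allclose(weighted_nodal_efficiency(adj),
                           nodal_efficiency(adj), atol=1e-12)


# ---------------------------------------------------------------------------
# Null model and sigma
# ---------------------------------------------------------------------------

class TestRewiring:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        adj = random_thresholded(rng, 20)
        new = random_rewire(adj, 300, rng)
        assert np.array_equal(new.sum(1), adj.sum(1))
        assert new.sum() == adj.sum()
        assert np.array_equal(new, new.T)
        assert np.all(np.diag(new) == 0)

    def test_fixed_seed_reproducible(self, rng):
        adj = random_thresholded(rng, 20)
        a = random_rewire(adj, 200, np.random.default_rng(5))
        b = random_rewire(adj, 200, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_self_null_gives_sigma_one(self, rng):
        adj = random_thresholded(rng, 30)
        # zero swap attempts: every "null" is the graph itself
        sigma, c_rand, l_rand = small_world_sigma(
            adj, n_null=3, rng=rng, swap_factor=0)
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        # ring of 18 nodes, each joined to 2 neighbours a side, plus a
        # couple of shortcuts (~10% rewiring)
        n = 18
        adj = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                adj[i, (i + d) % n] = adj[(i + d) % n, i] = 1
        rng = np.random.default_rng(0)
        adj = random_rewire(adj, 4, rng)
        sigma, _, _ = small_world_sigma(adj, n_null=40,
                                        rng=np.random.default_rng(1))
        assert sigma > 1.0

    def test_random_graph_sigma_near_one(self, rng):
        adj = random_thresholded(np.random.default_rng(3), 25)
        sigma, _, _ = small_world_sigma(adj, n_null=40,
                                        rng=np.random.default_rng(2))
        assert 0.6 < sigma < 1.5


class TestGlobalMetricsAggregate:
    def test_bundle_consistent_with_parts(self, rng):
        adj = random_thresholded(rng, 30)
        gm = global_metrics(adj, include_sigma=False)
        assert gm.cp == clustering_coefficient(adj)
        assert gm.eg == global_efficiency(adj)
        assert np.isnan(gm.sigma)
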