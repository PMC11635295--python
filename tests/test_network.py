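"""Graph-metric unit tests: closed forms, independent oracles, conventions."""

import numpy as np
import pytest

from nirsdoc.connectivity import FCMatrix
from nirsdoc.network import (
    BinaryNetwork,
    char_path_length,
    clustering_coeff,
    default_sparsity_grid,
    global_efficiency,
    local_efficiency,
    metric_auc,
    metrics_over_grid,
    shortest_paths,
    threshold_by_sparsity,
)
from tests.conftest import fc_from_matrix


def net_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return BinaryNetwork(adjacency=a, node_ids=np.arange(1, n + 1), sparsity=0.5)


# ---------------------------------------------------------------------------
# independent brute-force oracles

def floyd_warshall(adj):
    n = len(adj)
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_metrics(adj):
    """Lp/Cp/Eg/Eloc by exhaustive enumeration on the distance matrix."""
    n = len(adj)
    d = floyd_warshall(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = d[finite].mean() if finite.any() else np.nan
    eg = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)[off].mean()
    cp_terms, eloc_terms = [], []
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = len(nb)
        if k < 2:
            cp_terms.append(0.0)
            eloc_terms.append(0.0)
            continue
        e_i = sum(adj[u, v] for ai, u in enumerate(nb) for v in nb[ai + 1:])
        cp_terms.append(e_i / (k * (k - 1) / 2))
        sub = adj[np.ix_(nb, nb)]
        ds = floyd_warshall(sub)
        offs = ~np.eye(k, dtype=bool)
        eloc_terms.append(
            np.where(np.isfinite(ds) & offs, 1.0 / np.where(ds > 0, ds, np.inf), 0.0)[offs].mean()
        )
    return lp, float(np.mean(cp_terms)), float(eg), float(np.mean(eloc_terms))


# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_complete_graph_all_metrics_one(self):
        n = 5
        net = net_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
        assert char_path_length(net) == (1.0, 0)
        assert clustering_coeff(net) == 1.0
        assert global_efficiency(net) == 1.0
        assert local_efficiency(net) == 1.0

    def test_path_graph_three_nodes(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        lp, excl = char_path_length(net)
        assert lp == pytest.approx(4 / 3)
        assert excl == 0
        assert global_efficiency(net) == pytest.approx(5 / 6)
        assert local_efficiency(net) == 0.0
        assert clustering_coeff(net) == 0.0

    def test_triangle_clustering(self):
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert clustering_coeff(net) == 1.0

    def test_star_graph_no_triangles(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coeff(net) == 0.0

    def test_k4_local_efficiency(self):
        net = net_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert local_efficiency(net) == 1.0

    def test_empty_graph_eg_zero_lp_missing(self):
        net = net_from_edges(3, [])
        assert global_efficiency(net) == 0.0
        lp, excl = char_path_length(net)
        assert np.isnan(lp) and excl == 6

    def test_disconnected_lp_connected_pairs_convention(self):
        # edge 1-2 plus isolated node 3: Lp = 1 over the 2 connected ordered
        # pairs; 4 ordered pairs excluded
        net = net_from_edges(3, [(0, 1)])
        lp, excl = char_path_length(net)
        assert lp == 1.0
        assert excl == 4

    def test_path_distance(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_paths(net)
        assert d[0, 2] == 2.0

    def test_complete_k5_distances_all_one(self):
        net = net_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        d = shortest_paths(net)
        off = ~np.eye(5, dtype=bool)
        assert np.all(d[off] == 1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        p = rng.uniform(0.1, 0.9)
        a = rng.random((n, n)) < p
        a = np.triu(a, 1)
        a = a | a.T
        net = BinaryNetwork(adjacency=a, node_ids=np.arange(1, n + 1), sparsity=0.5)
        d_fw = floyd_warshall(a)
        assert np.array_equal(shortest_paths(net), d_fw)
        lp_o, cp_o, eg_o, eloc_o = brute_metrics(a)
        lp, _ = char_path_length(net)
        if np.isnan(lp_o):
            assert np.isnan(lp)
        else:
            assert lp == pytest.approx(lp_o, abs=1e-12)
        assert clustering_coeff(net) == pytest.approx(cp_o, abs=1e-12)
        assert global_efficiency(net) == pytest.approx(eg_o, abs=1e-12)
        assert local_efficiency(net) == pytest.approx(eloc_o, abs=1e-12)

    def test_networkx_cross_check(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(5)
        a = rng.random((10, 10)) < 0.4
        a = np.triu(a, 1)
        a = a | a.T
        net = BinaryNetwork(adjacency=a, node_ids=np.arange(1, 11), sparsity=0.5)
        g = nx.from_numpy_array(a.astype(int))
        assert global_efficiency(net) == pytest.approx(nx.global_efficiency(g), abs=1e-12)
        assert local_efficiency(net) == pytest.approx(nx.local_efficiency(g), abs=1e-12)


class TestThresholding:
    def test_edge_count_round_half_up(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, (4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = threshold_by_sparsity(fc_from_matrix(r), 0.5)
        assert net.n_edges == 3  # round(0.5 * 6)

    def test_full_sparsity_complete_graph(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, (5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = threshold_by_sparsity(fc_from_matrix(r), 1.0)
        assert net.n_edges == 10

    def test_tie_break_lexicographic_and_stable(self):
        # three entries tied at 0.5 straddling a cutoff of 2 edges: the
        # lexicographically first pairs win, identically across runs
        r = np.eye(4)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            r[i, j] = r[j, i] = 0.5
        r[0, 3] = r[3, 0] = 0.9
        fc = fc_from_matrix(r)
        nets = [threshold_by_sparsity(fc, 0.5) for _ in range(3)]  # k = 3
        edge_sets = [frozenset(map(tuple, np.argwhere(np.triu(n.adjacency)))) for n in nets]
        assert len(set(edge_sets)) == 1
        assert edge_sets[0] == frozenset({(0, 3), (0, 1), (0, 2)})

    def test_keeps_largest_raw_not_absolute(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = -0.9
        r[0, 2] = r[2, 0] = 0.1
        r[1, 2] = r[2, 1] = 0.2
        net = threshold_by_sparsity(fc_from_matrix(r), 1 / 3)
        assert net.adjacency[1, 2] and not net.adjacency[0, 1]

    def test_zero_edges_warns_not_raises(self):
        r = np.eye(3)
        with pytest.warns(UserWarning, match="0 edges"):
            net = threshold_by_sparsity(fc_from_matrix(r), 0.05)
        assert net.n_edges == 0

    def test_eg_monotone_in_sparsity(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(-1, 1, (12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        fc = fc_from_matrix(r)
        egs = [global_efficiency(threshold_by_sparsity(fc, s))
               for s in default_sparsity_grid()]
        assert np.all(np.diff(egs) >= 0)


class TestAUC:
    def test_constant_curve(self):
        grid = default_sparsity_grid()
        assert metric_auc(np.full(16, 2.0), grid) == pytest.approx(0.75 * 2.0)

    def test_zero_curve(self):
        assert metric_auc(np.zeros(16), default_sparsity_grid()) == 0.0

    def test_linear_curve_exact(self):
        grid = default_sparsity_grid()
        assert metric_auc(grid, grid) == pytest.approx((0.80**2 - 0.05**2) / 2)

    def test_missing_values_error_names_points(self):
        grid = default_sparsity_grid()
        curve = np.ones(16)
        curve[3] = np.nan
        with pytest.raises(ValueError, match="0.2"):
            metric_auc(curve, grid)


class TestMetricsOverGrid:
    def test_ranges_and_shape(self, rng):
        r = rng.uniform(-1, 1, (16, 16))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        m = metrics_over_grid(fc_from_matrix(r))
        for name in ("Cp", "Eg", "Eloc"):
            assert np.all((m.curves[name] >= 0) & (m.curves[name] <= 1))
        assert np.all(m.curves["Lp"] >= 1)
        assert set(m.auc) == {"Lp", "Cp", "Eg", "Eloc"}

    def test_metric_subset(self, rng):
        r = rng.uniform(-1, 1, (10, 10))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        m = metrics_over_grid(fc_from_matrix(r), metrics=("Eg", "Lp"))
        assert set(m.curves) == {"Eg", "Lp"}
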