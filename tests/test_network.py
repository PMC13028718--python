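import networkx as nx
import numpy as np
import pytest

from biocrust import (
    AbundanceTable,
    BlockSpec,
    CooccurrenceNetwork,
    SimulationConfig,
    bh_fdr,
    build_network,
    read_network,
    simulate_blocks,
    spearman_matrix,
    topology_panel,
    write_network,
    zipi,
)
from biocrust.network import classify_role


def _table_from_columns(cols):
    arr = np.array(cols).T
    return AbundanceTable(
        [f"s{i}" for i in range(arr.shape[0])],
        [f"a{j}" for j in range(arr.shape[1])],
        arr,
    )


class TestSpearman:
    def test_concordant_discordant_and_hand_value(self):
        t = _table_from_columns(
            [[1, 2, 3, 4], [2, 4, 6, 8], [8, 6, 4, 2], [1, 3, 2, 4]]
        )
        rho, p = spearman_matrix(t)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        # rank-formula oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) without ties
        assert rho[0, 3] == pytest.approx(1 - 6 * 2 / (4 * 15))
        assert rho[0, 3] == pytest.approx(0.8)

    def test_constant_asv_never_an_edge(self):
        t = _table_from_columns([[1, 2, 3, 4, 5], [5, 5, 5, 5, 5], [2, 1, 4, 3, 5]])
        rho, p = spearman_matrix(t)
        assert np.isnan(rho[0, 1]) and np.isnan(p[1, 2])
        net = build_network(t, rho_threshold=0.5, q_threshold=0.999, top_n=None)
        assert "a1" not in net.graph.nodes

    def test_matches_scipy_on_clean_data(self, rng):
        from scipy import stats

        counts = rng.integers(0, 60, size=(12, 8)) + 1
        t = AbundanceTable(
            [f"s{i}" for i in range(12)], [f"a{j}" for j in range(8)], counts
        )
        rho, p = spearman_matrix(t)
        ref_rho, ref_p = stats.spearmanr(counts.astype(float), axis=0)
        np.testing.assert_allclose(rho, ref_rho, atol=1e-12)
        iu = np.triu_indices(8, k=1)
        np.testing.assert_allclose(p[iu], np.asarray(ref_p)[iu], atol=1e-10)

    def test_too_few_samples_rejected(self):
        t = _table_from_columns([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError):
            spearman_matrix(t)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_step_up_hand_computation(self):
        # q_i = min over j>=i of p_(j) * m / j  ->  all 0.03 here
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_order_preserving_monotone(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestBuildNetwork:
    def test_unreachable_threshold_gives_empty_network(self, rng):
        counts = rng.integers(1, 100, size=(10, 20))
        t = AbundanceTable([f"s{i}" for i in range(10)], [f"a{j}" for j in range(20)], counts)
        with pytest.warns(UserWarning, match="empty"):
            net = build_network(t, rho_threshold=0.999999, q_threshold=1e-12, top_n=None)
        assert net.n_edges == 0

    def test_edge_filter_soundness_exhaustive(self):
        """Every built edge satisfies both thresholds; every excluded pair
        among the input ASVs violates at least one (independent re-check)."""
        cfg = SimulationConfig(
            n_samples=15, n_asvs=50, depth=4000, seed=5, noise_sd=0.5,
            blocks=[BlockSpec(15, 1, 0, 1.5), BlockSpec(15, -1, 0, 1.5)],
        )
        t = simulate_blocks(cfg)
        net = build_network(t, rho_threshold=0.6, q_threshold=0.001, top_n=None)
        assert net.n_edges > 0
        rho, p = spearman_matrix(t.drop_empty_asvs())
        sub = t.drop_empty_asvs()
        iu = np.triu_indices(sub.n_asvs, k=1)
        q = np.full_like(p, np.nan)
        q[iu] = bh_fdr(p[iu])
        idx = {a: i for i, a in enumerate(sub.asv_ids)}
        passing = set()
        for k in range(len(iu[0])):
            i, j = iu[0][k], iu[1][k]
            r, qq = rho[i, j], q[i, j]
            if not np.isnan(r) and not np.isnan(qq) and abs(r) > 0.6 and qq < 0.001:
                passing.add(frozenset((sub.asv_ids[i], sub.asv_ids[j])))
        built = {frozenset((u, v)) for u, v in net.graph.edges}
        assert built == passing
        for u, v, d in net.graph.edges(data=True):
            assert abs(d["weight"]) > 0.6 and d["q"] < 0.001
            assert d["weight"] == pytest.approx(rho[idx[u], idx[v]])

    def test_planted_blocks_recovered(self):
        cfg = SimulationConfig(
            n_samples=20, n_asvs=40, depth=5000, seed=1, noise_sd=0.1,
            blocks=[BlockSpec(20, 1, 0, 2.0), BlockSpec(20, -1, 0, 2.0)],
        )
        t = simulate_blocks(cfg)
        net = build_network(t, top_n=None)
        planted = {a: (0 if i < 20 else 1) for i, a in enumerate(t.asv_ids)}
        for u, v, d in net.graph.edges(data=True):
            if planted[u] == planted[v]:
                assert d["weight"] > 0
            else:
                assert d["weight"] < 0
        # module detection recovers the planted two-block split exactly
        from sklearn.metrics import adjusted_rand_score

        nodes = list(net.graph.nodes)
        ari = adjusted_rand_score(
            [planted[n] for n in nodes], [net.modules[n] for n in nodes]
        )
        assert ari == pytest.approx(1.0)


class TestTopologyPanel:
    def test_complete_graph_closed_form(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.9
        net = CooccurrenceNetwork(g, {n: 0 for n in g.nodes})
        panel = topology_panel(net, compute_rm=False)
        assert panel.avgK == pytest.approx(3.0)
        assert panel.D == pytest.approx(1.0)
        assert panel.avgCC == pytest.approx(1.0)
        assert panel.GD == pytest.approx(1.0)
        assert panel.E == pytest.approx(1.0)
        assert panel.HD == pytest.approx(1.0)
        assert panel.Con == pytest.approx(1.0)
        assert panel.positive_links_pct == 100.0

    @pytest.mark.parametrize(
        "n,e,avgk,dens",
        [(319, 5536, 34.71, 0.109), (312, 4127, 26.46, 0.085), (267, 8497, 63.65, 0.239)],
    )
    def test_degree_density_identities(self, n, e, avgk, dens):
        """avgK = 2E/N and D = 2E/(N(N-1)) reproduce the printed panel values
        for the internally consistent treatment networks."""
        g = nx.gnm_random_graph(n, e, seed=0)
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.8
        net = CooccurrenceNetwork(g, {node: 0 for node in g.nodes})
        panel = topology_panel(net, compute_rm=False)
        assert panel.avgK == pytest.approx(avgk, abs=0.005)
        assert panel.D == pytest.approx(dens, abs=0.0005)
        assert panel.positive_links_pct + panel.negative_links_pct == pytest.approx(100)

    def test_path_graph_geodesics(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.7
        net = CooccurrenceNetwork(g, {n: 0 for n in g.nodes})
        panel = topology_panel(net, compute_rm=False)
        assert panel.GD == pytest.approx((1 + 1 + 2) / 3)
        assert panel.E == pytest.approx((1 + 1 + 0.5) / 3)
        assert panel.HD == pytest.approx(1 / panel.E)

    def test_disconnected_connectedness(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.7)
        g.add_edge("c", "d", weight=-0.7)
        net = CooccurrenceNetwork(g, {"a": 0, "b": 0, "c": 1, "d": 1})
        panel = topology_panel(net, compute_rm=False)
        assert panel.Con == pytest.approx(2 / 6)
        assert panel.positive_links_pct == pytest.approx(50.0)

    def test_rm_near_zero_for_random_graph(self):
        """Degree-preserving nulls of an Erdos-Renyi graph have the same
        modularity as the graph itself in expectation."""
        g = nx.gnm_random_graph(40, 160, seed=3)
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.8
        from biocrust.network import _detect_modules

        net = CooccurrenceNetwork(g, _detect_modules(g))
        panel = topology_panel(net, n_null=30, seed=0)
        assert abs(panel.RM) < 0.15


class TestZiPi:
    def test_all_edges_within_module_gives_pi_zero(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        roles = zipi(CooccurrenceNetwork(g, {n: 0 for n in g.nodes}))
        assert all(r.pi == 0.0 for r in roles)

    def test_even_split_over_two_modules(self):
        g = nx.Graph()
        g.add_edge("x", "m1", weight=1.0)
        g.add_edge("x", "m2", weight=1.0)
        g.add_edge("m1", "m1b", weight=1.0)
        g.add_edge("m2", "m2b", weight=1.0)
        modules = {"x": 0, "m1": 1, "m1b": 1, "m2": 2, "m2b": 2}
        roles = {r.asv_id: r for r in zipi(CooccurrenceNetwork(g, modules))}
        assert roles["x"].pi == pytest.approx(1 - 2 * 0.25)

    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (3.0, 0.5, "module hub"),
            (1.0, 0.7, "connector"),
            (3.0, 0.7, "network hub"),
            (0.0, 0.0, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundary equality -> low quadrant
            (2.5, 0.7, "connector"),
            (3.0, 0.62, "module hub"),
        ],
    )
    def test_quadrant_classification(self, zi, pi, expected):
        assert classify_role(zi, pi) == expected

    def test_zi_mean_zero_within_module(self, rng):
        g = nx.gnm_random_graph(30, 90, seed=1)
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.9
        from biocrust.network import _detect_modules

        modules = _detect_modules(g)
        roles = zipi(CooccurrenceNetwork(g, modules))
        by_mod = {}
        for r in roles:
            by_mod.setdefault(r.module, []).append(r.zi)
        for zis in by_mod.values():
            if len(zis) > 1 and np.std(zis) > 0:
                assert np.mean(zis) == pytest.approx(0.0, abs=1e-9)
        assert all(0 <= r.pi < 1 for r in roles)


class TestNetworkIO:
    def test_empty_network_round_trip(self, tmp_path):
        net = CooccurrenceNetwork(nx.Graph(), {})
        path = tmp_path / "empty.tsv"
        write_network(net, path, format="edgelist")
        assert read_network(path, format="edgelist").n_edges == 0

    def test_signed_path_graph_edge_list(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.8, q=1e-5)
        g.add_edge("b", "c", weight=-0.7, q=2e-4)
        net = CooccurrenceNetwork(g, {"a": 0, "b": 0, "c": 1})
        path = tmp_path / "net.tsv"
        write_network(net, path, format="edgelist")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3  # header + 2 signed edges
        back = read_network(path, format="edgelist")
        assert back.graph["b"]["c"]["weight"] == pytest.approx(-0.7)

    @pytest.mark.parametrize("fmt", ["graphml", "edgelist"])
    def test_random_network_round_trip(self, fmt, tmp_path, rng):
        g = nx.gnm_random_graph(50, 120, seed=9)
        g = nx.relabel_nodes(g, lambda i: f"ASV{i}")
        for u, v in g.edges:
            g[u][v]["weight"] = float(np.round(rng.uniform(-1, 1), 6)) or 0.5
            g[u][v]["q"] = float(np.round(rng.uniform(0, 1e-3), 9))
        from biocrust.network import _detect_modules

        net = CooccurrenceNetwork(g, _detect_modules(g))
        path = tmp_path / f"net.{fmt}"
        write_network(net, path, format=fmt)
        back = read_network(path, format=fmt)
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in net.graph.edges
        }
        for u, v, d in net.graph.edges(data=True):
            assert back.graph[u][v]["weight"] == pytest.approx(d["weight"])
        if fmt == "graphml":
            assert set(back.graph.nodes) == set(net.graph.nodes)
            assert back.modules == net.modules

    def test_unknown_format_rejected(self, tmp_path):
        net = CooccurrenceNetwork(nx.Graph(), {})
        with pytest.raises(ValueError):
            write_network(net, tmp_path / "x", format="gexf")
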