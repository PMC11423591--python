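import networkx as nx
import numpy as np
import pandas as pd
import pytest

from planktonet import (build_network, detect_modules, node_metrics,
                        powerlaw_fit, topology_summary)
from planktonet.network import PI_THRESHOLD, ZI_THRESHOLD


@pytest.fixture
def two_triangles():
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


class TestBuildNetwork:
    def test_perfectly_correlated_features_get_positive_edge(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, size=20)
        t = pd.DataFrame({
            "u": base, "v": base * 3,                   # identical ranks
            "w": rng.integers(10, 100, size=20),
            "filler": rng.integers(100, 200, size=20),
        }, index=[f"s{i}" for i in range(20)])
        g = build_network(t, prevalence_min=0.5, r_min=0.6, q_max=0.05)
        assert g.has_edge("u", "v")
        assert g["u"]["v"]["sign"] == "positive"
        assert g["u"]["v"]["r"] == pytest.approx(1.0)

    def test_no_self_loops_and_thresholds_respected(self, neutral_dataset):
        g = build_network(neutral_dataset.table, prevalence_min=0.3,
                          r_min=0.5, q_max=0.2)
        assert nx.number_of_selfloops(g) == 0
        for _, _, attrs in g.edges(data=True):
            assert abs(attrs["r"]) >= 0.5
            assert attrs["q"] <= 0.2

    def test_false_edge_rate_controlled_on_independent_features(self):
        # independent features: the BH-passing fraction of tested pairs
        # stays at or below q_max on average
        rates = []
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            t = pd.DataFrame(rng.integers(1, 100, size=(38, 60)),
                             index=[f"s{i}" for i in range(38)],
                             columns=[f"f{j}" for j in range(60)])
            g = build_network(t, prevalence_min=0.0, r_min=0.0, q_max=0.05)
            rates.append(g.number_of_edges() / g.graph["n_tested_pairs"])
        assert np.mean(rates) <= 0.05


class TestDetectModules:
    def test_two_disconnected_triangles_q_half(self, two_triangles):
        labels, q = detect_modules(two_triangles)
        assert q == pytest.approx(0.5)
        assert len(set(labels.values())) == 2

    def test_complete_graph_single_module_zero_q(self):
        labels, q = detect_modules(nx.complete_graph(6))
        assert len(set(labels.values())) == 1
        assert q == pytest.approx(0.0)

    def test_partition_invariant_to_node_relabeling(self, two_triangles):
        mapping = {i: f"n{(i * 5) % 6}" for i in range(6)}
        relabeled = nx.relabel_nodes(two_triangles, mapping)
        labels1, q1 = detect_modules(two_triangles)
        labels2, q2 = detect_modules(relabeled)
        assert q1 == pytest.approx(q2)
        groups1 = {frozenset(mapping[n] for n in labels1 if labels1[n] == m)
                   for m in set(labels1.values())}
        groups2 = {frozenset(n for n in labels2 if labels2[n] == m)
                   for m in set(labels2.values())}
        assert groups1 == groups2

    def test_edgeless_network_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            detect_modules(g)


class TestTopologySummary:
    def test_triangle(self):
        ts = topology_summary(nx.complete_graph(3))
        assert ts.avg_clustering == pytest.approx(1.0)
        assert ts.avg_path_length == pytest.approx(1.0)
        assert ts.n_nodes == 3 and ts.n_edges == 3

    def test_three_node_path(self):
        ts = topology_summary(nx.path_graph(3))
        assert ts.avg_clustering == pytest.approx(0.0)
        assert ts.avg_path_length == pytest.approx(4.0 / 3.0)

    def test_adding_an_edge_never_decreases_average_degree(self, two_triangles):
        before = topology_summary(two_triangles).avg_degree
        two_triangles.add_edge(0, 3)
        assert topology_summary(two_triangles).avg_degree > before


class TestNodeMetrics:
    def test_intra_module_node_has_zero_participation(self, two_triangles):
        detect_modules(two_triangles)
        m = node_metrics(two_triangles)
        assert (m["pi"] == 0.0).all()      # no edges cross the two modules
        assert (m["role"] == "peripheral").all()

    def test_star_center_has_full_betweenness(self):
        g = nx.star_graph(4)               # node 0 is the hub
        detect_modules(g)
        m = node_metrics(g)
        assert m.loc[0, "betweenness"] == pytest.approx(1.0)
        assert m.loc[1, "betweenness"] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_zi_pi_match_brute_force_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(20, 0.25, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty random draw")
        modules, _ = detect_modules(g)
        m = node_metrics(g)
        for node in g.nodes:
            mod = modules[node]
            members = [v for v in g.nodes if modules[v] == mod]
            within = {v: sum(1 for nb in g.neighbors(v)
                             if modules[nb] == mod) for v in members}
            vals = np.array(list(within.values()), float)
            sd = vals.std()
            zi = 0.0 if sd == 0 else (within[node] - vals.mean()) / sd
            k = g.degree(node)
            pi = 0.0 if k == 0 else 1.0 - sum(
                (sum(1 for nb in g.neighbors(node) if modules[nb] == mm) / k) ** 2
                for mm in set(modules.values()))
            assert m.loc[node, "zi"] == pytest.approx(zi, abs=1e-9)
            assert m.loc[node, "pi"] == pytest.approx(pi, abs=1e-9)

    def test_role_thresholds(self):
        # hub-and-connector construction: central node linked into 3 modules
        g = nx.Graph()
        for mod in range(3):
            for i in range(4):
                g.add_edge(f"m{mod}core", f"m{mod}leaf{i}")
        g.add_edges_from([("bridge", "m0core"), ("bridge", "m1core"),
                          ("bridge", "m2core")])
        detect_modules(g)
        m = node_metrics(g)
        assert m.loc["bridge", "pi"] >= PI_THRESHOLD
        assert "connector" in m.loc["bridge", "role"] \
            or m.loc["bridge", "role"] == "network hub"
        assert (m.loc[[f"m{i}core" for i in range(3)], "zi"]
                > m.loc["m0leaf0", "zi"]).all()


class TestPowerlawFit:
    def test_exact_power_law_recovered(self):
        ks = np.arange(1, 21)
        degs = np.repeat(ks, np.round(1000.0 * ks ** -2.0).astype(int))
        fit = powerlaw_fit(degs)
        assert fit.assessable
        assert fit.gamma == pytest.approx(2.0, abs=0.1)
        assert fit.r2 > 0.99
        assert fit.p < 0.001

    def test_uniform_degrees_fit_poorly(self):
        degs = np.repeat(np.arange(1, 11), 50)
        fit = powerlaw_fit(degs)
        assert fit.assessable and fit.r2 < 0.5

    def test_too_few_distinct_degrees_flagged(self):
        fit = powerlaw_fit([3] * 30)
        assert not fit.assessable and np.isnan(fit.gamma)
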