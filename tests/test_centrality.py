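"""Phase IV: weighted betweenness and eigenvector centrality.

The betweenness implementation is cross-checked against an exhaustive
all-simple-paths oracle on small random graphs; the eigenvector
implementation against dense symmetric eigendecomposition.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from dice.centrality import (
    centrality_delta,
    centrality_table,
    eigenvector_centrality,
    weighted_betweenness,
)
from dice.errors import DiceInputError
from dice.network import ConditionNetwork


def net_from_edges(edges, condition="c"):
    """edges: iterable of (u, v, cc). distance = 1 - |cc|, affinity = |cc|."""
    g = nx.Graph()
    for u, v, cc in edges:
        g.add_edge(u, v, cc=cc, affinity=abs(cc), distance=1 - abs(cc))
    return ConditionNetwork(condition=condition, graph=g)


def net_with_distances(dist_edges, condition="c"):
    """edges: iterable of (u, v, distance); affinity = 1 - distance."""
    g = nx.Graph()
    for u, v, d in dist_edges:
        g.add_edge(u, v, cc=1 - d, affinity=1 - d, distance=d)
    return ConditionNetwork(condition=condition, graph=g)


def betweenness_oracle(graph):
    """Exhaustive all-simple-paths shortest-path enumeration (independent of
    the Brandes accumulation under test)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    cred = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        best, paths = np.inf, []
        for path in nx.all_simple_paths(graph, s, t):
            length = sum(
                graph[u][v]["distance"] for u, v in zip(path, path[1:])
            )
            if length < best - 1e-12:
                best, paths = length, [path]
            elif abs(length - best) <= 1e-12:
                paths.append(path)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                cred[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0 if n >= 3 else 1.0
    return {v: c / norm for v, c in cred.items()}


class TestWeightedBetweenness:
    def test_middle_of_path(self):
        net = net_with_distances([("A", "B", 1.0), ("B", "C", 1.0)])
        b = weighted_betweenness(net)
        assert b["B"] == pytest.approx(1.0) and b["A"] == b["C"] == 0.0

    def test_star_center(self):
        net = net_with_distances([("X", l, 1.0) for l in "abc"])
        b = weighted_betweenness(net)
        assert b["X"] == pytest.approx(1.0)
        assert all(b[l] == 0.0 for l in "abc")

    def test_four_cycle_with_heavy_edge(self):
        # distances AB=0.1 BC=0.1 CD=0.1 DA=0.5: every A-D path detours
        # through B and C, so B = C = 2/3 and A = D = 0
        net = net_with_distances(
            [("A", "B", 0.1), ("B", "C", 0.1), ("C", "D", 0.1), ("D", "A", 0.5)]
        )
        b = weighted_betweenness(net)
        assert b["B"] == pytest.approx(2 / 3, abs=1e-12)
        assert b["C"] == pytest.approx(2 / 3, abs=1e-12)
        assert b["A"] == b["D"] == 0.0

    def test_two_node_graph_is_zero(self):
        net = net_with_distances([("A", "B", 0.3)])
        assert weighted_betweenness(net) == {"A": 0.0, "B": 0.0}

    def test_negative_distance_rejected(self):
        net = net_with_distances([("A", "B", -0.1), ("B", "C", 0.5)])
        with pytest.raises(DiceInputError):
            weighted_betweenness(net)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        """>= 200 random connected graphs with <= 8 nodes, random distances."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            n = int(rng.integers(3, 9))
            p = float(rng.uniform(0.3, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g) or g.number_of_edges() == 0:
                continue
            net = net_with_distances(
                [(u, v, float(rng.uniform(0.05, 1.0))) for u, v in g.edges]
            )
            ours = weighted_betweenness(net)
            oracle = betweenness_oracle(net.graph)
            for v in net.graph.nodes:
                assert ours[v] == pytest.approx(oracle[v], abs=1e-9)
            checked += 1

    def test_uniform_weights_match_unweighted(self, rng):
        g = nx.gnp_random_graph(10, 0.4, seed=5)
        net = net_with_distances([(u, v, 0.37) for u, v in g.edges])
        ours = weighted_betweenness(net)
        ref = nx.betweenness_centrality(g, normalized=True)
        for v in g.nodes:
            assert ours[v] == pytest.approx(ref[v], abs=1e-9)


class TestEigenvectorCentrality:
    def test_triangle_symmetry(self):
        net = net_from_edges([("A", "B", 0.8), ("B", "C", 0.8), ("A", "C", 0.8)])
        e = eigenvector_centrality(net)
        for v in "ABC":
            assert e[v] == pytest.approx(1 / np.sqrt(3), abs=1e-9)

    def test_path_exact_values(self):
        net = net_from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        e = eigenvector_centrality(net)
        assert e["B"] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert e["A"] == pytest.approx(0.5, abs=1e-9)
        assert e["C"] == pytest.approx(0.5, abs=1e-9)

    def test_minor_component_goes_to_zero(self):
        net = net_from_edges(
            [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0), ("X", "Y", 1.0)]
        )
        e = eigenvector_centrality(net)
        for v in "ABC":
            assert e[v] == pytest.approx(1 / np.sqrt(3), abs=1e-8)
        assert e["X"] == pytest.approx(0.0, abs=1e-8)
        assert e["Y"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_dense_eigendecomposition(self):
        """Random graphs with <= 12 nodes vs numpy.linalg.eigh."""
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 50:
            n = int(rng.integers(3, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            net = net_from_edges(
                [(u, v, float(rng.uniform(0.1, 1.0))) for u, v in g.edges]
            )
            ours = eigenvector_centrality(net)
            nodes = list(net.graph.nodes)
            a = nx.to_numpy_array(net.graph, nodelist=nodes, weight="affinity")
            w, v = np.linalg.eigh(a)
            vec = np.abs(v[:, np.argmax(w)])
            vec /= np.linalg.norm(vec)
            for i, node in enumerate(nodes):
                assert ours[node] == pytest.approx(vec[i], abs=1e-8)
            checked += 1

    def test_nonnegative_and_unit_norm(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        net = net_from_edges(
            [(u, v, float(rng.uniform(-1, 1))) for u, v in g.edges]
        )
        e = eigenvector_centrality(net)
        vals = np.array(list(e.values()))
        assert (vals >= 0).all()
        assert np.linalg.norm(vals) == pytest.approx(1.0, abs=1e-9)

    def test_bipartite_graph_converges(self):
        # even cycles are bipartite (+/- lambda pair); the diagonal shift
        # must still converge to the Perron vector
        net = net_from_edges(
            [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0), ("D", "A", 1.0)]
        )
        e = eigenvector_centrality(net)
        for v in "ABCD":
            assert e[v] == pytest.approx(0.5, abs=1e-9)


class TestCentralityDelta:
    def test_absolute_difference_and_symmetry(self):
        import pandas as pd

        t1 = pd.DataFrame(
            {"betweenness": [0.4, 0.0], "eigenvector": [0.1, 0.9]}, index=["A", "B"]
        )
        t2 = pd.DataFrame(
            {"betweenness": [0.1, 0.0], "eigenvector": [0.5, 0.9]}, index=["A", "B"]
        )
        d = centrality_delta(t1, t2)
        assert d.loc["A", "delta_betweenness"] == pytest.approx(0.3)
        assert d.loc["B", "delta_eigenvector"] == 0.0
        d_swap = centrality_delta(t2, t1)
        assert (d == d_swap).all().all()

    def test_node_set_mismatch_rejected(self):
        import pandas as pd

        t1 = pd.DataFrame({"betweenness": [0.1], "eigenvector": [0.1]}, index=["A"])
        t2 = pd.DataFrame({"betweenness": [0.1], "eigenvector": [0.1]}, index=["B"])
        with pytest.raises(DiceInputError):
            centrality_delta(t1, t2)


class TestCentralityTable:
    def test_identical_networks_give_zero_deltas(self):
        net = net_from_edges([("A", "B", 0.5), ("B", "C", 0.7)], "x")
        net2 = ConditionNetwork(condition="y", graph=net.graph.copy())
        t = centrality_table(net, net2)
        assert (t["delta_betweenness"] == 0).all()
        assert (t["delta_eigenvector"] == 0).all()

    def test_columns_and_invariants(self, rng):
        g = nx.gnp_random_graph(10, 0.5, seed=11)
        e1 = [(u, v, float(rng.uniform(0.2, 0.9))) for u, v in g.edges]
        e2 = [(u, v, float(rng.uniform(0.2, 0.9))) for u, v in g.edges]
        t = centrality_table(net_from_edges(e1, "a"), net_from_edges(e2, "b"))
        assert ((t["betweenness_c1"] >= 0) & (t["betweenness_c1"] <= 1)).all()
        for tag in ("c1", "c2"):
            assert np.linalg.norm(t[f"eigen_{tag}"]) == pytest.approx(1.0, abs=1e-8)
            assert (t[f"eigen_{tag}"] >= 0).all()
        np.testing.assert_allclose(
            t["delta_betweenness"],
            (t["betweenness_c2"] - t["betweenness_c1"]).abs(),
            atol=1e-12,
        )
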