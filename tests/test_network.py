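"""Correlation edges, catalog intersection, betweenness centrality against
a hand-rolled shortest-path oracle, and key-gene ranking."""

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from co2prof import (
    GeneNetwork,
    InteractionCatalog,
    betweenness_centrality,
    build_signal_net,
    correlation_edges,
    rank_key_genes,
)
from co2prof.network import correlation_pvalue

from conftest import matrix_from_groups


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths
    (BFS distances + depth-first path counting; no library centrality)."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    directed = g.is_directed()

    def neighbors(u):
        return g.successors(u) if directed else g.neighbors(u)

    def dists_from(s):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        return dist

    def all_shortest_paths(s, t, dist):
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in neighbors(u):
                if dist.get(w) == dist[u] + 1 and dist.get(t) is not None and dist[w] <= dist[t]:
                    path.append(w)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    for s in nodes:
        dist = dists_from(s)
        for t in nodes:
            if t == s or t not in dist:
                continue
            paths = all_shortest_paths(s, t, dist)
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = (n - 1) * (n - 2) if directed else (n - 1) * (n - 2)
    # undirected: each unordered pair counted twice above
    scale = 1.0 / norm if directed else 1.0 / norm
    return {v: score[v] * scale for v in nodes}


def network_from_edges(edges, directed=True) -> GeneNetwork:
    g = nx.DiGraph()
    for u, v in edges:
        g.add_edge(u, v, relations=("activation",))
    return GeneNetwork(graph=g)


class TestCorrelationEdges:
    def test_hand_t_transform(self):
        """r = 0.7 over 9 points gives t ~ 2.593 on 7 df, p ~ 0.036."""
        assert correlation_pvalue(0.7, 9) == pytest.approx(0.0358, abs=0.0005)

    def test_identical_rows_are_an_edge(self):
        m = matrix_from_groups(
            {
                "a": [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
                "b": [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
            }
        )
        edges = correlation_edges(m, ["a", "b"])
        assert len(edges) == 1
        assert edges.iloc[0]["r"] == pytest.approx(1.0)
        assert edges.iloc[0]["p"] <= 1e-12

    def test_negative_pair_excluded_without_abs(self):
        m = matrix_from_groups(
            {
                "a": [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
                "b": [[9.0, 8.0, 7.0], [6.0, 5.0, 4.0], [3.0, 2.0, 1.0]],
            }
        )
        assert len(correlation_edges(m, ["a", "b"], use_abs=True)) == 1
        assert len(correlation_edges(m, ["a", "b"], use_abs=False)) == 0

    def test_zero_variance_gene_skipped_with_warning(self):
        m = matrix_from_groups(
            {
                "a": [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
                "flat": [[2.0, 2.0, 2.0], [2.0, 2.0, 2.0], [2.0, 2.0, 2.0]],
            }
        )
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            edges = correlation_edges(m, ["a", "flat"])
        assert edges.empty

    def test_gene_order_symmetry(self):
        rng = np.random.default_rng(8)
        vals = {f"g{i}": [list(rng.normal(5, 1, 3)) for _ in range(3)] for i in range(6)}
        m = matrix_from_groups(vals)
        genes = list(vals)
        e1 = correlation_edges(m, genes)
        e2 = correlation_edges(m, genes[::-1])
        pairs1 = {frozenset((a, b)) for a, b in zip(e1["gene_a"], e1["gene_b"])}
        pairs2 = {frozenset((a, b)) for a, b in zip(e2["gene_a"], e2["gene_b"])}
        assert pairs1 == pairs2


class TestBuildSignalNet:
    def test_intersection_semantics(self):
        edges = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "r": [0.9], "p": [0.001]})
        cat = InteractionCatalog(
            relations=[("A", "activation", "B"), ("B", "activation", "C")]
        )
        net = build_signal_net(edges, cat)
        assert list(net.graph.edges) == [("A", "B")]

    def test_empty_catalog_empty_network(self):
        edges = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "r": [0.9], "p": [0.001]})
        net = build_signal_net(edges, InteractionCatalog(relations=[]))
        assert net.nodes == []
        assert rank_key_genes(net).empty

    def test_degrees_on_hand_digraph(self):
        """5-node digraph: A->B, B->A, A->C, D->C, C->E; degree counts
        distinct neighbors regardless of direction."""
        net = network_from_edges([("A", "B"), ("B", "A"), ("A", "C"), ("D", "C"), ("C", "E")])
        assert net.degree("A") == 2  # B (both ways) and C
        assert net.indegree("C") == 2 and net.outdegree("C") == 1 and net.degree("C") == 3
        assert net.degree("E") == 1 and net.indegree("E") == 1 and net.outdegree("E") == 0


class TestBetweenness:
    def test_path_graph(self):
        net = network_from_edges([("A", "B"), ("B", "C")])
        bc = betweenness_centrality(net)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_four_cycle(self):
        net = network_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        bc = betweenness_centrality(net)
        for v in "ABCD":
            assert bc[v] == pytest.approx(1 / 6)

    def test_five_node_star(self):
        net = network_from_edges([("hub", leaf) for leaf in ("a", "b", "c", "d")])
        bc = betweenness_centrality(net)
        assert bc["hub"] == pytest.approx(1.0)
        assert all(bc[leaf] == 0.0 for leaf in "abcd")

    def test_fewer_than_three_nodes_all_zero(self):
        net = network_from_edges([("A", "B")])
        assert betweenness_centrality(net) == {"A": 0.0, "B": 0.0}

    @pytest.mark.parametrize("treat_as", ["undirected", "directed"])
    def test_random_graphs_match_brute_force(self, treat_as):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for u in range(n):
                for v in range(n):
                    if u != v and rng.random() < 0.3:
                        g.add_edge(u, v, relations=("activation",))
            net = GeneNetwork(graph=g)
            got = betweenness_centrality(net, treat_as=treat_as)
            ref = brute_force_betweenness(
                g if treat_as == "directed" else g.to_undirected()
            )
            for v in g.nodes:
                assert got[v] == pytest.approx(ref[v], abs=1e-9)


class TestRanking:
    def test_star_hub_first(self):
        net = network_from_edges([("hub", leaf) for leaf in ("a", "b", "c", "d")])
        assert rank_key_genes(net, top_k=1)["gene"].iloc[0] == "hub"

    def test_tie_break_by_degree_then_id(self):
        # two disconnected 3-paths: both middles have bc > 0; equal bc and
        # degree -> lexicographic order
        net = network_from_edges([("a1", "m1"), ("m1", "z1"), ("a2", "m2"), ("m2", "z2")])
        ranked = rank_key_genes(net)
        assert list(ranked["gene"][:2]) == ["m1", "m2"]
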