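import math
from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from repotax.core_model import ClassLabel
from repotax.network import (
    GraphError,
    TriadGraph,
    avg_clustering_by_type,
    build_graph,
    effective_diameter,
    local_clustering,
    small_world_score,
    summarize_network,
    transitivity,
)

from conftest import make_case

NODE_TYPES = ("drug", "target", "indication")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def typed(g: nx.Graph) -> TriadGraph:
    """Wrap an arbitrary graph, cycling node types (metrics ignore types)."""
    h = nx.Graph()
    mapping = {
        n: (NODE_TYPES[i % 3], str(n)) for i, n in enumerate(sorted(g.nodes))
    }
    h.add_nodes_from(mapping.values())
    h.add_edges_from((mapping[u], mapping[v]) for u, v in g.edges)
    return TriadGraph(graph=h)


def oracle_local_clustering(g: nx.Graph, v) -> float:
    nbrs = list(g.neighbors(v))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for u, w in combinations(nbrs, 2) if g.has_edge(u, w))
    return links / (k * (k - 1) / 2)


def oracle_transitivity(g: nx.Graph) -> float:
    triangles = sum(
        1
        for u, v, w in combinations(g.nodes, 3)
        if g.has_edge(u, v) and g.has_edge(v, w) and g.has_edge(u, w)
    )
    triples = sum(
        d * (d - 1) // 2 for _, d in g.degree
    )
    return 3.0 * triangles / triples if triples else 0.0


def oracle_bfs_distances(g: nx.Graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_effective_diameter(g: nx.Graph, q=90.0) -> float:
    comps = []
    seen = set()
    for n in g.nodes:
        if n not in seen:
            comp = set(oracle_bfs_distances(g, n))
            seen |= comp
            comps.append(comp)
    biggest = max(comps, key=len)
    sub = g.subgraph(biggest)
    dists = []
    nodes = sorted(sub.nodes, key=str)
    for i, u in enumerate(nodes):
        d = oracle_bfs_distances(sub, u)
        for v in nodes[i + 1 :]:
            dists.append(d[v])
    dists.sort()
    m = len(dists)
    r = q * (m - 1) / 100.0
    lo, hi = math.floor(r), math.ceil(r)
    return dists[lo] + (r - lo) * (dists[hi] - dists[lo])


def random_graphs(n_graphs=40, max_n=12, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.15, 0.8))
        out.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return out


# ---------------------------------------------------------------------------
# build_graph
# ---------------------------------------------------------------------------

class TestBuildGraph:
    def test_single_case_hand_enumerated(self):
        case = make_case(
            orig_mesh="C04", sec_mesh="C10",
            orig_targets=["T1"], sec_targets=["T1"],
        )
        g = build_graph([(case, ClassLabel.TARGET_CENTRIC)])
        assert g.n_nodes == 4  # drug, target, two indications
        assert g.n_edges == 5  # drug-T, T-I1, T-I2, drug-I1, drug-I2
        assert g.class_label is ClassLabel.TARGET_CENTRIC

    def test_empty_case_set_gives_empty_graph(self):
        g = build_graph([])
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_mixed_labels_rejected(self):
        a = make_case(drug="a", orig_mesh="C04", sec_mesh="C04")
        b = make_case(drug="b", orig_mesh="C04", sec_mesh="C10",
                      orig_targets=["T"], sec_targets=["T"])
        with pytest.raises(GraphError, match="mixed"):
            build_graph(
                [(a, ClassLabel.DISEASE_CENTRIC), (b, ClassLabel.TARGET_CENTRIC)]
            )

    def test_counts_match_flat_set_enumeration(self, fixture_kept, fixture_summary):
        label = ClassLabel.TARGET_CENTRIC
        cases = [
            c for c in fixture_kept if fixture_summary.per_case[c.drug_name] is label
        ]
        g = build_graph([(c, label) for c in cases])
        # independent flat scan building the same node and edge sets
        nodes, edges = set(), set()
        for c in cases:
            drug = ("drug", c.drug_name)
            i1 = ("indication", c.original.mesh_key.code)
            i2 = ("indication", c.secondary.mesh_key.code)
            nodes |= {drug, i1, i2}
            for e in ({drug, i1}, {drug, i2}):
                if len(e) == 2:
                    edges.add(frozenset(e))
            for ts, ind in ((c.original_targets, i1), (c.secondary_targets, i2)):
                for t in ts:
                    tn = ("target", t.target_id)
                    nodes.add(tn)
                    edges.add(frozenset({drug, tn}))
                    edges.add(frozenset({tn, ind}))
        assert g.n_nodes == len(nodes)
        assert g.n_edges == len(edges)

    def test_simple_graph_no_self_loops_or_duplicates(self, fixture_kept, fixture_summary):
        label = ClassLabel.DISEASE_CENTRIC
        cases = [
            c for c in fixture_kept if fixture_summary.per_case[c.drug_name] is label
        ]
        g = build_graph([(c, label) for c in cases]).graph
        assert nx.number_of_selfloops(g) == 0


# ---------------------------------------------------------------------------
# metrics vs oracles
# ---------------------------------------------------------------------------

class TestLocalClustering:
    def test_clique_center_is_one(self):
        g = typed(nx.complete_graph(3))
        for node in g.graph.nodes:
            assert local_clustering(g, node) == 1.0

    def test_star_center_is_zero(self):
        g = typed(nx.star_graph(4))
        center = next(n for n in g.graph.nodes if g.graph.degree(n) == 4)
        assert local_clustering(g, center) == 0.0

    def test_degree_below_two_is_zero(self):
        g = typed(nx.path_graph(2))
        for node in g.graph.nodes:
            assert local_clustering(g, node) == 0.0

    def test_unknown_node_rejected(self):
        g = typed(nx.path_graph(3))
        with pytest.raises(GraphError):
            local_clustering(g, ("drug", "nope"))

    def test_matches_triangle_oracle_on_random_graphs(self):
        for raw in random_graphs(seed=1):
            g = typed(raw)
            for node in g.graph.nodes:
                expected = oracle_local_clustering(g.graph, node)
                assert local_clustering(g, node) == pytest.approx(expected)


class TestAvgClusteringByType:
    def test_all_degree_one_drugs_average_zero(self):
        g = nx.Graph()
        g.add_edge(("drug", "d1"), ("indication", "C04"))
        g.add_edge(("drug", "d2"), ("indication", "C04"))
        assert avg_clustering_by_type(TriadGraph(graph=g), "drug") == 0.0

    def test_triangle_targets_average_one(self):
        g = nx.Graph()
        tri = [("target", "t"), ("drug", "d"), ("indication", "C04")]
        g.add_edges_from([(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])])
        assert avg_clustering_by_type(TriadGraph(graph=g), "target") == 1.0

    def test_absent_type_rejected(self):
        g = nx.Graph()
        g.add_node(("drug", "d"))
        with pytest.raises(GraphError):
            avg_clustering_by_type(TriadGraph(graph=g), "target")

    def test_matches_mean_of_oracled_locals(self):
        for raw in random_graphs(10, seed=2):
            g = typed(raw)
            for node_type in NODE_TYPES:
                nodes = g.nodes_of_type(node_type)
                if not nodes:
                    continue
                expected = sum(
                    oracle_local_clustering(g.graph, n) for n in nodes
                ) / len(nodes)
                assert avg_clustering_by_type(g, node_type) == pytest.approx(expected)


class TestTransitivity:
    def test_triangle_is_one(self):
        assert transitivity(typed(nx.complete_graph(3))) == 1.0

    def test_path_of_three_is_zero(self):
        assert transitivity(typed(nx.path_graph(3))) == 0.0

    def test_matches_exhaustive_triple_counting(self):
        for raw in random_graphs(seed=3):
            g = typed(raw)
            assert transitivity(g) == pytest.approx(oracle_transitivity(g.graph))


class TestEffectiveDiameter:
    def test_complete_graph_is_one(self):
        for n in (2, 5, 9):
            assert effective_diameter(typed(nx.complete_graph(n))) == 1.0

    def test_path_graph_p5_hand_interpolated(self):
        # pair distances: {1,1,1,1,2,2,2,3,3,4}; rank r = 0.9*9 = 8.1
        # -> 3 + 0.1*(4-3) = 3.1
        assert effective_diameter(typed(nx.path_graph(5))) == pytest.approx(3.1)

    def test_matches_bfs_oracle_on_random_graphs(self):
        for raw in random_graphs(seed=4):
            if max(len(c) for c in nx.connected_components(raw)) < 2:
                continue
            g = typed(raw)
            assert effective_diameter(g) == pytest.approx(
                oracle_effective_diameter(raw)
            )

    def test_too_small_component_rejected(self):
        g = nx.Graph()
        g.add_node(("drug", "d"))
        with pytest.raises(GraphError):
            effective_diameter(TriadGraph(graph=g))


class TestSmallWorldScore:
    def test_published_drug_centric_inputs(self):
        assert round(small_world_score(0.27, 51, 3.43), 2) == 4.01

    def test_zero_transitivity_gives_zero(self):
        assert small_world_score(0.0, 100, 2.5) == 0.0

    def test_direct_arithmetic(self):
        assert small_world_score(1.0, 10, 2.0) == 5.0

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(GraphError):
            small_world_score(0.5, 10, 0.0)


class TestSummarizeNetwork:
    def test_triangle_with_pendant(self):
        g = typed(nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)]))
        s = summarize_network(g)
        assert s.n_nodes == 4 and s.n_edges == 4
        assert s.pct_nodes_biggest == 100.0

    def test_two_disjoint_triangles_split_evenly(self):
        g = typed(nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]))
        s = summarize_network(g)
        assert s.pct_nodes_biggest == 50.0
        assert s.pct_edges_biggest == 50.0

    def test_fields_match_per_operation_oracles(self):
        for raw in random_graphs(15, seed=5):
            if max(len(c) for c in nx.connected_components(raw)) < 2:
                continue
            g = typed(raw)
            s = summarize_network(g)
            assert s.transitivity == pytest.approx(oracle_transitivity(raw))
            assert s.effective_diameter == pytest.approx(
                oracle_effective_diameter(raw)
            )
            assert s.small_world == pytest.approx(
                s.transitivity * s.n_nodes / s.effective_diameter
            )

    def test_consistency_invariant(self, fixture_kept, fixture_summary):
        for label in (
            ClassLabel.DISEASE_CENTRIC,
            ClassLabel.TARGET_CENTRIC,
            ClassLabel.DRUG_CENTRIC,
        ):
            cases = [
                c
                for c in fixture_kept
                if fixture_summary.per_case[c.drug_name] is label
            ]
            s = summarize_network(build_graph([(c, label) for c in cases]))
            assert s.small_world * s.effective_diameter == pytest.approx(
                s.transitivity * s.n_nodes, abs=1e-9
            )

    def test_isolated_node_changes_only_node_count(self):
        base = typed(nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)]))
        grown = TriadGraph(graph=base.graph.copy())
        grown.graph.add_node(("drug", "isolated"))
        s0, s1 = summarize_network(base), summarize_network(grown)
        assert s1.transitivity == s0.transitivity
        assert s1.effective_diameter == s0.effective_diameter
        assert s1.n_nodes == s0.n_nodes + 1
        assert s1.small_world > s0.small_world

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(6)
        for raw in random_graphs(10, seed=7):
            if max(len(c) for c in nx.connected_components(raw)) < 2:
                continue
            perm = list(raw.nodes)
            rng.shuffle(perm)
            relabeled = nx.relabel_nodes(raw, dict(zip(raw.nodes, perm)))
            s0, s1 = summarize_network(typed(raw)), summarize_network(typed(relabeled))
            assert s0.transitivity == pytest.approx(s1.transitivity)
            assert s0.effective_diameter == pytest.approx(s1.effective_diameter)
            assert s0.small_world == pytest.approx(s1.small_world)

    def test_empty_graph_rejected(self):
        with pytest.raises(GraphError):
            summarize_network(TriadGraph(graph=nx.Graph()))
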