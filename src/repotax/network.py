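"""Typed drug-target-indication graphs and their summary statistics.

For each repositioning class an undirected simple graph is built whose
nodes are drugs, target identifiers, and top-level MeSH disease codes.
Every case contributes drug-target, target-indication, and
drug-indication edges; duplicates collapse.  The summary row holds node
and edge counts, largest-component shares, per-type average clustering,
transitivity, the 90th-percentile effective diameter of the largest
component, and the small-world score

    transitivity * number of nodes / effective diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core_model import ClassLabel, RepositioningCase

__all__ = [
    "NetworkSummary",
    "TriadGraph",
    "avg_clustering_by_type",
    "build_graph",
    "effective_diameter",
    "local_clustering",
    "small_world_score",
    "summarize_network",
    "transitivity",
]

NODE_TYPES = ("drug", "target", "indication")

_EDGE_TYPE = {
    frozenset({"drug", "target"}): "drug_target",
    frozenset({"target", "indication"}): "target_indication",
    frozenset({"drug", "indication"}): "drug_indication",
}


class GraphError(ValueError):
    pass


@dataclass
class TriadGraph:
    """A simple undirected graph with typed nodes, one repositioning class.

    Nodes are ``(node_type, id)`` tuples so that identifier spaces of the
    three types cannot collide.
    """

    graph: nx.Graph
    class_label: ClassLabel | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_type(self, node_type: str) -> list[tuple[str, str]]:
        if node_type not in NODE_TYPES:
            raise GraphError(f"unknown node type {node_type!r}")
        return [n for n in self.graph.nodes if n[0] == node_type]

    def edge_records(self) -> list[tuple[str, str, str]]:
        """(source id, target id, edge_type) triples, sorted."""
        records = []
        for u, v in self.graph.edges:
            a, b = sorted((u, v))
            records.append((a[1], b[1], _EDGE_TYPE[frozenset({a[0], b[0]})]))
        return sorted(records)


def _add_edge(g: nx.Graph, u: tuple[str, str], v: tuple[str, str]) -> None:
    if u == v:
        return
    g.add_edge(u, v, edge_type=_EDGE_TYPE[frozenset({u[0], v[0]})])


def build_graph(
    labeled_cases: Iterable[tuple[RepositioningCase, ClassLabel]],
) -> TriadGraph:
    """Build the graph of one repositioning class from (case, label) pairs.

    All labels must agree; indication nodes are the top-level MeSH codes.
    """
    g = nx.Graph()
    labels: set[ClassLabel] = set()
    for case, label in labeled_cases:
        labels.add(label)
        if len(labels) > 1:
            raise GraphError(
                "mixed class labels in one graph: "
                + ", ".join(sorted(l.value for l in labels))
            )
        drug = ("drug", case.drug_name)
        orig_ind = ("indication", case.original.mesh_key.code)
        sec_ind = ("indication", case.secondary.mesh_key.code)
        g.add_node(drug)
        g.add_node(orig_ind)
        g.add_node(sec_ind)
        _add_edge(g, drug, orig_ind)
        _add_edge(g, drug, sec_ind)
        for targets, ind in (
            (case.original_targets, orig_ind),
            (case.secondary_targets, sec_ind),
        ):
            for t in targets:
                tn = ("target", t.target_id)
                g.add_node(tn)
                _add_edge(g, drug, tn)
                _add_edge(g, tn, ind)
    return TriadGraph(graph=g, class_label=next(iter(labels), None))


def local_clustering(g: TriadGraph, node: tuple[str, str]) -> float:
    """Triangle-based local clustering coefficient; degree < 2 gives 0."""
    if node not in g.graph:
        raise GraphError(f"unknown node {node!r}")
    return float(nx.clustering(g.graph, node))


def avg_clustering_by_type(g: TriadGraph, node_type: str) -> float:
    """Mean local clustering over all nodes of one type."""
    nodes = g.nodes_of_type(node_type)
    if not nodes:
        raise GraphError(f"graph has no node of type {node_type!r}")
    clust = nx.clustering(g.graph, nodes)
    return float(sum(clust.values()) / len(nodes))


def transitivity(g: TriadGraph) -> float:
    """3 x triangles / connected triples; 0 when the graph has no triples."""
    if g.n_nodes == 0:
        raise GraphError("transitivity of an empty graph is undefined")
    return float(nx.transitivity(g.graph))


def _largest_component(g: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp)


def effective_diameter(g: TriadGraph, percentile: float = 90.0) -> float:
    """Interpolated percentile of the shortest-path-length distribution.

    Distances are taken over unordered distinct node pairs of the largest
    connected component; with the ``m`` sorted distances, the ``q``-th
    percentile sits at rank ``q * (m - 1) / 100`` with linear
    interpolation (fractional results are expected).
    """
    if g.n_nodes == 0:
        raise GraphError("effective diameter of an empty graph is undefined")
    sub = _largest_component(g.graph)
    if sub.number_of_nodes() < 2:
        raise GraphError(
            "effective diameter needs at least 2 nodes in the largest component"
        )
    order = {n: i for i, n in enumerate(sub.nodes)}
    dists: list[int] = []
    for source, lengths in nx.all_pairs_shortest_path_length(sub):
        si = order[source]
        dists.extend(d for node, d in lengths.items() if order[node] > si)
    return float(np.percentile(np.asarray(dists, dtype=float), percentile))


def small_world_score(
    transitivity_value: float, n_nodes: int, eff_diameter: float
) -> float:
    """transitivity * number of nodes / effective diameter."""
    if eff_diameter <= 0:
        raise GraphError(f"effective diameter must be positive, got {eff_diameter}")
    return transitivity_value * n_nodes / eff_diameter


@dataclass
class NetworkSummary:
    """One summary row for a repositioning-class graph."""

    n_nodes: int
    n_edges: int
    pct_nodes_biggest: float
    pct_edges_biggest: float
    avg_clust_drug: float
    avg_clust_disease: float
    avg_clust_target: float
    transitivity: float
    effective_diameter: float
    small_world: float

    def to_json_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "pct_nodes_biggest": self.pct_nodes_biggest,
            "pct_edges_biggest": self.pct_edges_biggest,
            "avg_clust_drug": self.avg_clust_drug,
            "avg_clust_disease": self.avg_clust_disease,
            "avg_clust_target": self.avg_clust_target,
            "transitivity": self.transitivity,
            "effective_diameter": self.effective_diameter,
            "small_world": self.small_world,
        }


def summarize_network(g: TriadGraph) -> NetworkSummary:
    """All summary statistics of one class graph.

    The per-type clustering averages fall back to 0.0 when a node type is
    absent (a class built purely from target-free cases has no target
    nodes); all other fields are computed as documented per operation.
    """
    if g.n_nodes == 0:
        raise GraphError("cannot summarize an empty graph")
    sub = _largest_component(g.graph)
    pct_nodes = 100.0 * sub.number_of_nodes() / g.n_nodes
    pct_edges = (
        100.0 * sub.number_of_edges() / g.n_edges if g.n_edges else 0.0
    )

    def _avg(node_type: str) -> float:
        try:
            return avg_clustering_by_type(g, node_type)
        except GraphError:
            return 0.0

    trans = transitivity(g)
    diam = effective_diameter(g)
    return NetworkSummary(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        pct_nodes_biggest=pct_nodes,
        pct_edges_biggest=pct_edges,
        avg_clust_drug=_avg("drug"),
        avg_clust_disease=_avg("indication"),
        avg_clust_target=_avg("target"),
        transitivity=trans,
        effective_diameter=diam,
        small_world=small_world_score(trans, g.n_nodes, diam),
    )
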