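"""Topology metrics, betweenness, articulation points, ego subnetworks.

All metrics treat the consensus network as a simple unweighted undirected
graph: distances are counted in edges (correlation strength does not enter
path metrics). The networks of interest are typically disconnected, so path
metrics are taken over connected pairs only and the diameter is the largest
finite shortest-path distance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import networkx as nx

__all__ = [
    "TopologyReport",
    "compute_topology",
    "betweenness",
    "articulation_points",
    "extract_subnetwork",
]


@dataclass
class TopologyReport:
    """Key properties of a co-occurrence network.

    ``components_gt3`` counts connected components larger than 3 nodes and
    ``components_pairs`` those consisting of a single node pair. When the
    graph has fewer than 2 nodes, path metrics are reported as 0 with
    ``path_metrics_defined`` unset.
    """

    n_nodes: int
    n_env_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    density: float
    diameter: int
    modularity: float
    transitivity: float
    components_total: int
    components_gt3: int
    components_pairs: int
    modularity_algorithm: str = "louvain"
    modularity_seed: int = 0
    path_metrics_defined: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_table(self) -> str:
        """Two-column TSV in the style of a network-properties table."""
        rows = [
            ("Edges (co-occurrences)", self.n_edges),
            ("Nodes", self.n_nodes),
            ("Nodes of environmental parameters", self.n_env_nodes),
            ("Average degree", round(self.average_degree, 2)),
            ("Average path length", round(self.average_path_length, 2)),
            ("Connected components (larger than 3 nodes)", self.components_gt3),
            ("Density", round(self.density, 3)),
            ("Diameter", self.diameter),
            ("Modularity", round(self.modularity, 2)),
            ("Transitivity", round(self.transitivity, 2)),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def compute_topology(net: nx.Graph, modularity_seed: int = 0) -> TopologyReport:
    """Compute degree, density, path, clustering and community metrics.

    average_degree = 2E/N and density = 2E/(N(N-1)) by their closed forms;
    transitivity is the global clustering coefficient (3 x triangles over
    connected triples); average path length is the mean unweighted
    shortest-path distance over connected pairs; the diameter is the maximum
    finite shortest-path distance. Modularity scores the partition found by
    seeded Louvain community detection (community assignment is a modeling
    choice; the partition algorithm is recorded in the report).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = net.number_of_edges()

    comps = [set(c) for c in nx.connected_components(net)]
    total_dist = 0
    n_pairs = 0
    diameter = 0
    for comp in comps:
        if len(comp) < 2:
            continue
        sub = net.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total_dist += d
                    n_pairs += 1
                    diameter = max(diameter, d)
    path_defined = n_pairs > 0
    apl = total_dist / n_pairs if path_defined else 0.0

    if e > 0:
        communities = nx.community.louvain_communities(net, seed=modularity_seed)
        modularity = nx.community.modularity(net, communities)
    else:
        modularity = 0.0

    return TopologyReport(
        n_nodes=n,
        n_env_nodes=sum(1 for _, env in net.nodes(data="is_env") if env),
        n_edges=e,
        average_degree=2.0 * e / n,
        average_path_length=apl,
        density=(2.0 * e / (n * (n - 1))) if n > 1 else 0.0,
        diameter=diameter,
        modularity=float(modularity),
        transitivity=nx.transitivity(net),
        components_total=len(comps),
        components_gt3=sum(1 for c in comps if len(c) > 3),
        components_pairs=sum(1 for c in comps if len(c) == 2),
        modularity_seed=modularity_seed,
        path_metrics_defined=path_defined,
    )


def betweenness(net: nx.Graph) -> dict:
    """Raw (unnormalized) shortest-path betweenness, endpoints excluded.

    Each unordered node pair contributes the fraction of its shortest paths
    passing through a node; pairs in different components contribute nothing.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.betweenness_centrality(net, normalized=False)


def articulation_points(net: nx.Graph) -> set:
    """Nodes whose removal increases the number of connected components."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return set(nx.articulation_points(net))


def extract_subnetwork(net: nx.Graph, focal) -> nx.Graph:
    """Induced subgraph on a focal node and its direct neighbors.

    Retains focal-neighbor edges and any edges the neighbors share among
    themselves; an isolated focal node yields a single-node subgraph.
    """
    if focal not in net:
        raise ValueError(f"focal node not in network: {focal!r}")
    nodes = {focal} | set(net.neighbors(focal))
    return net.subgraph(nodes).copy()
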