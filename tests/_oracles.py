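"""Brute-force graph oracles, independent of the library's metric code.

Pure-Python path enumeration and triple counting on small graphs; used to
verify the topology, betweenness, and attack computations exhaustively.
"""

import itertools

INF = float("inf")


def adjacency(graph) -> dict:
    return {u: set(graph.neighbors(u)) for u in graph.nodes}


def floyd_warshall(graph) -> dict:
    nodes = list(graph.nodes)
    dist = {(u, v): (0 if u == v else INF) for u in nodes for v in nodes}
    for u, v in graph.edges:
        dist[(u, v)] = dist[(v, u)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def average_path_length(graph) -> float:
    dist = floyd_warshall(graph)
    finite = [d for (u, v), d in dist.items() if u != v and d < INF]
    return sum(finite) / len(finite) if finite else 0.0


def diameter(graph) -> int:
    dist = floyd_warshall(graph)
    finite = [d for (u, v), d in dist.items() if u != v and d < INF]
    return int(max(finite)) if finite else 0


def transitivity(graph) -> float:
    """3 x triangles over centered connected triples (a triangle holds 3)."""
    adj = adjacency(graph)
    triangles = 0
    open_triples = 0
    for a, b, c in itertools.combinations(graph.nodes, 3):
        links = (b in adj[a]) + (c in adj[a]) + (c in adj[b])
        if links == 3:
            triangles += 1
        elif links == 2:
            open_triples += 1
    denom = 3 * triangles + open_triples
    return (3 * triangles) / denom if denom else 0.0


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate all shortest s-t paths by DFS along decreasing distance."""
    if dist[(s, t)] == INF:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nb in adj[node]:
            if dist[(nb, t)] == dist[(node, t)] - 1:
                walk(nb, path + [nb])

    walk(s, [s])
    return paths


def betweenness(graph) -> dict:
    """Unnormalized betweenness: per unordered pair, the fraction of its
    shortest paths through each interior node."""
    adj = adjacency(graph)
    dist = floyd_warshall(graph)
    scores = {u: 0.0 for u in graph.nodes}
    for s, t in itertools.combinations(graph.nodes, 2):
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for path in paths:
            for interior in path[1:-1]:
                scores[interior] += 1.0 / len(paths)
    return scores


def components(graph) -> list[set]:
    seen, comps = set(), []
    for start in graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(graph.neighbors(u))
        seen |= comp
        comps.append(comp)
    return comps


def articulation_points(graph) -> set:
    """Remove-and-count test per node."""
    base = len(components(graph))
    arts = set()
    for node in list(graph.nodes):
        h = graph.copy()
        h.remove_node(node)
        if h.number_of_nodes() == 0:
            continue
        expected = base - (1 if graph.degree(node) == 0 else 0)
        if len(components(h)) > expected:
            arts.add(node)
    return arts
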