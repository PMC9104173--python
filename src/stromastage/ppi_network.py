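"""ELI subnetwork extraction from a protein-protein interaction graph.

The invasibility gene sets form densely connected subnetworks of the
Reactome-style PPI graph once a few linker genes are added. Extraction
is a greedy Steiner-style merge: starting from the connected components
of the seed-induced subgraph, the two closest components are repeatedly
joined by a shortest path through the full graph (length capped, default
2 edges, i.e. at most one linker per bridge), with the path's interior
nodes added as linkers. Connectivity metrics are the graph density
2E / n(n-1) and the mean local clustering coefficient (nodes of degree
< 2 contribute 0).
"""

from __future__ import annotations

import networkx as nx

from stromastage.io_formats import GeneSet


def density(graph: nx.Graph) -> float:
    """Graph density 2E / (n (n-1)); requires n >= 2."""
    if graph.number_of_nodes() < 2:
        raise ValueError("density needs >= 2 nodes")
    return nx.density(graph)


def avg_clustering(graph: nx.Graph) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    if graph.number_of_nodes() < 1:
        raise ValueError("clustering needs >= 1 node")
    return nx.average_clustering(graph)


def _shortest_connecting_path(
    graph: nx.Graph,
    comp_a: set,
    comp_b: set,
    max_len: int,
) -> tuple | None:
    """Lexicographically canonical shortest path (<= max_len edges)
    between two node sets, interior nodes outside both sets."""
    # BFS from all of comp_a, depth-limited; deterministic order
    dist = {n: 0 for n in comp_a}
    parent: dict = {}
    frontier = sorted(comp_a)
    depth = 0
    hits: list = []
    while frontier and depth < max_len and not hits:
        depth += 1
        nxt = []
        for u in frontier:
            for v in sorted(graph.neighbors(u)):
                if v in dist:
                    continue
                if v in comp_a:
                    continue
                dist[v] = depth
                parent[v] = u
                if v in comp_b:
                    hits.append(v)
                elif depth < max_len:
                    nxt.append(v)
        frontier = sorted(nxt)
    if not hits:
        return None

    def backtrack(end) -> tuple:
        path = [end]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        return tuple(reversed(path))

    return min(backtrack(h) for h in sorted(hits))


def extract_subnetwork(
    graph: nx.Graph,
    seeds: GeneSet,
    max_linker_path: int = 2,
) -> nx.Graph:
    """Extract the seed subnetwork, adding linker genes where needed.

    Returns the subgraph induced on seeds plus linkers, with a ``role``
    node attribute ('seed' or 'linker'). Components that cannot be
    joined within ``max_linker_path`` edges remain as separate
    components of the result (disconnected seeds are retained, not
    dropped). Ties between equally close component pairs break on the
    lexicographically smallest connecting path.
    """
    present = [g for g in seeds.members if g in graph]
    if not present:
        raise ValueError(f"no seed of {seeds.name!r} is in the graph")
    components = [set(c) for c in
                  nx.connected_components(graph.subgraph(present))]
    components.sort(key=lambda c: sorted(c)[0])
    linkers: set = set()
    while len(components) > 1:
        best = None
        best_pair = None
        for i in range(len(components)):
            for j in range(i + 1, len(components)):
                path = _shortest_connecting_path(
                    graph, components[i], components[j], max_linker_path
                )
                if path is None:
                    continue
                key = (len(path), path)
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        if best is None:
            break
        i, j = best_pair
        path = best[1]
        interior = set(path[1:-1])
        linkers |= interior - set(present)
        merged = components[i] | components[j] | interior
        components = [c for k, c in enumerate(components)
                      if k not in (i, j)]
        components.append(merged)
        # a path may run through a third seed component; coalesce overlaps
        coalesced: list[set] = []
        for c in components:
            hit = next((k for k, d in enumerate(coalesced) if d & c), None)
            if hit is None:
                coalesced.append(set(c))
            else:
                coalesced[hit] |= c
        components = coalesced
        components.sort(key=lambda c: sorted(c)[0])
    nodes = set(present) | linkers
    sub = graph.subgraph(nodes).copy()
    for n in sub.nodes:
        sub.nodes[n]["role"] = "linker" if n in linkers else "seed"
    return sub


def subnetwork_metrics(graph: nx.Graph, sub: nx.Graph) -> dict:
    """Density/clustering of the extracted subnetwork vs the full graph."""
    linkers = [n for n, d in sub.nodes(data=True)
               if d.get("role") == "linker"]
    return {
        "n_seeds": sum(1 for _, d in sub.nodes(data=True)
                       if d.get("role") == "seed"),
        "n_linkers": len(linkers),
        "n_components": nx.number_connected_components(sub)
        if sub.number_of_nodes() else 0,
        "subnetwork_density": density(sub),
        "subnetwork_clustering": avg_clustering(sub),
        "graph_density": density(graph),
        "graph_clustering": avg_clustering(graph),
    }
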