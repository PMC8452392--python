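import itertools

import networkx as nx
import numpy as np
import pytest

from netpharm.datasets import load_ldp_compounds, load_ldp_docking
from netpharm.ppi_screen import PPIGraph, graph_from_edges


@pytest.fixture(scope="session")
def ldp_compounds():
    return load_ldp_compounds()


@pytest.fixture(scope="session")
def ldp_docking():
    return load_ldp_docking()


def er_graph(rng: np.random.Generator, n: int, p: float, prefix: str = "N") -> PPIGraph:
    """Erdos-Renyi graph over labelled nodes, isolates retained."""
    nodes = [f"{prefix}{i:02d}" for i in range(n)]
    edges = [(a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < p]
    return graph_from_edges(edges, extra_nodes=nodes)


def to_networkx(g: PPIGraph) -> "nx.Graph":
    G = nx.Graph()
    G.add_nodes_from(g.nodes)
    G.add_edges_from(g.edges)
    return G


def betweenness_by_path_enumeration(G: "nx.Graph") -> dict:
    """Independent oracle: enumerate all shortest paths per unordered pair."""
    bc = {v: 0.0 for v in G}
    for s, t in itertools.combinations(sorted(G.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in G:
            if v in (s, t):
                continue
            hits = sum(v in path for path in paths)
            if hits:
                bc[v] += hits / len(paths)
    return bc


def closeness_by_bfs(G: "nx.Graph") -> dict:
    out = {}
    for v in G:
        dist = nx.single_source_shortest_path_length(G, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out
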