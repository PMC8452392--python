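"""Scored PPI graphs, centrality computation, and iterative median-threshold screening.

The screening procedure mirrors the common CytoNCA workflow: on the current
network compute betweenness, closeness and degree centrality for every node,
take the per-measure sample median as an inclusive threshold triple, keep the
nodes at or above all three, induce the subgraph on the survivors, and repeat
until a fixed point, an empty graph, a round budget, or a target size.

Centralities are computed by in-repo algorithms on unweighted graphs:

* degree — incident edge count;
* closeness — for node v in its connected component C (|C| > 1),
  ``(|C| - 1) / sum of BFS distances from v within C``; isolated nodes get 0;
* betweenness — Brandes' accumulation, unnormalized, with each unordered
  source/target pair counted once (the undirected convention behind
  CytoNCA/Cytoscape's printed values, which exceed 1 on real networks).

Node iteration is over lexicographically sorted nodes wherever order could
affect floating-point accumulation, so outputs are bit-stable.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, NamedTuple, Sequence

from .core_model import normalize_symbol
from .errors import FormatError, ValidationError


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIGraph:
    """Simple undirected graph over gene symbols with optional edge scores.

    Edges are stored once as sorted pairs; scores (when present) are STRING-style
    combined scores on the 0-1000 integer scale.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    scores: Mapping[tuple[str, str], int] | None = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a > b:
                raise ValidationError(f"edge ({a!r}, {b!r}) not stored in sorted order")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge ({a!r}, {b!r}) references a missing node")

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, list[str]]:
        """Sorted adjacency lists (deterministic traversal order)."""
        adj: dict[str, list[str]] = {v: [] for v in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        for v in adj:
            adj[v].sort()
        return adj

    def induced_subgraph(self, keep: Iterable[str]) -> "PPIGraph":
        keep_set = frozenset(keep)
        if not keep_set <= self.nodes:
            raise ValidationError("induced_subgraph: nodes outside the graph")
        edges = frozenset(e for e in self.edges if e[0] in keep_set and e[1] in keep_set)
        scores = {e: s for e, s in self.scores.items() if e in edges} if self.scores else None
        return PPIGraph(keep_set, edges, scores)


def graph_from_edges(pairs: Iterable[tuple[str, str]],
                     extra_nodes: Iterable[str] = ()) -> PPIGraph:
    """Build an unscored graph from node pairs (order-insensitive, deduplicated)."""
    edges = {_edge_key(a, b) for a, b in pairs if a != b}
    nodes = {v for e in edges for v in e} | set(extra_nodes)
    return PPIGraph(frozenset(nodes), frozenset(edges))


def read_string_edges(path: str | Path, score_min: int = 700,
                      delimiter: str | None = None) -> PPIGraph:
    """Read a STRING-style edge table, keeping edges with combined score >= score_min.

    The file needs two node columns and a ``combined_score`` column on the
    0-1000 integer scale. Duplicate and reversed pairs collapse to one edge
    keeping the maximum score; self-loops are dropped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file, expected a header row")
        delim = delimiter or ("\t" if "\t" in first else "," if "," in first else " ")
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim, skipinitialspace=True)
        header = [c.strip().lower() for c in next(reader)]
        try:
            score_col = header.index("combined_score")
        except ValueError:
            raise FormatError("combined_score column not found", column="combined_score") from None
        node_cols = [i for i in range(len(header)) if i != score_col][:2]
        if len(node_cols) < 2:
            raise FormatError("expected two node columns besides combined_score")

        best: dict[tuple[str, str], int] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            try:
                a = normalize_symbol(row[node_cols[0]])
                b = normalize_symbol(row[node_cols[1]])
            except (IndexError, ValidationError) as exc:
                raise FormatError(f"malformed row: {exc}", line=lineno) from None
            raw_score = row[score_col].strip()
            try:
                score = int(raw_score)
            except ValueError:
                raise FormatError(f"non-integer combined score {raw_score!r}", line=lineno) from None
            if not (0 <= score <= 1000):
                raise FormatError(f"combined score {score} outside [0, 1000]", line=lineno)
            if a == b:
                continue
            key = _edge_key(a, b)
            if score > best.get(key, -1):
                best[key] = score

    kept = {e: s for e, s in best.items() if s >= score_min}
    nodes = frozenset(v for e in kept for v in e)
    return PPIGraph(nodes, frozenset(kept), kept)


def remove_isolates(g: PPIGraph) -> PPIGraph:
    """Drop degree-0 nodes only ("hide discrete targets")."""
    connected = frozenset(v for e in g.edges for v in e)
    return g.induced_subgraph(connected)


# --------------------------------------------------------------------------
# Centralities (unweighted, in-repo implementations)
# --------------------------------------------------------------------------

def degree_centrality(g: PPIGraph) -> dict[str, int]:
    degrees = {v: 0 for v in g.nodes}
    for a, b in g.edges:
        degrees[a] += 1
        degrees[b] += 1
    return degrees


def _bfs_distances(adj: Mapping[str, Sequence[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness_centrality(g: PPIGraph) -> dict[str, float]:
    """Within-component closeness: (|C|-1) / sum of distances; isolates get 0."""
    adj = g.adjacency()
    out: dict[str, float] = {}
    for v in sorted(g.nodes):
        dist = _bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def betweenness_centrality(g: PPIGraph) -> dict[str, float]:
    """Brandes' betweenness on unweighted graphs, unnormalized.

    Each unordered source/target pair contributes once (the directed-pair
    accumulation is halved at the end).
    """
    adj = g.adjacency()
    bc = {v: 0.0 for v in g.nodes}
    for s in sorted(g.nodes):
        # single-source shortest-path counts
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in adj}
        sigma = {v: 0.0 for v in adj}
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in adj}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: bc[v] / 2.0 for v in bc}


class Centrality(NamedTuple):
    betweenness: float
    closeness: float
    degree: int


def centrality_table(g: PPIGraph) -> dict[str, Centrality]:
    """Per-node (betweenness, closeness, degree) triples."""
    b = betweenness_centrality(g)
    c = closeness_centrality(g)
    d = degree_centrality(g)
    return {v: Centrality(b[v], c[v], d[v]) for v in sorted(g.nodes)}


def write_centrality_table(table: Mapping[str, Centrality], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node", "betweenness", "closeness", "degree"])
        for node in sorted(table):
            row = table[node]
            writer.writerow([node, repr(row.betweenness), repr(row.closeness), row.degree])


def write_edge_tsv(g: PPIGraph, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node1", "node2", "combined_score"])
        for a, b in sorted(g.edges):
            score = g.scores.get((a, b), "") if g.scores else ""
            writer.writerow([a, b, score])


# --------------------------------------------------------------------------
# Median-threshold screening
# --------------------------------------------------------------------------

class Thresholds(NamedTuple):
    b_min: float
    c_min: float
    d_min: float


def median_thresholds(table: Mapping[str, Centrality]) -> Thresholds:
    """Per-measure sample medians (even counts: mean of the two middle values)."""
    if not table:
        raise ValidationError("centrality table is empty")
    rows = list(table.values())
    return Thresholds(
        b_min=median(r.betweenness for r in rows),
        c_min=median(r.closeness for r in rows),
        d_min=median(r.degree for r in rows),
    )


@dataclass(frozen=True)
class ScreeningRound:
    """One screening pass: thresholds applied, survivors and their induced graph."""

    thresholds: Thresholds
    centralities: Mapping[str, Centrality]  # computed on the pre-screen graph
    graph: PPIGraph  # induced subgraph on the survivors
    removed: frozenset[str]

    @property
    def surviving_nodes(self) -> frozenset[str]:
        return self.graph.nodes

    @property
    def surviving_edges(self) -> frozenset[tuple[str, str]]:
        return self.graph.edges

    @property
    def node_count(self) -> int:
        return self.graph.node_count

    @property
    def edge_count(self) -> int:
        return self.graph.edge_count


def screen_round(g: PPIGraph, thresholds: Thresholds,
                 table: Mapping[str, Centrality] | None = None) -> ScreeningRound:
    """Keep nodes meeting all three inclusive thresholds; induce their subgraph.

    Isolated survivors are retained (isolate removal is a separate,
    pre-screening step).
    """
    if table is None:
        table = centrality_table(g)
    survivors = [v for v, row in table.items()
                 if row.betweenness >= thresholds.b_min
                 and row.closeness >= thresholds.c_min
                 and row.degree >= thresholds.d_min]
    sub = g.induced_subgraph(survivors)
    return ScreeningRound(thresholds, dict(table), sub, g.nodes - sub.nodes)


def iterative_screen(g: PPIGraph, max_rounds: int | None = None,
                     target_size: int | None = None,
                     min_size: int | None = None,
                     overrides: Sequence[Thresholds | None] | None = None
                     ) -> list[ScreeningRound]:
    """Repeat median-threshold screening until a stopping condition.

    Each round recomputes centralities on the previous round's induced
    subgraph and derives fresh median thresholds, unless an override triple
    is supplied for that round (``overrides[i]`` applies to round i; None
    entries fall back to medians). Stops at a fixed point (no node removed),
    an empty graph, ``max_rounds`` rounds, or node count <= ``target_size``.

    ``min_size`` makes the stopping rule a floor instead: a round that would
    leave fewer than ``min_size`` survivors is discarded and iteration stops
    with the previous network. Median cuts typically remove well over half
    of the nodes per round, so a strict ``target_size`` stop can land far
    below the size actually wanted; the floor mirrors the workflow of
    screening down TO a key-target set of about the wanted size, never past
    it.
    """
    if not g.nodes:
        raise ValidationError("cannot screen an empty graph")
    if max_rounds is None and target_size is None:
        max_rounds = 100  # fixed-point detection terminates long before this
    history: list[ScreeningRound] = []
    current = g
    round_idx = 0
    while current.nodes:
        if max_rounds is not None and round_idx >= max_rounds:
            break
        if target_size is not None and current.node_count <= target_size:
            break
        table = centrality_table(current)
        override = overrides[round_idx] if overrides and round_idx < len(overrides) else None
        thresholds = Thresholds(*override) if override is not None else median_thresholds(table)
        rnd = screen_round(current, thresholds, table)
        if min_size is not None and rnd.node_count < min_size:
            break  # discard the overshooting round
        history.append(rnd)
        round_idx += 1
        if not rnd.removed:  # fixed point
            break
        current = rnd.graph
    return history
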