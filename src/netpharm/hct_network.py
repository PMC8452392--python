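"""Herb-compound-target bipartite network and compound degree ranking.

The network links each active compound to the common targets it hits.
Herb membership is carried as a node attribute on compound nodes (not as a
third partition). Compound degree — the number of common targets a compound
reaches — is the ranking statistic used to nominate crucial compounds.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .core_model import CompoundTargetMap
from .errors import ValidationError
from .target_sets import CommonTargetSet


@dataclass(frozen=True)
class BipartiteNetwork:
    """Compound/target two-partition simple graph.

    ``compound_herbs`` annotates each compound node with its herb set
    (possibly empty when no compound table was supplied).
    """

    compound_nodes: frozenset[str]
    target_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (mol_id, gene)
    compound_herbs: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, t in self.edges:
            if c not in self.compound_nodes or t not in self.target_nodes:
                raise ValidationError(f"edge ({c}, {t}) has an endpoint outside its partition")

    @property
    def node_count(self) -> int:
        return len(self.compound_nodes) + len(self.target_nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def compound_degrees(self) -> dict[str, int]:
        degrees = {c: 0 for c in self.compound_nodes}
        for c, _ in self.edges:
            degrees[c] += 1
        return degrees

    def target_degrees(self) -> dict[str, int]:
        degrees = {t: 0 for t in self.target_nodes}
        for _, t in self.edges:
            degrees[t] += 1
        return degrees


def build_hct(ctmap: CompoundTargetMap, common: CommonTargetSet | frozenset[str] | set[str],
              keep_isolated_compounds: bool = True,
              compound_herbs: Mapping[str, frozenset[str]] | None = None) -> BipartiteNetwork:
    """Build the bipartite network restricted to the common target set.

    Edges are ``(mol_id, gene)`` pairs with gene in both the compound's
    target set and the common set. Target nodes are targets with at least
    one edge; compound nodes are all mapped compounds by default, or only
    those with an edge when ``keep_isolated_compounds`` is False.
    """
    common_symbols = common.symbols if isinstance(common, CommonTargetSet) else frozenset(common)
    edges: set[tuple[str, str]] = set()
    for mol_id, targets in ctmap.entries.items():
        for gene in targets & common_symbols:
            edges.add((mol_id, gene))
    if keep_isolated_compounds:
        compounds = frozenset(ctmap.entries)
    else:
        compounds = frozenset(c for c, _ in edges)
    targets_with_edges = frozenset(t for _, t in edges)
    herbs = {c: frozenset(compound_herbs.get(c, frozenset())) for c in compounds} \
        if compound_herbs else {c: frozenset() for c in compounds}
    return BipartiteNetwork(compounds, targets_with_edges, frozenset(edges), herbs)


def compound_degree_ranking(net: BipartiteNetwork, k: int) -> list[tuple[str, int]]:
    """Top-k compounds by degree, ties broken by mol_id lexicographic order."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    ranked = sorted(net.compound_degrees().items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def export_network(net: BipartiteNetwork, path: str | Path, format: str) -> None:
    """Write the network as SIF, GraphML or two-column edge TSV."""
    path = Path(path)
    edges = sorted(net.edges)
    if format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for c, t in edges:
                fh.write(f"{c} ct {t}\n")
    elif format == "edge-tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["compound", "target"])
            writer.writerows(edges)
    elif format == "graphml":
        _write_graphml(net, path)
    else:
        raise ValidationError(f"unknown export format {format!r}; "
                              "expected one of: sif, graphml, edge-tsv")


def read_edge_tsv(path: str | Path) -> frozenset[tuple[str, str]]:
    """Re-import an edge TSV written by :func:`export_network`."""
    edges: set[tuple[str, str]] = set()
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if i == 0 and row[:2] == ["compound", "target"]:
                continue
            if len(row) >= 2:
                edges.add((row[0], row[1]))
    return frozenset(edges)


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _write_graphml(net: BipartiteNetwork, path: Path) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    for key_id, attr in (("d0", "partition"), ("d1", "herbs")):
        key = ET.SubElement(root, f"{{{_GRAPHML_NS}}}key")
        key.set("id", key_id)
        key.set("for", "node")
        key.set("attr.name", attr)
        key.set("attr.type", "string")
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    graph.set("id", "hct")
    graph.set("edgedefault", "undirected")
    for c in sorted(net.compound_nodes):
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=c)
        ET.SubElement(node, f"{{{_GRAPHML_NS}}}data", key="d0").text = "compound"
        herbs = ", ".join(sorted(net.compound_herbs.get(c, frozenset())))
        ET.SubElement(node, f"{{{_GRAPHML_NS}}}data", key="d1").text = herbs
    for t in sorted(net.target_nodes):
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=t)
        ET.SubElement(node, f"{{{_GRAPHML_NS}}}data", key="d0").text = "target"
    for i, (c, t) in enumerate(sorted(net.edges)):
        edge = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge")
        edge.set("id", f"e{i}")
        edge.set("source", c)
        edge.set("target", t)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)
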