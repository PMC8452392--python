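import itertools
import random

import networkx as nx
import numpy as np
import pytest

from conftest import (betweenness_by_path_enumeration, closeness_by_bfs, er_graph,
                      to_networkx)
from netpharm.errors import FormatError, ValidationError
from netpharm.ppi_screen import (Centrality, Thresholds, betweenness_centrality,
                                 centrality_table, closeness_centrality,
                                 degree_centrality, graph_from_edges, iterative_screen,
                                 median_thresholds, read_string_edges, remove_isolates,
                                 screen_round)


class TestStringReader:
    def _write(self, tmp_path, rows):
        p = tmp_path / "edges.tsv"
        p.write_text("node1\tnode2\tcombined_score\n" +
                     "".join(f"{a}\t{b}\t{s}\n" for a, b, s in rows))
        return p

    def test_dedupe_reverse_and_self_loops(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 900), ("B", "A", 950), ("C", "C", 950)])
        g = read_string_edges(p)
        assert g.edges == {("A", "B")}
        assert g.scores[("A", "B")] == 950  # max of the duplicate pair

    def test_score_boundary_inclusive(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 699), ("C", "D", 700)])
        g = read_string_edges(p, score_min=700)
        assert g.edges == {("C", "D")}

    def test_missing_score_column(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("node1\tnode2\tscore\nA\tB\t900\n")
        with pytest.raises(FormatError, match="combined_score"):
            read_string_edges(p)

    def test_non_integer_score_reports_line(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", "0.9")])
        with pytest.raises(FormatError, match="line 2"):
            read_string_edges(p)

    def test_matches_brute_force_filter(self, tmp_path):
        rng = random.Random(17)
        rows = [(f"G{rng.randrange(40)}", f"G{rng.randrange(40)}", rng.randrange(0, 1001))
                for _ in range(1000)]
        g = read_string_edges(self._write(tmp_path, rows), score_min=700)
        best: dict[tuple, int] = {}
        for a, b, s in rows:
            if a == b:
                continue
            key = tuple(sorted((a, b)))
            best[key] = max(best.get(key, -1), s)
        assert g.edges == {e for e, s in best.items() if s >= 700}


def test_remove_isolates():
    g = graph_from_edges([("A", "B")], extra_nodes=["C"])
    assert remove_isolates(g).nodes == {"A", "B"}
    g2 = graph_from_edges([("A", "B"), ("B", "C")])
    assert remove_isolates(g2).nodes == g2.nodes
    rng = np.random.default_rng(1)
    g3 = er_graph(rng, 20, 0.08)
    deg = degree_centrality(g3)
    assert remove_isolates(g3).nodes == {v for v, d in deg.items() if d > 0}


class TestCentralityClosedForms:
    def test_triangle_degrees(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        assert degree_centrality(g) == {"A": 2, "B": 2, "C": 2}

    def test_star_degree_and_betweenness(self):
        leaves = [f"L{i}" for i in range(5)]
        g = graph_from_edges([("HUB", leaf) for leaf in leaves])
        deg = degree_centrality(g)
        assert deg["HUB"] == 5 and all(deg[l] == 1 for l in leaves)
        bc = betweenness_centrality(g)
        assert bc["HUB"] == pytest.approx(5 * 4 / 2)  # n(n-1)/2 for n leaves
        assert all(bc[l] == 0.0 for l in leaves)

    def test_path_closeness_and_betweenness(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        c = closeness_centrality(g)
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx(2 / 3)
        bc = betweenness_centrality(g)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_complete_graph_closeness(self):
        g = graph_from_edges(itertools.combinations("ABCD", 2))
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(g).values())

    def test_isolated_node_gets_zero_closeness(self):
        g = graph_from_edges([("A", "B")], extra_nodes=["Z"])
        assert closeness_centrality(g)["Z"] == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_centralities_match_oracles_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    g = er_graph(rng, 8, 0.3)
    G = to_networkx(g)
    assert degree_centrality(g) == dict(G.degree())
    for v, c in closeness_centrality(g).items():
        assert c == pytest.approx(closeness_by_bfs(G)[v], abs=1e-12)
    oracle = betweenness_by_path_enumeration(G)
    for v, b in betweenness_centrality(g).items():
        assert b == pytest.approx(oracle[v], abs=1e-9)


def test_isomorphism_invariance():
    rng = np.random.default_rng(23)
    g = er_graph(rng, 10, 0.3)
    mapping = {v: f"X{v}" for v in g.nodes}
    relabeled = graph_from_edges([(mapping[a], mapping[b]) for a, b in g.edges],
                                 extra_nodes=[mapping[v] for v in g.nodes])
    orig = centrality_table(g)
    perm = centrality_table(relabeled)
    for v, row in orig.items():
        assert perm[mapping[v]].betweenness == pytest.approx(row.betweenness, abs=1e-12)
        assert perm[mapping[v]].closeness == pytest.approx(row.closeness, abs=1e-12)
        assert perm[mapping[v]].degree == row.degree


class TestMedianAndScreening:
    def test_median_rules(self):
        def table(degrees):
            return {f"N{i}": Centrality(0.0, 0.0, d) for i, d in enumerate(degrees)}

        assert median_thresholds(table([1, 2, 3])).d_min == 2
        assert median_thresholds(table([1, 2, 3, 4])).d_min == 2.5
        with pytest.raises(ValidationError):
            median_thresholds({})

    def test_zero_thresholds_keep_everything(self):
        rng = np.random.default_rng(2)
        g = remove_isolates(er_graph(rng, 12, 0.3))
        rnd = screen_round(g, Thresholds(0, 0, 0))
        assert rnd.surviving_nodes == g.nodes
        assert rnd.surviving_edges == g.edges

    def test_thresholds_above_maxima_empty_round(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        rnd = screen_round(g, Thresholds(1e9, 1e9, 1e9))
        assert rnd.node_count == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_survivors_satisfy_and_removed_violate(self, seed):
        rng = np.random.default_rng(seed)
        g = remove_isolates(er_graph(rng, 25, 0.15))
        table = centrality_table(g)
        th = median_thresholds(table)
        rnd = screen_round(g, th, table)
        for v in rnd.surviving_nodes:
            row = table[v]
            assert (row.betweenness >= th.b_min and row.closeness >= th.c_min
                    and row.degree >= th.d_min)
        for v in rnd.removed:
            row = table[v]
            assert (row.betweenness < th.b_min or row.closeness < th.c_min
                    or row.degree < th.d_min)
        # induced edges only among survivors
        assert all(a in rnd.surviving_nodes and b in rnd.surviving_nodes
                   for a, b in rnd.surviving_edges)

    def test_k5_reaches_fixed_point_in_one_round(self):
        g = graph_from_edges(itertools.combinations("ABCDE", 2))
        history = iterative_screen(g)
        assert len(history) == 1
        assert history[0].surviving_nodes == g.nodes
        assert history[0].removed == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_round_history_is_decreasing_chain(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = remove_isolates(er_graph(rng, 30, 0.12))
        history = iterative_screen(g)
        nodes = [g.nodes] + [r.surviving_nodes for r in history]
        edges = [g.edge_count] + [r.edge_count for r in history]
        for prev, cur in zip(nodes, nodes[1:]):
            assert cur <= prev
        for prev, cur in zip(edges, edges[1:]):
            assert cur <= prev

    def test_min_size_floor_never_undershoots(self):
        rng = np.random.default_rng(42)
        g = remove_isolates(er_graph(rng, 40, 0.15))
        history = iterative_screen(g, min_size=8)
        assert all(r.node_count >= 8 for r in history)

    def test_overrides_replace_medians_per_round(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("B", "D")])
        history = iterative_screen(g, max_rounds=1, overrides=[Thresholds(0, 0, 2)])
        assert history[0].thresholds == Thresholds(0, 0, 2)
        assert history[0].surviving_nodes == {"B", "C", "D"}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            iterative_screen(graph_from_edges([]))


def test_handshake_lemma_on_random_graphs():
    rng = np.random.default_rng(3)
    for _ in range(5):
        g = er_graph(rng, 15, 0.2)
        assert sum(degree_centrality(g).values()) == 2 * g.edge_count
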