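import math
import random

import pytest
from scipy import stats

from netpharm.enrichment import (AnnotationCollection, AnnotationTerm, EnrichmentRow,
                                 fold_enrichment, hypergeometric_upper_tail, read_gmt,
                                 run_enrichment, top_terms)
from netpharm.errors import FormatError, ValidationError


def tail_oracle(k, K, n, N):
    """Exhaustive binomial-coefficient summation with exact integers."""
    total = sum(math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1))
    return total / math.comb(N, n)


class TestHypergeometricTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_upper_tail(0, 5, 5, 20) == 1.0

    def test_full_overlap_closed_form(self):
        # C(5,5) C(15,0) / C(20,5) = 1/15504
        assert hypergeometric_upper_tail(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-12)

    def test_partial_overlap_matches_term_sum(self):
        expected = sum(math.comb(5, i) * math.comb(15, 5 - i) for i in range(3, 6))
        expected /= math.comb(20, 5)
        assert hypergeometric_upper_tail(3, 5, 5, 20) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_survival_function(self):
        for (k, K, n, N) in [(3, 40, 25, 500), (10, 120, 60, 2000), (1, 5, 3, 10),
                             (17, 300, 100, 20000)]:
            assert hypergeometric_upper_tail(k, K, n, N) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9)

    def test_monotone_non_increasing_in_k(self):
        values = [hypergeometric_upper_tail(k, 30, 20, 100) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(6, 5, 5, 20)
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(1, 25, 5, 20)

    def test_large_background_no_underflow(self):
        p = hypergeometric_upper_tail(50, 200, 100, 20000)
        assert 0.0 < p < 1e-50  # far under double underflow if summed naively


class TestFoldEnrichment:
    def test_forced_arithmetic(self):
        assert fold_enrichment(3, 5, 5, 20) == pytest.approx(2.4)

    def test_zero_overlap(self):
        assert fold_enrichment(0, 5, 5, 20) == 0.0

    def test_random_tuples_match_formula(self):
        rng = random.Random(8)
        for _ in range(50):
            N = rng.randrange(10, 200)
            K = rng.randrange(1, N + 1)
            n = rng.randrange(1, N + 1)
            k = rng.randrange(0, min(K, n) + 1)
            assert fold_enrichment(k, K, n, N) == pytest.approx((k / n) / (K / N))

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            fold_enrichment(0, 0, 5, 20)


class TestGmtReader:
    def test_parse(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("T1\tfirst term\tjun\tTNF\nT2\tsecond\takt1\n")
        coll = read_gmt(p, "BP")
        assert len(coll) == 2
        assert coll.terms[0].genes == {"JUN", "TNF"}
        assert coll.terms[1].category == "BP"

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("T1\tdesc-only\n")
        with pytest.raises(FormatError, match="line 1"):
            read_gmt(p)

    def test_duplicate_term_ids_rejected(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("T1\ta\tJUN\nT1\tb\tTNF\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_gmt(p)


def _collection(term_genes, category="BP"):
    return AnnotationCollection(tuple(
        AnnotationTerm(tid, tid, category, frozenset(genes))
        for tid, genes in term_genes.items()))


class TestRunEnrichment:
    def test_query_disjoint_from_terms_gives_empty_result(self):
        coll = _collection({"T1": {"A", "B", "C"}})
        bg = {"A", "B", "C", "X", "Y", "Z"}
        assert run_enrichment({"X", "Y"}, coll, bg) == []

    def test_planted_design_passes_all_gates(self):
        bg = [f"G{i:04d}" for i in range(1000)]
        term = set(bg[:20])
        query = set(bg[:15]) | set(bg[500:535])  # 50 genes, 15 in the term
        coll = _collection({"T": term, "PAD": set(bg[900:950])})
        rows = run_enrichment(query, coll, set(bg))
        (row,) = [r for r in rows if r.term_id == "T"]
        assert (row.k, row.K, row.n, row.N) == (15, 20, 50, 1000)
        assert row.fold == pytest.approx((15 / 50) / (20 / 1000))  # = 15.0
        assert row.p_raw == pytest.approx(tail_oracle(15, 20, 50, 1000), rel=1e-9)
        assert row.p_raw < 1e-12

    def test_min_overlap_gate_blocks_small_hits(self):
        # overlap of exactly 2 is filtered no matter how extreme the p-value
        bg = [f"G{i:03d}" for i in range(500)]
        coll = _collection({"T": set(bg[:2])})
        query = set(bg[:2])
        assert run_enrichment(query, coll, set(bg)) == []

    def test_p_gate_is_strict_and_fold_gate_inclusive(self):
        bg = [f"G{i}" for i in range(40)]
        coll = _collection({"T": set(bg[:10])})
        query = set(bg[:5]) | set(bg[20:25])  # k=5, K=10, n=10, N=40 -> fold 2.0
        rows = run_enrichment(query, coll, set(bg), min_fold=2.0, p_max=1.0)
        assert rows and rows[0].fold == pytest.approx(2.0)
        p = rows[0].p_raw
        assert run_enrichment(query, coll, set(bg), min_fold=2.0, p_max=p) == []

    def test_bh_q_values_monotone_and_above_p(self):
        rng = random.Random(5)
        bg = [f"G{i:03d}" for i in range(300)]
        terms = {f"T{i}": set(rng.sample(bg, rng.randrange(5, 60))) for i in range(25)}
        coll = _collection(terms)
        query = set(rng.sample(bg, 40))
        rows = run_enrichment(query, coll, set(bg), min_overlap=0, min_fold=0.0, p_max=1.1)
        assert len(rows) == 25
        for row in rows:
            assert row.q_bh >= row.p_raw - 1e-15
        qs = [r.q_bh for r in rows]  # rows sorted by p => BH q non-decreasing
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))
        # independent BH oracle: q_i = min_{j>=i} p_j * m / (j+1)
        ps = [r.p_raw for r in rows]
        m = len(ps)
        oracle = [min(min(ps[j] * m / (j + 1) for j in range(i, m)), 1.0)
                  for i in range(m)]
        for row, q in zip(rows, oracle):
            assert row.q_bh == pytest.approx(q, rel=1e-9)

    def test_background_restriction_idempotent(self):
        rng = random.Random(6)
        bg = set(f"G{i:03d}" for i in range(200))
        terms = {f"T{i}": set(rng.sample(sorted(bg), 30)) | {f"OUT{i}"} for i in range(10)}
        coll = _collection(terms)
        query = set(rng.sample(sorted(bg), 30)) | {"OUTQ"}
        gates = dict(min_overlap=0, min_fold=0.0, p_max=1.1)  # compare all rows
        direct = run_enrichment(query, coll, bg, **gates)
        restricted_coll = _collection({t: g & bg for t, g in terms.items()})
        restricted = run_enrichment(query & bg, restricted_coll, bg, **gates)
        assert direct  # non-vacuous
        assert [(r.term_id, r.k, r.K, r.p_raw) for r in direct] == \
               [(r.term_id, r.k, r.K, r.p_raw) for r in restricted]

    def test_empty_query_after_restriction_rejected(self):
        coll = _collection({"T": {"A"}})
        with pytest.raises(ValidationError):
            run_enrichment({"Z"}, coll)  # annotated-union background is {A}


def test_top_terms_slices_per_category():
    def row(i, cat, p):
        return EnrichmentRow(f"{cat}{i}", "", cat, 3, 10, 20, 100, p, 2.0, p)

    rows = sorted([row(i, "BP", 0.001 * (i + 1)) for i in range(3)] +
                  [row(i, "KEGG", 0.0005 * (i + 1)) for i in range(15)],
                  key=lambda r: (r.p_raw, r.term_id))
    top = top_terms(rows, per_category=10)
    assert len(top["BP"]) == 3
    assert len(top["KEGG"]) == 10
    assert [r.term_id for r in top["KEGG"]] == [f"KEGG{i}" for i in range(10)]
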