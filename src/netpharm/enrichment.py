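"""Over-representation analysis with hypergeometric upper-tail p-values.

Given a query gene set (e.g. the common targets of a formula and a disease)
and annotation collections (GO BP/CC/MF, KEGG pathways in GMT format), each
term is tested for over-representation: with background size N, term size K,
query size n and overlap k, the p-value is P[X >= k] for X hypergeometric.
Terms pass when overlap >= min_overlap, fold enrichment >= min_fold and raw
p < p_max — the Metascape-style gate triple (3 / 1.5 / 0.01 by default).

The tail sum is evaluated in log space (log-gamma binomial coefficients,
max-shifted compensated summation), so backgrounds of tens of thousands of
genes do not underflow. Benjamini-Hochberg q-values are computed per
category over ALL tested terms, not only the survivors, and reported
alongside the raw p that drives the gate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

from statsmodels.stats.multitest import multipletests

from .core_model import normalize_symbol
from .errors import FormatError, ValidationError

CATEGORIES = ("BP", "CC", "MF", "KEGG", "custom")


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if not self.genes:
            raise ValidationError(f"term {self.term_id} has an empty gene set")


@dataclass(frozen=True)
class AnnotationCollection:
    terms: tuple[AnnotationTerm, ...]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate term_ids in annotation collection")

    def __len__(self) -> int:
        return len(self.terms)

    def annotated_union(self) -> frozenset[str]:
        out: set[str] = set()
        for term in self.terms:
            out |= term.genes
        return frozenset(out)

    @staticmethod
    def merge(*collections: "AnnotationCollection") -> "AnnotationCollection":
        terms: list[AnnotationTerm] = []
        for coll in collections:
            terms.extend(coll.terms)
        return AnnotationCollection(tuple(terms))


def read_gmt(path: str | Path, category: str = "custom") -> AnnotationCollection:
    """Read a GMT file (term, description, genes..., tab-separated)."""
    terms: list[AnnotationTerm] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError("GMT line needs term, description and >= 1 gene",
                                  line=lineno)
            term_id, name = fields[0].strip(), fields[1].strip()
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"term {term_id!r} has no genes", line=lineno)
            terms.append(AnnotationTerm(term_id, name, category, genes))
    return AnnotationCollection(tuple(terms))


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: overlap statistics, p-value, fold enrichment, BH q."""

    term_id: str
    name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    fold: float
    q_bh: float


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), computed in log space.

    X counts the overlap between a fixed K-subset and a uniformly drawn
    n-subset of an N-element background.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"infeasible hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    if k <= max(0, n + K - N):
        return 1.0
    log_denom = _log_binom(N, n)
    log_terms = [_log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
                 for i in range(k, min(K, n) + 1)]
    m = max(log_terms)
    total = math.fsum(math.exp(t - m) for t in log_terms)
    return min(1.0, math.exp(m) * total)


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """(k/n) / (K/N): query hit rate relative to the background rate."""
    if n <= 0 or K <= 0:
        raise ValidationError("fold enrichment requires n > 0 and K > 0")
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def run_enrichment(query: set[str] | frozenset[str],
                   annotations: AnnotationCollection,
                   background: set[str] | frozenset[str] | str = "annotated-union",
                   min_overlap: int = 3, min_fold: float = 1.5,
                   p_max: float = 0.01) -> list[EnrichmentRow]:
    """Test every term against the query; return the gate-passing rows.

    The background defaults to the union of all annotated genes; query and
    term gene sets are restricted to it before testing. The overlap and fold
    gates are inclusive (>=); the p gate is strict (<). BH q-values are
    assigned per category over all tested terms before gating. Rows are
    sorted ascending by raw p, ties by term_id.
    """
    if background == "annotated-union":
        bg = annotations.annotated_union()
    else:
        bg = frozenset(background)
    if not bg:
        raise ValidationError("background gene set is empty")
    q = frozenset(query) & bg
    if not q:
        raise ValidationError("query is empty after restriction to the background")
    n, N = len(q), len(bg)

    tested: list[tuple[AnnotationTerm, int, int, float, float]] = []
    for term in annotations.terms:
        term_bg = term.genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(q & term_bg)
        p = hypergeometric_upper_tail(k, K, n, N)
        fold = fold_enrichment(k, K, n, N)
        tested.append((term, k, K, p, fold))

    # BH per category over all tested terms
    q_bh: dict[str, float] = {}
    for category in {t[0].category for t in tested}:
        cat = [t for t in tested if t[0].category == category]
        adjusted = multipletests([t[3] for t in cat], method="fdr_bh")[1]
        for (term, *_), qv in zip(cat, adjusted):
            q_bh[term.term_id] = float(qv)

    rows = [
        EnrichmentRow(term.term_id, term.name, term.category, k, K, n, N, p, fold,
                      q_bh[term.term_id])
        for term, k, K, p, fold in tested
        if k >= min_overlap and fold >= min_fold and p < p_max
    ]
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def top_terms(rows: list[EnrichmentRow], per_category: int = 10
              ) -> dict[str, list[EnrichmentRow]]:
    """First ``per_category`` rows per category under the run_enrichment order."""
    out: dict[str, list[EnrichmentRow]] = {}
    for row in rows:
        bucket = out.setdefault(row.category, [])
        if len(bucket) < per_category:
            bucket.append(row)
    return out


def write_enrichment_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["term_id", "name", "category", "k", "K", "n", "N",
                         "p_raw", "fold", "q_bh"])
        for r in rows:
            writer.writerow([r.term_id, r.name, r.category, r.k, r.K, r.n, r.N,
                             repr(r.p_raw), repr(r.fold), repr(r.q_bh)])
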