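"""Disease-target union with provenance, and formula/disease intersection.

Disease targets typically come from several curated databases (OMIM,
GeneCards, TTD, DisGeNET, DrugBank). The union is taken with provenance
retained, so each symbol can be traced back to the sources that reported
it; the intersection with the formula's compound-target union yields the
common (candidate therapeutic) target set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .core_model import CompoundTargetMap
from .errors import ValidationError


@dataclass(frozen=True)
class VennSummary:
    """Per-source counts, union size, and per-symbol source membership."""

    per_source_counts: Mapping[str, int]
    union_count: int
    membership: Mapping[str, frozenset[str]]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_source_counts": dict(sorted(self.per_source_counts.items())),
            "union_count": self.union_count,
            "membership": {sym: sorted(srcs) for sym, srcs in sorted(self.membership.items())},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


@dataclass(frozen=True)
class CommonTargetSet:
    """Formula ∩ disease targets, with the input totals recorded."""

    symbols: frozenset[str]
    formula_total: int
    disease_total: int

    def __post_init__(self) -> None:
        if len(self.symbols) > min(self.formula_total, self.disease_total):
            raise ValidationError("common set larger than an input set")


def union_with_provenance(sources: Mapping[str, set[str] | frozenset[str]]) -> VennSummary:
    """Union named symbol sets, recording which sources contain each symbol."""
    if not sources:
        raise ValidationError("at least one target source is required")
    membership: dict[str, set[str]] = {}
    for label, symbols in sources.items():
        for sym in symbols:
            membership.setdefault(sym, set()).add(label)
    return VennSummary(
        per_source_counts={label: len(symbols) for label, symbols in sources.items()},
        union_count=len(membership),
        membership={sym: frozenset(srcs) for sym, srcs in membership.items()},
    )


def formula_target_union(ctmap: CompoundTargetMap) -> set[str]:
    """Union of every compound's target set."""
    out: set[str] = set()
    for targets in ctmap.entries.values():
        out |= targets
    return out


def intersect_targets(formula: set[str] | frozenset[str],
                      disease: set[str] | frozenset[str]) -> CommonTargetSet:
    """Intersect formula and disease targets; totals are kept for reporting."""
    return CommonTargetSet(
        symbols=frozenset(formula) & frozenset(disease),
        formula_total=len(formula),
        disease_total=len(disease),
    )
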