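"""ADME screening of herbal compounds by oral bioavailability and drug-likeness.

Compounds are kept when OB >= ob_min (percent) and DL >= dl_min, both
inclusive — the conventional TCMSP activity screen (OB >= 30%, DL >= 0.18).
Rejected rows are reported with the failing criterion named, for audit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .core_model import CompoundRecord
from .errors import ValidationError


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusive ADME thresholds: OB in percent, DL on [0, 1]."""

    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ob_min) and math.isfinite(self.dl_min)):
            raise ValidationError("filter thresholds must be finite")
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValidationError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class RejectedCompound:
    record: CompoundRecord
    reasons: tuple[str, ...]  # subset of ("ob_percent", "dl")


@dataclass(frozen=True)
class FilterResult:
    kept: tuple[CompoundRecord, ...]
    rejected: tuple[RejectedCompound, ...]


def apply_filter(records: list[CompoundRecord],
                 criteria: FilterCriteria = FilterCriteria()) -> FilterResult:
    """Partition records into kept and rejected, preserving input order."""
    kept: list[CompoundRecord] = []
    rejected: list[RejectedCompound] = []
    for rec in records:
        reasons = []
        if rec.ob_percent < criteria.ob_min:
            reasons.append("ob_percent")
        if rec.dl < criteria.dl_min:
            reasons.append("dl")
        if reasons:
            rejected.append(RejectedCompound(rec, tuple(reasons)))
        else:
            kept.append(rec)
    return FilterResult(tuple(kept), tuple(rejected))


def filter_compounds(records: list[CompoundRecord],
                     criteria: FilterCriteria = FilterCriteria()) -> list[CompoundRecord]:
    """Keep exactly the records with OB >= ob_min and DL >= dl_min (inclusive)."""
    return list(apply_filter(records, criteria).kept)


def per_herb_counts(records: list[CompoundRecord]) -> dict[str, int]:
    """Count compounds per herb; a multi-herb compound counts once per herb."""
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(rec.herbs)
    return dict(counts)


def unique_compound_count(records: list[CompoundRecord]) -> int:
    """Number of distinct Mol IDs in the table."""
    return len({rec.mol_id for rec in records})
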