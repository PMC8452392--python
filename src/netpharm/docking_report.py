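"""Classification and ranking of externally produced molecular-docking results.

Binding energies (kcal/mol, AutoDock-Vina-style affinities) are interpreted
with the conventional thresholds: a non-negative energy means binding is not
spontaneous; energies between -5 and 0 indicate weak spontaneous binding;
at or below -5 kcal/mol the pair is a good binder. No docking is performed
here — the table is an input.
"""

from __future__ import annotations

import csv
import enum
import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .core_model import normalize_symbol
from .errors import FormatError, ValidationError

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


class BindingClass(enum.Enum):
    NON_SPONTANEOUS = "non_spontaneous"
    SPONTANEOUS_WEAK = "spontaneous_weak"
    GOOD_BINDER = "good_binder"


@dataclass(frozen=True)
class DockingRecord:
    pdb_id: str
    target: str
    compound: str
    energy: float  # kcal/mol

    def __post_init__(self) -> None:
        if not _PDB_ID_RE.match(self.pdb_id):
            raise ValidationError(f"invalid PDB identifier {self.pdb_id!r}")
        if not math.isfinite(self.energy):
            raise ValidationError(f"non-finite binding energy for {self.target}")


def classify_binding(energy: float, strict_good: bool = False) -> BindingClass:
    """Classify a binding energy in kcal/mol.

    The -5 boundary goes to GOOD_BINDER by default; ``strict_good`` moves
    exactly -5.0 into SPONTANEOUS_WEAK for callers wanting a strict cut.
    """
    if not math.isfinite(energy):
        raise ValidationError("binding energy must be finite")
    if energy >= 0:
        return BindingClass.NON_SPONTANEOUS
    good = energy < -5.0 if strict_good else energy <= -5.0
    return BindingClass.GOOD_BINDER if good else BindingClass.SPONTANEOUS_WEAK


@dataclass(frozen=True)
class DockingSummary:
    class_counts: dict[str, int]
    min_energy: float
    min_energy_pairs: tuple[tuple[str, str], ...]  # (target, compound)
    ranking: tuple[DockingRecord, ...]  # ascending energy

    def to_dict(self) -> dict:
        return {
            "class_counts": self.class_counts,
            "min_energy": self.min_energy,
            "min_energy_pairs": [list(p) for p in self.min_energy_pairs],
            "ranking": [
                {"pdb_id": r.pdb_id, "target": r.target,
                 "compound": r.compound, "energy": r.energy}
                for r in self.ranking
            ],
        }


def summarize_docking(records: list[DockingRecord],
                      strict_good: bool = False) -> DockingSummary:
    """Count binding classes, locate the minimum energy, rank all pairs.

    The ranking is ascending by energy with ties broken by (target,
    compound) lexicographically, so it is a deterministic permutation of
    the input.
    """
    if not records:
        raise ValidationError("no docking records to summarize")
    counts = Counter(classify_binding(r.energy, strict_good).value for r in records)
    ranking = tuple(sorted(records, key=lambda r: (r.energy, r.target, r.compound)))
    min_energy = ranking[0].energy
    pairs = tuple(sorted((r.target, r.compound) for r in records if r.energy == min_energy))
    return DockingSummary(dict(counts), min_energy, pairs, ranking)


def read_docking_table(path: str | Path, delimiter: str | None = None) -> list[DockingRecord]:
    """Read a (pdb_id, target, compound, energy) table; unicode minus tolerated."""
    path = Path(path)
    records: list[DockingRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file, expected a header row")
        delim = delimiter or ("\t" if "\t" in first else ",")
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"pdb_id", "target", "compound", "energy"}
        have = {c.strip().lower() for c in (reader.fieldnames or [])}
        missing = required - have
        if missing:
            raise FormatError("docking table is missing required column(s)",
                              column=", ".join(sorted(missing)))
        for lineno, row in enumerate(reader, start=2):
            cells = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            try:
                energy = float(cells["energy"].replace("−", "-"))
            except ValueError:
                raise FormatError(f"unparseable energy {cells['energy']!r}",
                                  line=lineno) from None
            try:
                records.append(DockingRecord(
                    pdb_id=cells["pdb_id"].upper(),
                    target=normalize_symbol(cells["target"]),
                    compound=cells["compound"],
                    energy=energy,
                ))
            except ValidationError as exc:
                raise FormatError(str(exc), line=lineno) from None
    return records
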