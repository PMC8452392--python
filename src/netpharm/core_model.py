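"""Domain types and delimited-text I/O shared by every pipeline stage.

The pipeline consumes TCMSP-style flat-file exports: compound tables
(Mol ID, name, herb attribution, oral bioavailability, drug-likeness),
one-symbol-per-line gene lists, and two-column compound-to-target maps.
Gene identifiers are treated as opaque HGNC-style symbols, normalized to
uppercase; no alias or ortholog resolution is attempted.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ValidationError

_MOL_ID_RE = re.compile(r"^MOL\d+$")

#: Canonical compound-table header and the TCMSP-style aliases accepted for it.
_COMPOUND_COLUMN_ALIASES: dict[str, str] = {
    "mol_id": "mol_id",
    "mol id": "mol_id",
    "molid": "mol_id",
    "name": "name",
    "compound": "name",
    "herbs": "herbs",
    "herb": "herbs",
    "drug": "herbs",
    "ob_percent": "ob_percent",
    "ob (%)": "ob_percent",
    "ob": "ob_percent",
    "dl": "dl",
}


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.

    Raises
    ------
    ValidationError
        If the input is empty or whitespace-only.
    """
    token = raw.strip().upper()
    if not token:
        raise ValidationError("gene symbol is empty after stripping whitespace")
    return token


@dataclass(frozen=True)
class CompoundRecord:
    """One herbal compound row: Mol ID, name, herb attribution and ADME scores.

    ``ob_percent`` is predicted oral bioavailability in percent; ``dl`` is the
    drug-likeness score on [0, 1].
    """

    mol_id: str
    name: str
    herbs: frozenset[str]
    ob_percent: float
    dl: float

    def __post_init__(self) -> None:
        if not _MOL_ID_RE.match(self.mol_id):
            raise ValidationError(f"mol_id {self.mol_id!r} does not match 'MOL' + digits")
        if not self.herbs:
            raise ValidationError(f"compound {self.mol_id} has no herb attribution")
        for herb in self.herbs:
            if not herb or herb != herb.strip():
                raise ValidationError(f"invalid herb label {herb!r} on {self.mol_id}")
        if not (math.isfinite(self.ob_percent) and math.isfinite(self.dl)):
            raise ValidationError(f"non-finite ADME value on {self.mol_id}")
        if self.ob_percent < 0:
            raise ValidationError(f"negative oral bioavailability on {self.mol_id}")
        if not (0.0 <= self.dl <= 1.0):
            raise ValidationError(f"drug-likeness outside [0, 1] on {self.mol_id}")


@dataclass(frozen=True)
class CompoundTargetMap:
    """Per-compound target sets aggregated from a two-column (mol_id, gene) file."""

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mol_id, targets in self.entries.items():
            if not targets:
                raise ValidationError(f"compound {mol_id} maps to an empty target set")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, mol_id: str) -> frozenset[str]:
        return self.entries[mol_id]

    def __iter__(self):
        return iter(self.entries)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _resolve_compound_header(fieldnames: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical column names; error on missing columns."""
    resolved: dict[str, str] = {}
    for raw in fieldnames:
        canon = _COMPOUND_COLUMN_ALIASES.get(raw.strip().lower())
        if canon is not None and canon not in resolved.values():
            resolved[raw] = canon
    missing = {"mol_id", "name", "herbs", "ob_percent", "dl"} - set(resolved.values())
    if missing:
        raise FormatError("compound table is missing required column(s)",
                          column=", ".join(sorted(missing)))
    return resolved


def read_compound_table(path: str | Path, delimiter: str | None = None) -> list[CompoundRecord]:
    """Read a delimited compound table into a list of :class:`CompoundRecord`.

    The delimiter is auto-detected between tab and comma unless given.
    Multi-herb attribution cells are split on commas; surrounding whitespace
    is stripped from each herb label. Duplicate Mol IDs are an error (they
    signal a corrupt export, not a merge request).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file, expected a header row")
        delim = delimiter or _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        colmap = _resolve_compound_header(reader.fieldnames or [])

        records: list[CompoundRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            cells = {canon: (row.get(raw) or "").strip() for raw, canon in colmap.items()}
            try:
                ob = float(cells["ob_percent"])
                dl = float(cells["dl"])
            except ValueError as exc:
                raise FormatError(f"unparseable numeric value: {exc}", line=lineno) from None
            herbs = frozenset(h.strip() for h in cells["herbs"].split(",") if h.strip())
            try:
                rec = CompoundRecord(mol_id=cells["mol_id"], name=cells["name"],
                                     herbs=herbs, ob_percent=ob, dl=dl)
            except ValidationError as exc:
                raise FormatError(str(exc), line=lineno) from None
            if rec.mol_id in seen:
                raise FormatError(f"duplicate mol_id {rec.mol_id!r}", line=lineno)
            seen.add(rec.mol_id)
            records.append(rec)
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path,
                         delimiter: str = ",") -> None:
    """Write records in the canonical header layout; round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["mol_id", "name", "herbs", "ob_percent", "dl"])
        for rec in records:
            herbs = ", ".join(sorted(rec.herbs))
            writer.writerow([rec.mol_id, rec.name, herbs,
                             repr(rec.ob_percent), repr(rec.dl)])


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; '#' comments and blanks ignored."""
    symbols: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            symbols.add(normalize_symbol(token))
    return symbols


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for sym in sorted(symbols):
            fh.write(sym + "\n")


def read_compound_target_map(path: str | Path, delimiter: str | None = None) -> CompoundTargetMap:
    """Read two-column (mol_id, gene) rows and aggregate per-compound target sets.

    Repeated rows are allowed and deduplicated after symbol normalization.
    """
    path = Path(path)
    grouped: dict[str, set[str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        delim = delimiter or _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if lineno == 1 and row[0].strip().lower() in {"mol_id", "mol id"}:
                continue  # optional header
            if len(row) < 2:
                raise FormatError("expected two columns (mol_id, gene)", line=lineno)
            mol_id, gene = row[0].strip(), row[1].strip()
            if not mol_id or not gene:
                raise FormatError("blank mol_id or gene cell", line=lineno)
            try:
                grouped.setdefault(mol_id, set()).add(normalize_symbol(gene))
            except ValidationError as exc:
                raise FormatError(str(exc), line=lineno) from None
    return CompoundTargetMap({m: frozenset(s) for m, s in grouped.items()})


def write_compound_target_map(ctmap: CompoundTargetMap, path: str | Path,
                              delimiter: str = ",") -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["mol_id", "gene"])
        for mol_id in sorted(ctmap.entries):
            for gene in sorted(ctmap.entries[mol_id]):
                writer.writerow([mol_id, gene])
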