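"""Bundled reference tables.

Two small published reference tables for the six-herb Liuwei Dihuang
formula ship with the package as plain CSV: the TCMSP-screened active
compound table (41 compounds across Shudihuang, Mudanpi, Shanyao,
Shanzhuyu, Zexie and Fuling) and the AutoDock-Vina binding-energy table
for the nine key diabetic-nephropathy targets against their corresponding
compounds (16 pairs).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core_model import CompoundRecord, read_compound_table
from .docking_report import DockingRecord, read_docking_table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("netpharm").joinpath("data", name)))


def ldp_compound_table_path() -> Path:
    return _data_path("ldp_compounds.csv")


def ldp_docking_table_path() -> Path:
    return _data_path("ldp_docking.csv")


def load_ldp_compounds() -> list[CompoundRecord]:
    """The 41-compound Liuwei Dihuang active-compound table."""
    return read_compound_table(ldp_compound_table_path())


def load_ldp_docking() -> list[DockingRecord]:
    """The 16-pair key-target docking-result table."""
    return read_docking_table(ldp_docking_table_path())
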