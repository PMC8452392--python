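"""Seeded generator of complete synthetic network-pharmacology bundles.

The generator emits, in exactly the flat-file formats the readers consume,
a dataset with the statistical structure the pipeline assumes: a compound
table with a controlled ADME pass rate, a compound-target map with a few
hub compounds of much higher degree (the quercetin-like pattern), disease
source lists partially overlapping the formula target union, a scored PPI
edge list with a planted dense core and sparse periphery, and GMT
collections whose planted terms over-sample the common targets. A
ground-truth manifest records what was planted so recovery can be scored.

One integer seed drives one root stream with a named substream per
artifact, so adding a generator does not perturb the others; identical
configs and seeds give byte-identical bundles. Degree structure is planted
by explicit range assignment rather than preferential attachment —
controllable ground truth beats realism for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_model import CompoundRecord, write_compound_table, write_gene_list
from .errors import ValidationError

_SUBSTREAMS = {"compounds": 0, "map": 1, "disease": 2, "ppi": 3, "terms": 4}

_DEFAULT_HERBS = ("Shudihuang", "Mudanpi", "Shanyao", "Shanzhuyu", "Zexie", "Fuling")
_DEFAULT_SOURCES = ("OMIM", "GeneCards", "TTD", "DisGeNET", "DrugBank")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults mirror the study scale, with
    targets downscaled roughly 1:3 so end-to-end runs take seconds."""

    seed: int = 0
    n_herbs: int = 6
    compounds_per_herb: int = 7
    ob_pass_fraction: float = 0.5
    multi_herb_fraction: float = 0.1
    n_targets: int = 150
    n_hub_compounds: int = 5
    hub_degree_range: tuple[int, int] = (15, 30)
    background_degree_range: tuple[int, int] = (1, 5)
    disease_source_sizes: tuple[int, ...] = (15, 120, 12, 43, 20)
    n_disease_only: int = 120
    disease_formula_overlap_fraction: float = 0.6
    ppi_core_size: int = 10
    ppi_p_core: float = 0.9
    ppi_p_periphery: float = 0.02
    ppi_p_core_periphery: float = 0.1
    n_terms_per_category: int = 20
    planted_enriched_terms: int = 2
    planted_term_common_fraction: float = 0.7
    planted_term_size_range: tuple[int, int] = (15, 30)
    background_term_size_range: tuple[int, int] = (10, 40)

    def __post_init__(self) -> None:
        sizes = (self.n_herbs, self.compounds_per_herb, self.n_targets,
                 self.n_hub_compounds, self.ppi_core_size,
                 self.n_terms_per_category, self.n_disease_only)
        if any(s <= 0 for s in sizes):
            raise ValidationError("all size parameters must be positive")
        for p in (self.ob_pass_fraction, self.disease_formula_overlap_fraction,
                  self.ppi_p_core, self.ppi_p_periphery, self.ppi_p_core_periphery):
            if not (0.0 < p < 1.0):
                raise ValidationError("probabilities must lie strictly in (0, 1)")
        if self.hub_degree_range[0] <= self.background_degree_range[1]:
            raise ValidationError("hub degree range must lie above the background range")
        if self.hub_degree_range[1] > self.n_targets:
            raise ValidationError("hub degree exceeds the target pool")

    @property
    def n_compounds(self) -> int:
        return self.n_herbs * self.compounds_per_herb


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: hubs, PPI core, enriched terms, true common set."""

    hub_mol_ids: tuple[str, ...]
    ppi_core: tuple[str, ...]
    planted_term_ids: tuple[str, ...]
    common_targets: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return GroundTruth(**{k: tuple(v) for k, v in raw.items()})


@dataclass(frozen=True)
class SynthBundle:
    """File layout of one generated dataset."""

    out_dir: Path
    compounds: Path
    compound_targets: Path
    disease_lists: dict[str, Path]
    ppi_edges: Path
    gmt_files: dict[str, Path]
    ground_truth_path: Path
    ground_truth: GroundTruth


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _SUBSTREAMS[stream]])


def _herb_labels(config: SynthConfig) -> list[str]:
    if config.n_herbs == len(_DEFAULT_HERBS):
        return list(_DEFAULT_HERBS)
    return [f"Herb{i + 1:02d}" for i in range(config.n_herbs)]


def _source_labels(config: SynthConfig) -> list[str]:
    if len(config.disease_source_sizes) == len(_DEFAULT_SOURCES):
        return list(_DEFAULT_SOURCES)
    return [f"source{i + 1}" for i in range(len(config.disease_source_sizes))]


def generate(config: SynthConfig, out_dir: str | Path) -> SynthBundle:
    """Write a complete synthetic bundle under ``out_dir`` and return its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- compound table -----------------------------------------------------
    rng = _rng(config, "compounds")
    herbs = _herb_labels(config)
    records: list[CompoundRecord] = []
    passing: list[str] = []
    for i in range(config.n_compounds):
        mol_id = f"MOL9{i:05d}"
        herb_set = {herbs[i % config.n_herbs]}
        if rng.random() < config.multi_herb_fraction:
            extra = herbs[int(rng.integers(config.n_herbs))]
            herb_set.add(extra)  # may coincide with the primary herb
        passes = rng.random() < config.ob_pass_fraction
        if passes:
            ob = float(rng.uniform(30.0, 100.0))
            dl = float(rng.uniform(0.18, 1.0))
            passing.append(mol_id)
        else:
            mode = int(rng.integers(3))  # fail OB, fail DL, or both
            ob = float(rng.uniform(0.0, 30.0)) if mode in (0, 2) else float(rng.uniform(30.0, 100.0))
            dl = float(rng.uniform(0.0, 0.18)) if mode in (1, 2) else float(rng.uniform(0.18, 1.0))
        records.append(CompoundRecord(mol_id, f"compound-{i:03d}", frozenset(herb_set), ob, dl))
    compounds_path = out / "compounds.csv"
    write_compound_table(records, compounds_path)

    if len(passing) < config.n_hub_compounds:
        raise ValidationError("too few compounds pass the ADME filter to plant hubs; "
                              "raise ob_pass_fraction or the compound count")

    # --- compound-target map (actives only, hubs planted by degree range) ---
    rng = _rng(config, "map")
    pool = np.array([f"TGT{i:04d}" for i in range(config.n_targets)])
    hubs = sorted(rng.choice(np.array(sorted(passing)), config.n_hub_compounds,
                             replace=False).tolist())
    map_path = out / "compound_targets.csv"
    with map_path.open("w", encoding="utf-8") as fh:
        fh.write("mol_id,gene\n")
        formula_union: set[str] = set()
        for mol_id in sorted(passing):
            lo, hi = (config.hub_degree_range if mol_id in hubs
                      else config.background_degree_range)
            deg = int(rng.integers(lo, hi + 1))
            targets = sorted(rng.choice(pool, deg, replace=False).tolist())
            formula_union.update(targets)
            for gene in targets:
                fh.write(f"{mol_id},{gene}\n")

    # --- disease source lists ----------------------------------------------
    rng = _rng(config, "disease")
    n_common = int(round(config.disease_formula_overlap_fraction * len(formula_union)))
    if n_common < config.ppi_core_size:
        raise ValidationError("common set smaller than the PPI core to plant")
    if n_common > sum(config.disease_source_sizes):
        raise ValidationError("disease source sizes cannot hold the planted overlap")
    common = sorted(rng.choice(np.array(sorted(formula_union)), n_common,
                               replace=False).tolist())
    disease_only = [f"DIS{i:04d}" for i in range(config.n_disease_only)]
    pool_all = np.array(common + disease_only)
    if max(config.disease_source_sizes) > len(pool_all):
        raise ValidationError("a disease source is larger than the disease gene pool")

    labels = _source_labels(config)
    members: dict[str, set[str]] = {lab: set() for lab in labels}
    capacity = {lab: size for lab, size in zip(labels, config.disease_source_sizes)}
    for gene in common:  # every planted common gene lands in >= 1 source
        open_labels = [lab for lab in labels if len(members[lab]) < capacity[lab]]
        weights = np.array([capacity[lab] - len(members[lab]) for lab in open_labels], float)
        pick = open_labels[int(rng.choice(len(open_labels), p=weights / weights.sum()))]
        members[pick].add(gene)
    for lab in labels:
        need = capacity[lab] - len(members[lab])
        remaining = np.array(sorted(set(pool_all.tolist()) - members[lab]))
        members[lab].update(rng.choice(remaining, need, replace=False).tolist())

    disease_paths: dict[str, Path] = {}
    for lab in labels:
        p = out / f"disease_{lab.lower()}.txt"
        write_gene_list(members[lab], p)
        disease_paths[lab] = p

    # --- PPI edge list with planted core ------------------------------------
    rng = _rng(config, "ppi")
    core = sorted(rng.choice(np.array(common), config.ppi_core_size, replace=False).tolist())
    core_set = set(core)
    ppi_path = out / "ppi_edges.tsv"
    with ppi_path.open("w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        nodes = common
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                in_core = (a in core_set) + (b in core_set)
                # periphery attaches preferentially to the core (Borgatti-Everett
                # style), so the planted core is central on all three measures
                p = (config.ppi_p_core if in_core == 2
                     else config.ppi_p_core_periphery if in_core == 1
                     else config.ppi_p_periphery)
                if rng.random() < p:
                    score = int(rng.integers(700, 1001))
                    fh.write(f"{a}\t{b}\t{score}\n")

    # --- annotation collections ---------------------------------------------
    rng = _rng(config, "terms")
    universe = np.array(sorted(set(common) | formula_union | set(disease_only)))
    common_arr = np.array(common)
    gmt_paths: dict[str, Path] = {}
    planted_ids: list[str] = []
    for category in ("BP", "CC", "MF", "KEGG"):
        fname = f"go_{category.lower()}.gmt" if category != "KEGG" else "kegg.gmt"
        path = out / fname
        with path.open("w", encoding="utf-8") as fh:
            for t in range(config.n_terms_per_category):
                term_id = f"{category}_T{t:03d}"
                if t < config.planted_enriched_terms:
                    lo, hi = config.planted_term_size_range
                    size = int(rng.integers(lo, hi + 1))
                    n_from_common = min(int(round(size * config.planted_term_common_fraction)),
                                        len(common_arr))
                    genes = set(rng.choice(common_arr, n_from_common, replace=False).tolist())
                    rest = np.array(sorted(set(universe.tolist()) - genes))
                    genes |= set(rng.choice(rest, size - n_from_common, replace=False).tolist())
                    planted_ids.append(term_id)
                    desc = "planted"
                else:
                    lo, hi = config.background_term_size_range
                    size = int(rng.integers(lo, hi + 1))
                    genes = set(rng.choice(universe, size, replace=False).tolist())
                    desc = "background"
                fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")
        gmt_paths[category] = path

    truth = GroundTruth(tuple(hubs), tuple(core), tuple(planted_ids), tuple(common))
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)

    return SynthBundle(out, compounds_path, map_path, disease_paths, ppi_path,
                       gmt_paths, truth_path, truth)


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of planted structure in the pipeline's outputs."""

    hub_precision: float | None
    hub_recall: float | None
    core_precision: float | None
    core_recall: float | None
    term_precision: float | None
    term_recall: float | None


def _precision_recall(truth: set[str], found: set[str]) -> tuple[float, float]:
    if not truth:
        raise ValidationError("empty ground-truth set")
    tp = len(truth & found)
    precision = tp / len(found) if found else 0.0
    return precision, tp / len(truth)


def evaluate_recovery(truth: GroundTruth,
                      top_compounds: list[str] | None = None,
                      key_targets: set[str] | frozenset[str] | None = None,
                      enriched_term_ids: set[str] | frozenset[str] | None = None
                      ) -> RecoveryReport:
    """Score pipeline outputs against the planted structure.

    ``top_compounds`` is the degree-ranked compound list (hub recovery),
    ``key_targets`` the final screening survivors (core recovery), and
    ``enriched_term_ids`` the gate-passing terms (planted-term recovery).
    Sections not supplied are reported as None.
    """
    hub_p = hub_r = core_p = core_r = term_p = term_r = None
    if top_compounds is not None:
        hub_p, hub_r = _precision_recall(set(truth.hub_mol_ids), set(top_compounds))
    if key_targets is not None:
        core_p, core_r = _precision_recall(set(truth.ppi_core), set(key_targets))
    if enriched_term_ids is not None:
        term_p, term_r = _precision_recall(set(truth.planted_term_ids),
                                           set(enriched_term_ids))
    return RecoveryReport(hub_p, hub_r, core_p, core_r, term_p, term_r)
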