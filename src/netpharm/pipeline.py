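"""End-to-end orchestration: filter -> intersect -> network -> screen -> enrich -> dock.

A single :class:`RunConfig` (YAML-loadable) names the inputs and parameters;
:func:`run_all` executes the stages in order, skipping any stage whose inputs
are absent (with a logged warning), writes every stage's outputs as plain
text under the output directory, and returns a :class:`RunSummary` whose
counts mirror the headline numbers a network-pharmacology study reports.
Every default parameter is the conventional published setting: OB >= 30%,
DL >= 0.18, STRING combined score >= 700, Min Overlap 3, Min Enrichment 1.5,
p < 0.01, top-10 terms, screening down to 9 key targets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .adme_filter import FilterCriteria, apply_filter, per_herb_counts, unique_compound_count
from .core_model import (read_compound_table, read_compound_target_map, read_gene_list,
                         write_compound_table, write_gene_list)
from .docking_report import read_docking_table, summarize_docking
from .enrichment import AnnotationCollection, read_gmt, run_enrichment, top_terms, \
    write_enrichment_tsv
from .errors import NetpharmError, ValidationError
from .hct_network import build_hct, compound_degree_ranking, export_network
from .ppi_screen import (Thresholds, iterative_screen, read_string_edges, remove_isolates,
                         write_centrality_table, write_edge_tsv)
from .target_sets import formula_target_union, intersect_targets, union_with_provenance

log = logging.getLogger("netpharm")


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run; any input may be omitted."""

    out_dir: Path
    compounds: Path | None = None
    compound_targets: Path | None = None
    disease_lists: dict[str, Path] = field(default_factory=dict)
    string_edges: Path | None = None
    gmt_files: dict[str, Path] = field(default_factory=dict)  # category -> path
    docking: Path | None = None

    ob_min: float = 30.0
    dl_min: float = 0.18
    score_min: int = 700
    target_size: int | None = 9
    min_size: int | None = None
    max_rounds: int | None = None
    screening_overrides: list[tuple[float, float, float] | None] | None = None
    min_overlap: int = 3
    min_fold: float = 1.5
    p_max: float = 0.01
    top_k: int = 10
    background: str = "annotated-union"
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        base = Path(path).parent

        def _path(value):  # input paths resolve relative to the config file
            return (base / value) if value is not None else None

        cfg = RunConfig(out_dir=_path(raw.get("out_dir", "out")))
        for key in ("compounds", "compound_targets", "string_edges", "docking"):
            setattr(cfg, key, _path(raw.get(key)))
        cfg.disease_lists = {k: base / v for k, v in (raw.get("disease_lists") or {}).items()}
        cfg.gmt_files = {k: base / v for k, v in (raw.get("gmt_files") or {}).items()}
        for key in ("ob_min", "dl_min", "score_min", "target_size", "min_size", "max_rounds",
                    "min_overlap", "min_fold", "p_max", "top_k", "background",
                    "seed", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if raw.get("screening_overrides") is not None:
            cfg.screening_overrides = [tuple(t) if t is not None else None
                                       for t in raw["screening_overrides"]]
        return cfg

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        for key in ("compounds", "compound_targets", "string_edges", "docking"):
            d[key] = str(d[key]) if d[key] is not None else None
        d["disease_lists"] = {k: str(v) for k, v in sorted(self.disease_lists.items())}
        d["gmt_files"] = {k: str(v) for k, v in sorted(self.gmt_files.items())}
        return d


def config_hash(config: RunConfig) -> str:
    """Digest of the canonicalized config (paths and parameters)."""
    text = json.dumps(config.canonical_dict(), sort_keys=True)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def version_stamp(config: RunConfig) -> str:
    """Package version plus config digest, embedded in every summary."""
    return f"netpharm {__version__}+cfg.{config_hash(config)[:12]}"


@dataclass
class RunSummary:
    """Machine-readable per-stage counts and headline results of one run."""

    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _exists(path: Path | None) -> bool:
    return path is not None and Path(path).exists()


def run_all(config: RunConfig) -> RunSummary:
    """Execute all stages whose inputs are present; see the module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(version=version_stamp(config),
                         config=config.canonical_dict(),
                         started_at=time.strftime("%Y-%m-%dT%H:%M:%S"))

    filtered = None
    herbs_by_compound: dict[str, frozenset[str]] = {}
    common = None
    ctmap = None

    # --- stage: filter ------------------------------------------------------
    if _exists(config.compounds):
        log.info("START filter: %s", config.compounds)
        records = read_compound_table(config.compounds)
        result = apply_filter(records, FilterCriteria(config.ob_min, config.dl_min))
        filtered = list(result.kept)
        herbs_by_compound = {r.mol_id: r.herbs for r in filtered}
        write_compound_table(filtered, out / "compounds_kept.csv")
        with (out / "compounds_rejected.csv").open("w", encoding="utf-8") as fh:
            fh.write("mol_id,failed_criteria\n")
            for rej in result.rejected:
                fh.write(f"{rej.record.mol_id},{';'.join(rej.reasons)}\n")
        summary.stages["filter"] = {
            "input_compounds": len(records),
            "kept": len(filtered),
            "rejected": len(result.rejected),
            "unique_kept": unique_compound_count(filtered),
            "per_herb_counts": dict(sorted(per_herb_counts(filtered).items())),
        }
        log.info("END filter: kept %d / %d", len(filtered), len(records))
    else:
        summary.stages["filter"] = {"skipped": True}
        log.warning("filter skipped: no compound table")

    # --- stage: intersect ---------------------------------------------------
    if _exists(config.compound_targets) and config.disease_lists:
        log.info("START intersect")
        ctmap = read_compound_target_map(config.compound_targets)
        if filtered is not None:  # restrict the map to ADME-passing compounds
            kept_ids = {r.mol_id for r in filtered}
            from .core_model import CompoundTargetMap
            ctmap = CompoundTargetMap({m: t for m, t in ctmap.entries.items()
                                       if m in kept_ids})
        formula = formula_target_union(ctmap)
        sources = {label: read_gene_list(path)
                   for label, path in config.disease_lists.items()}
        venn = union_with_provenance(sources)
        venn.to_json(out / "venn.json")
        disease = set(venn.membership)
        common = intersect_targets(formula, disease)
        if not common.symbols:
            log.warning("intersect: formula and disease target sets are disjoint")
        write_gene_list(common.symbols, out / "common_targets.txt")
        summary.stages["intersect"] = {
            "formula_targets": len(formula),
            "per_source_counts": dict(sorted(venn.per_source_counts.items())),
            "disease_union": venn.union_count,
            "common_targets": len(common.symbols),
        }
        log.info("END intersect: %d common of %d formula / %d disease",
                 len(common.symbols), len(formula), venn.union_count)
    else:
        summary.stages["intersect"] = {"skipped": True}
        log.warning("intersect skipped: need compound-target map and disease lists")

    # --- stage: network -----------------------------------------------------
    if ctmap is not None and common is not None:
        log.info("START network")
        net = build_hct(ctmap, common, compound_herbs=herbs_by_compound)
        export_network(net, out / "hct_network.sif", "sif")
        export_network(net, out / "hct_network.graphml", "graphml")
        export_network(net, out / "hct_edges.tsv", "edge-tsv")
        ranking = compound_degree_ranking(net, max(config.top_k, 1))
        with (out / "compound_ranking.tsv").open("w", encoding="utf-8") as fh:
            fh.write("mol_id\tdegree\n")
            for mol_id, deg in ranking:
                fh.write(f"{mol_id}\t{deg}\n")
        summary.stages["network"] = {
            "compound_nodes": len(net.compound_nodes),
            "target_nodes": len(net.target_nodes),
            "nodes": net.node_count,
            "edges": net.edge_count,
            "top_compounds": [[m, d] for m, d in ranking],
        }
        log.info("END network: %d nodes / %d edges", net.node_count, net.edge_count)
    else:
        summary.stages["network"] = {"skipped": True}
        log.warning("network skipped: no intersect result")

    # --- stage: screen ------------------------------------------------------
    if _exists(config.string_edges):
        log.info("START screen: %s", config.string_edges)
        overrides = None
        if config.screening_overrides is not None:
            overrides = [Thresholds(*t) if t is not None else None
                         for t in config.screening_overrides]
        graph = remove_isolates(read_string_edges(config.string_edges, config.score_min))
        if not graph.nodes:
            summary.stages["screen"] = {"skipped": True, "reason": "no edges pass the score gate"}
            log.warning("screen skipped: no edges pass the score gate")
        else:
            history = iterative_screen(graph, max_rounds=config.max_rounds,
                                       target_size=config.target_size,
                                       min_size=config.min_size,
                                       overrides=overrides)
            rounds_meta = []
            for i, rnd in enumerate(history, start=1):
                write_centrality_table(rnd.centralities, out / f"screen_round{i}_centrality.tsv")
                write_edge_tsv(rnd.graph, out / f"screen_round{i}_edges.tsv")
                rounds_meta.append({
                    "thresholds": list(rnd.thresholds),
                    "nodes": rnd.node_count,
                    "edges": rnd.edge_count,
                })
            key = sorted((history[-1].graph if history else graph).nodes)
            write_gene_list(key, out / "key_targets.txt")
            summary.stages["screen"] = {
                "input_nodes": graph.node_count,
                "input_edges": graph.edge_count,
                "rounds": rounds_meta,
                "key_targets": key,
            }
            log.info("END screen: %d -> %d nodes over %d round(s)",
                     graph.node_count, len(key), len(history))
    else:
        summary.stages["screen"] = {"skipped": True}
        log.warning("screen skipped: no PPI edge list")

    # --- stage: enrich ------------------------------------------------------
    if config.gmt_files and common is not None and common.symbols:
        log.info("START enrich")
        collection = AnnotationCollection.merge(
            *(read_gmt(path, category) for category, path in sorted(config.gmt_files.items())))
        background = config.background
        if background != "annotated-union":
            background = read_gene_list(background)
        try:
            rows = run_enrichment(common.symbols, collection, background,
                                  config.min_overlap, config.min_fold, config.p_max)
        except ValidationError as exc:
            summary.stages["enrich"] = {"skipped": True, "reason": str(exc)}
            log.warning("enrich skipped: %s", exc)
        else:
            write_enrichment_tsv(rows, out / "enrichment.tsv")
            top = top_terms(rows, config.top_k)
            summary.stages["enrich"] = {
                "terms_tested": len(collection),
                "terms_passing": len(rows),
                "per_category_passing": {cat: sum(r.category == cat for r in rows)
                                         for cat in sorted({r.category for r in rows})},
                "top_terms": {cat: [r.term_id for r in rows_] for cat, rows_ in top.items()},
            }
            log.info("END enrich: %d/%d terms pass", len(rows), len(collection))
    else:
        summary.stages["enrich"] = {"skipped": True}
        log.warning("enrich skipped: need GMT files and a non-empty common set")

    # --- stage: dock-report -------------------------------------------------
    if _exists(config.docking):
        log.info("START dock-report: %s", config.docking)
        records = read_docking_table(config.docking)
        dock = summarize_docking(records)
        (out / "docking_summary.json").write_text(
            json.dumps(dock.to_dict(), indent=2) + "\n", encoding="utf-8")
        summary.stages["dock_report"] = {
            "records": len(records),
            "class_counts": dock.class_counts,
            "min_energy": dock.min_energy,
            "min_energy_pairs": [list(p) for p in dock.min_energy_pairs],
        }
        log.info("END dock-report: %d records, min %.2f kcal/mol",
                 len(records), dock.min_energy)
    else:
        summary.stages["dock_report"] = {"skipped": True}
        log.warning("dock-report skipped: no docking table")

    summary.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    summary.to_json(out / "summary.json")
    return summary
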