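# netpharm

A tested, reproducible pipeline for the standard network-pharmacology workflow
used to study multi-compound herbal formulas — the analysis that is usually
performed by hand across web tools (TCMSP exports, Venn web apps, STRING,
Cytoscape/CytoNCA, Metascape), reimplemented as a library plus CLI so every
step is scriptable, auditable and testable offline.

The running example shipped with the package is the six-herb formula Liuwei
Dihuang (Shudihuang, Mudanpi, Shanyao, Shanzhuyu, Zexie, Fuling) studied
against diabetic nephropathy: its published 41-compound ADME-screened table
and its 16-pair molecular-docking result table are bundled as plain CSV.

## What the pipeline computes

1. **ADME filter** — keep compounds with oral bioavailability OB ≥ 30% and
   drug-likeness DL ≥ 0.18 (both inclusive); rejected rows are reported with
   the failing criterion.
2. **Target sets** — union disease-gene lists from several databases with
   per-source provenance (Venn summary), intersect with the formula's
   compound-target union to get the common targets.
3. **Herb-compound-target network** — bipartite graph of compounds vs common
   targets (herb membership as a node attribute); compounds ranked by degree
   to nominate crucial compounds.
4. **PPI screening** — read a STRING-style scored edge list (combined score
   ≥ 700), drop isolates, then iteratively screen: compute betweenness,
   closeness and degree centrality *B(v), C(v), D(v)* with in-repo algorithms
   (Brandes' betweenness, unnormalized; within-component closeness
   (|C|−1)/Σd), keep nodes with
   *B(v) ≥ med(B), C(v) ≥ med(C), D(v) ≥ med(D)* (all inclusive), induce the
   subgraph and repeat. Survivors are the key targets.
5. **Enrichment** — over-representation of the common targets against GMT
   collections (GO BP/CC/MF, KEGG): for overlap *k*, term size *K*, query
   size *n*, background *N*, the p-value is the hypergeometric upper tail
   P[X ≥ k], computed in log space; gates are overlap ≥ 3, fold enrichment
   (k/n)/(K/N) ≥ 1.5, raw p < 0.01; Benjamini–Hochberg q-values are reported
   per category.
6. **Docking report** — classify externally produced binding energies
   (kcal/mol): ≥ 0 non-spontaneous, (−5, 0) weak, ≤ −5 good binder; rank
   pairs by energy. (No docking is performed.)

A seeded synthetic-data generator (`netpharm.synthetic_data`) emits complete
bundles — compound tables with a controlled pass rate, hub-structured
compound-target maps, overlapping disease lists, core-periphery PPI graphs,
planted enriched GMT terms — with a ground-truth manifest, so the whole
pipeline is benchmarked end to end without downloads.

## Worked example

```sh
$ netpharm filter --compounds src/netpharm/data/ldp_compounds.csv --out kept.csv
kept 41, rejected 0; per-herb: {'Fuling': 6, 'Mudanpi': 6, 'Shanyao': 12, 'Shanzhuyu': 13, 'Shudihuang': 2, 'Zexie': 7}
```

All 41 bundled compounds pass the screen (the table is already
ADME-filtered; the boundary compound MOL001559 with DL = 0.18 exactly is
kept because both thresholds are inclusive), and the per-herb composition is
2/6/12/13/7/6 across the six herbs — 46 attributions for 41 compounds, since
stigmasterol belongs to three herbs and sitosterol to four.

```sh
$ netpharm simulate --seed 7 --out demo/
$ netpharm screen --edges demo/ppi_edges.tsv --score-min 700 --target-size 10 --history hist/
input: 56 nodes / 126 edges
round 1: thresholds b>=1.58869 c>=0.370375 d>=2 -> 20 nodes / 64 edges
round 2: thresholds b>=3.65476 c>=0.577586 d>=6.5 -> 8 nodes / 27 edges
key targets: TGT0001, TGT0030, TGT0045, TGT0061, TGT0091, TGT0102, TGT0116, TGT0128
```

Each round prints the median threshold triple it derived and the surviving
network size; the final survivors are the key targets.

```sh
$ netpharm dock-report --table src/netpharm/data/ldp_docking.csv
{
  "class_counts": { "good_binder": 16 },
  "min_energy": -8.8,
  "min_energy_pairs": [["JUN", "Quercetin"], ["MAPK1", "Quercetin"]],
  ...
}
```

All 16 docked pairs bind at −5 kcal/mol or better; the strongest predicted
binding (−8.8 kcal/mol) is quercetin against JUN and against MAPK1.

End-to-end runs are driven by a YAML config
(`netpharm run-all --config run.yaml`), which writes every stage's outputs
plus a machine-readable `summary.json` stamped with the package version and
a digest of the configuration. `configs/reference_replay.yaml` is the
full-scale reference configuration: supplied with the original
disease-database exports and STRING edge table, it replays the published
analysis verbatim (including the printed per-round screening thresholds);
its expected reference counts are recorded in the file's comments.

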