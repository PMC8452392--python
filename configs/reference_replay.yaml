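# Reference replay of the published full-scale Liuwei Dihuang / diabetic-nephropathy
# analysis. The five disease-database exports, the compound-target map and the STRING
# edge export are not redistributable with this repository; place them under
# ./supplementary/ with the names below, then run from the repository root:
#
#     netpharm run-all --config configs/reference_replay.yaml
#
# Reference values reported for this run (recorded for comparison; the counts
# depending on the supplementary files are reproducible only with them):
#   formula targets 186; disease-target union 3701; common targets 131
#   herb-compound-target network: 172 nodes / 293 edges; top compound degrees
#   quercetin 104, kaempferol 42, beta-sitosterol 16, diosgenin 16, stigmasterol 13
#   PPI screening trajectory: 122 -> 43 -> 20 -> 9 nodes (914 -> 440 -> 155 -> 77 edges)
#   final key targets: JUN, MAPK8, AKT1, EGF, TP53, VEGFA, MMP9, MAPK1, TNF
#
# The per-round threshold triples below replay the published screening verbatim
# (the third round's printed thresholds are not exactly the medians of the
# 20-node network, so overrides are required for an exact replay).
out_dir: reference_out
compounds: ../src/netpharm/data/ldp_compounds.csv
compound_targets: supplementary/compound_targets.csv
disease_lists:
  OMIM: supplementary/omim.txt
  GeneCards: supplementary/genecards.txt
  TTD: supplementary/ttd.txt
  DisGeNET: supplementary/disgenet.txt
  DrugBank: supplementary/drugbank.txt
string_edges: supplementary/string_edges.tsv
docking: ../src/netpharm/data/ldp_docking.csv
ob_min: 30
dl_min: 0.18
score_min: 700
target_size: 9
screening_overrides:
  - [38.641242955, 0.445673703, 11]
  - [13.17520385, 0.65625, 20]
  - [3.3646742145, 0.826086957, 15]
min_overlap: 3
min_fold: 1.5
p_max: 0.01
top_k: 10
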