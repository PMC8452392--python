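# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, the design decisions taken where the workflow is
conventionally underspecified, and what the synthetic benchmark does and
does not establish.

## ADME screening

Compounds are kept when OB ≥ `ob_min` (percent, default 30) **and**
DL ≥ `dl_min` (default 0.18). Both comparisons are inclusive: TCMSP-style
tables contain compounds sitting exactly on the DL = 0.18 boundary, and the
conventional criterion is stated with ≥. OB and DL are inputs, not
predictions; the package performs no chemistry. Compounds are keyed by Mol
ID only — duplicate Mol IDs in a table are treated as a corrupt export and
rejected rather than merged, and no deduplication by compound name is
attempted. Rejected rows are returned alongside the kept ones with the
failing criteria named, because published analyses report only survivors
and the rejects are otherwise unauditable.

## Target sets

Gene identifiers are opaque HGNC-style symbols normalized to uppercase with
whitespace stripped; no alias, ortholog or species resolution is performed
(identifier mapping is upstream data curation). The disease-target union
keeps provenance — for every symbol, the set of source databases that
reported it — so each common target can be traced back; the published
workflow discards this information after drawing a Venn diagram. Source
lists are taken as given; no relevance-score cutoffs are applied before the
union.

## Herb-compound-target network

The network is a simple bipartite graph: edges are (compound, target) pairs
with the target in the common set. A compound hitting the same target
through multiple herb attributions contributes one edge. Herb membership is
a node attribute rather than a third partition (published figures encode
herbs as node colors). Compounds left without edges are retained by default
— the published node counts include them — and can be dropped with a flag.
The degree ranking breaks ties by Mol ID lexicographically so output is
deterministic.

## PPI screening

**Input.** STRING-style edge tables with integer combined scores on
0–1000. "Confidence > 0.7" maps to score ≥ 700, inclusive (STRING exports
integers; the web UI's 0.700 cutoff is conventionally inclusive).
Duplicate and reversed pairs collapse to one edge keeping the maximum
score; self-loops are dropped; degree-0 nodes are removed in a separate
"hide discrete targets" step, not during screening.

**Centralities** (unweighted, authored in-repo; external graph libraries
are used only as test oracles):

* degree — incident edge count;
* closeness — for node *v* in connected component *C* with |C| > 1,
  (|C|−1)/Σ_{u∈C} d(v,u); isolated nodes get 0. This within-component
  convention (the common Cytoscape/CytoNCA behaviour, values in [0,1]) was
  chosen over harmonic centrality; it is the configurable point most likely
  to differ between tools.
* betweenness — Brandes' algorithm, **unnormalized**, with each unordered
  source–target pair counted once. Published screening thresholds exceed 1,
  which rules out normalized values.

Nodes are iterated in lexicographic order wherever order could affect
floating-point accumulation, making outputs bit-stable.

**Median screening.** Each round computes the centrality table on the
current graph, takes the per-measure sample median (even counts: mean of
the two middle order statistics) as an inclusive threshold triple, keeps
nodes at or above all three, and induces the subgraph on the survivors.
Thresholds are recomputed each round on the shrinking graph. Per-round
override triples are supported so a published trajectory can be replayed
verbatim (published third-round thresholds are not always exact medians,
suggesting manual choice).

**Stopping.** Four stop conditions are supported: fixed point (a round
removes nothing — e.g. complete graphs, where all centralities are equal
and the inclusive median keeps everything), empty graph, a round budget
(`max_rounds`), and a size rule. The size rule comes in two forms.
`target_size` stops once the node count is at or below the target; because
a three-way median cut typically removes well over half of the nodes, this
can land far below the target. `min_size` is a floor: a round that would
leave fewer than `min_size` survivors is discarded and iteration stops with
the previous network. The floor mirrors the practice of screening down *to*
a key-target set of roughly the wanted size and never past it, and it is
the form used by the synthetic-recovery benchmark; `target_size` is the
form used when replaying a published trajectory whose final round lands
exactly on the wanted count.

## Enrichment

One-sided over-representation only. The p-value for overlap *k* between a
query of size *n* and a term of size *K* in background *N* is the
hypergeometric upper tail P[X ≥ k], evaluated in log space: each term
exp(lnC(K,i) + lnC(N−K,n−i) − lnC(N,n)) is max-shifted and summed with
compensated summation, so backgrounds of tens of thousands of genes do not
underflow. The background defaults to the union of all annotated genes in
the supplied collections (self-contained and reproducible) and can be
overridden with an explicit list; query and terms are restricted to the
background before testing, and this restriction is idempotent.

Gates follow the Metascape-style convention: overlap ≥ 3 and fold
enrichment (k/n)/(K/N) ≥ 1.5 inclusive, raw p < 0.01 strict. "Min
Enrichment" is taken to be this fold factor (Metascape's documented
convention). Benjamini–Hochberg q-values are computed per category over
*all* tested terms — not only gate survivors — and reported alongside the
raw p that drives the gate. Term counts from hosted platforms are not
reproduced: they depend on database snapshots; the statistics, not the
annotation content, are the contract here. No GO DAG redundancy collapsing
or term clustering is performed.

The test suite calibrates the test under a null query drawn uniformly from
the background. Because the hypergeometric tail is discrete, the achievable
rate of p < 0.05 sits strictly below 0.05; the calibration design uses
N = 2000, n = 500 and term sizes 600–1000, where the tail's probability
steps are ≈ 0.01 and the realized rate stays within three binomial standard
errors of the nominal level.

## Docking report

Units are kcal/mol throughout (AutoDock-Vina-style affinities; published
tables that mix "kJ mol" into running text while printing kcal/mol values
are treated as containing a units typo). Classification: energy ≥ 0
non-spontaneous; −5 < energy < 0 spontaneous but weak; energy ≤ −5 good
binder. The −5 boundary is assigned to the stronger class because the
convention is stated as "−5.0 or lower"; a strict flag moves exactly −5.0
to the weak class. The ranking is ascending by energy with ties broken by
(target, compound), a deterministic permutation of the input. Which
target–compound pairs were docked is an input, never computed.

## Synthetic benchmark

The generator emulates the data shapes the pipeline assumes, at roughly the
published scale with targets downscaled ~1:3 so 50 end-to-end runs finish
in seconds:

* **Compounds** — `n_herbs × compounds_per_herb` (default 6 × 7) records;
  each passes the OB/DL screen independently with probability
  `ob_pass_fraction` (default 0.5); passers draw OB ~ U(30, 100) and
  DL ~ U(0.18, 1), failers draw the failing coordinate(s) below the
  threshold. About 10% of compounds get a second herb attribution.
* **Compound-target map** — only passing compounds are mapped (mirroring
  maps built for active compounds). `n_hub_compounds` (default 5) planted
  hubs draw degrees from `hub_degree_range` (default 15–30), the rest from
  `background_degree_range` (1–5), over a pool of `n_targets` (150)
  symbols. Degree structure is planted by explicit range assignment, not
  preferential attachment: controllable ground truth beats realism for
  testing.
* **Disease lists** — five sources with default sizes (15, 120, 12, 43,
  20), the published source-size ranking scaled ~1:28. A planted common set
  of `disease_formula_overlap_fraction` (0.6) of the formula-target union
  is distributed so every common gene appears in at least one source; the
  remainder of each list is filled from disease-only symbols.
* **PPI graph** — over the common targets: intra-core pairs (core size 10)
  present with `p_core` = 0.9, core–periphery pairs with
  `p_core_periphery` = 0.1, periphery–periphery pairs with
  `p_periphery` = 0.02; scores uniform on 700–1000 so every edge passes the
  score gate. The periphery attaches preferentially to the core
  (Borgatti–Everett-style core-periphery structure); with
  periphery-periphery attachment alone, sparse periphery chains would carry
  the highest betweenness while intra-core nodes carry almost none, and the
  betweenness median would cut the planted core — the opposite of the
  structure the model is meant to plant.
* **Annotations** — four categories × 20 terms; the first 2 per category
  are planted (70% of their genes sampled from the common set), the rest
  sample the gene universe uniformly.

One integer seed drives a root stream with named substreams per artifact
(compounds, map, disease, ppi, terms), so adding a generator leaves the
others byte-identical. Identical config + seed ⇒ byte-identical bundles.

**What passing the benchmark shows — and does not.** Recovery of planted
hubs/core/terms shows the pipeline's ranking, screening and gating are
faithful to their definitions under clean, well-separated signal. It does
not show robustness to real data's features the generator deliberately
omits: realistic ADME value distributions, STRING score structure,
correlated annotation terms (GO DAG), symbol aliasing, or hub degrees that
arise from biology rather than planted ranges.

**Benchmark protocol** (frozen in the test suite after one calibration
run): 50 seeds (0–49); hub recovery = recall of the 5 planted hubs among
the top-5 degree-ranked compounds; core recovery = recall of the 10 planted
core nodes among the final screening survivors with `min_size = 10`; both
must average ≥ 0.9. Measured values are ≈ 1.00 and ≈ 0.97–0.99.

## Known limitations

* The closeness convention and the −5 kcal/mol boundary are configurable
  because published workflows are ambiguous on both; defaults follow the
  most common tool behaviour.
* Betweenness/closeness are unweighted; STRING scores gate edges but do not
  weight paths. No eigenvector/subgraph or other centralities.
* Full-scale reference counts (186/3701/131 targets, 172-node/293-edge
  network, the 122→43→20→9 screening trajectory) require the original
  database exports, which are not redistributable; the repository ships
  `configs/reference_replay.yaml` to replay them when those files are
  supplied, and records the expected values in its comments.
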