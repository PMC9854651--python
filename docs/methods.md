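# Methods

## Scope and model

`pigmentnet` implements a network-centric analysis of skin pigmentation
disorders in five connected stages.

**1. Diseasome curation.** Gene-disease association records from three
source tracks (a curated review, a literature appendix, and OpenTargets
genetic-association queries) are matched against an official gene-symbol
catalog; unmatched genes are removed and duplicate (gene, disease) pairs
are merged while recording all contributing sources. Disease identity is
the exact trimmed name string, so disease subtypes are distinct nodes.
Diseases carry one of four phenotype classes — hyperpigmentation (HYPER),
hypopigmentation (HYPO), mixed (MIXED), and pigmentation phenotype without
disease (PHENOTYPE). When sources disagree on a class the review
classification wins, then the appendix, then OpenTargets; the conflict is
logged. The diseasome is the bipartite graph with one link per curated
association. Genes are given a single network class: their unique disease
class, or MULTIPLE when their diseases span classes — a deliberate
single-label scheme so each protein has one category in downstream edge
statistics. Overlap between chosen diseases is summarized as exclusive
intersection ("upset") counts, which partition the covered genes by
construction.

**2. Confidence-filtered PPI network.** STRING-style scored edge tables
(combined confidence either in [0, 1] or as integer 0–1000, divided by
1000 on ingest) are filtered at an inclusive threshold of 0.700 ("minimum
required score" semantics) and induced on the disease proteins. Seeds
without a surviving edge are not network nodes but are reported as
unconnected; the connected fraction is the percentage of seeds that are
nodes, rounded half-up to an integer. Self-loops are dropped on ingest and
duplicate canonical pairs keep the maximum score (scored exports are
symmetric, and max is idempotent).

**3. Markov clustering.** MCL is implemented from scratch (dense NumPy):
the score-weighted adjacency gains a self-loop per node equal to its
maximum incident edge weight (configurable to a fixed 1.0) and is column
normalized; iterations alternate expansion (matrix squaring) and inflation
(entrywise power, default 2.5, then renormalization), with pruning of
entries below 1e-5 (each column's maximum is protected so no column can
vanish) and renormalization. Convergence is a maximum entrywise change
below 1e-6, capped at 200 iterations; non-convergence is flagged, not
fatal. Clusters are read from the limit matrix as the supports of attractor
rows (positive diagonal), with overlapping attractor systems merged so the
result is always a partition; unattached nodes become singletons. Clusters
are numbered 1..k strictly by decreasing size (ties by smallest member
symbol). Note that in the source analysis the cluster called "cluster 1"
(30 proteins) is not the largest by count; this package numbers strictly by
size and leaves the naming to the reader.

**4. Functional profiling and over-representation.** Each gene carries one
functional class per level of a three-level annotation (321 fine classes /
58 groups / 15 top-level groups, including "Unknown", which also absorbs
unannotated genes). Profiles report per-class counts and percentages for a
gene list. ORA uses the one-sided (upper-tail) hypergeometric test,
P(X ≥ k) for an overlap of k between an n-gene query and a K-gene term in
an N-gene universe, computed via `scipy.stats.hypergeom`; the universe
defaults to all annotated genes. Multiple testing is controlled with
Benjamini–Hochberg step-up adjustment (via `statsmodels`), significant
meaning adjusted p ≤ 0.05. Ranked-list (Kolmogorov–Smirnov style) GSEA is
deliberately out of scope: the usage here is unranked gene-set ORA.

**5. Expansion and LFQ overlay.** Expansion greedily grows the seed
network against a background interactome filtered at the same threshold:
at each step the non-member with the greatest summed score of
above-threshold edges to current members is added (ties: more edges, then
lexically smaller symbol), all above-threshold edges among members are
included, and growth stops at the first state whose realized edge count
exceeds the target. The greedy criterion is an interpretation — the
original interactive expansion tool does not document its ranking — and is
configurable to plain edge-count greedy. Added proteins are flagged and
classed NONE unless they are themselves disease genes. Edges are then
categorized by the unordered pair of endpoint classes; counts conserve the
edge total.

LFQ intensities (arbitrary units, one row per protein and cell line,
triplicate columns, 0 = not quantified) are summarized per protein: a
protein is detected in a line iff quantified in ≥ 2 of 3 replicates
(configurable); means are taken over quantified replicates only; for
proteins detected in both lines the fold change is max/min of the two
means and a protein is differential iff fold change is strictly > 2.
Proteins detected in one line only are flagged exclusive and excluded from
ratio calls. No replicate-level test statistic is applied — calls are by
fold change alone, matching the exploratory character of the analysis.
Log-transformed abundances (base 10) are attached to network nodes for
visualization; undetected means carry no log value rather than a
fabricated zero or −∞.

## Synthetic data: what it emulates and what it does not

All inputs can be simulated with planted structure
(`pigmentnet.simulate`). Defaults are fixed study-scale conditions:

- 174 diseases allocated 73/55/40/6 over the four classes by largest
  remainder (deterministic, so the partition is exact under every seed);
  per-disease gene counts 1 + Poisson(0.6) (≈ 278 associations); gene
  reuse probabilities 0.10 within class and 0.025 across classes, sized to
  give roughly 243 unique genes; a handful of catalog-absent records and
  duplicate-source pairs so curation is exercised.
- PPI: 4 planted modules of 10 disease proteins, within-module edge
  probability 0.9 with scores Uniform(0.70, 0.999), between-module 0.02
  with Uniform(0.15, 0.699) — the score bands deliberately straddle the
  0.700 threshold so filtering at 0.700 retains exactly the within-module
  edges; plus a 60-protein background interactome attached with
  high-confidence edges for expansion.
- Expression: log-normal base intensities (ln-scale mean 16, sd 1),
  triplicates with multiplicative noise exp(N(0, 0.1)), 10 proteins planted
  at 3-fold in the pigmented line, and a 5% replicate-wise dropout rate.

The generator emulates scale and planted signal, not biology: no degree
heterogeneity or hub structure in the PPI blocks, no evidence-channel
score combination, no intensity-dependent missingness or shared-peptide
effects in the LFQ tables, and functional classes are assigned uniformly
rather than coherently with the modules (except for the explicitly planted
GMT term sets). Passing tests therefore demonstrate correctness of the
counting, clustering, testing and overlay machinery under controlled
conditions — not recovery performance on real interactomes or real
proteomes. One consequence of realistic dropout worth knowing: a planted
differential protein that loses ≥ 2 replicates in a line is excluded from
ratio calls, so planted-recovery is exact over quantifiable proteins.

## Numerical and design choices

- Symbols are upper-cased and whitespace-stripped on ingest (official
  symbols are upper case); edge endpoints are stored lexically ordered.
- The SIF format cannot carry edge scores, so the SIF writer emits a
  companion `.edges.tsv`; round-trips through SIF+companion, GraphML and
  the node-attribute CSV preserve nodes, canonical edges and scores to six
  decimals.
- MCL pruning protects each column's maximum, guaranteeing column
  stochasticity (±1e-9) after every step; expansion power is fixed at 2.
- Percentages reported as integers use round-half-up.
- Rounding/tie-breaks make every stage deterministic: two runs of
  simulation plus pipeline under one seed/config are byte-identical.
- The reported run sizes (e.g. a 300-edge expansion target in the examples
  and acceptance script) are scaled to the synthetic background
  interactome; all thresholds (0.700, inflation 2.5, α 0.05, fold 2) are
  the analysis defaults.
- The source analysis's text once swaps the exclusive
  hyper-/hypopigmentation gene counts; the figure caption (68 hyper / 125
  hypo) is the consistent reading and the MULTIPLE/exclusive logic here
  follows it.

## Known limitations

- MCL is dense O(n³) per iteration — intended for networks up to a few
  hundred nodes, not whole interactomes.
- Disease-name normalization is exact trimmed match only; no fuzzy
  matching or ontology mapping.
- The expansion criterion approximates an undocumented interactive tool;
  different criteria can produce different added-node sets at equal edge
  targets.
- ORA assumes a single fixed universe and independence across terms; the
  BH control is over the tested term list only.
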