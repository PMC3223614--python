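# Methods

## Model and assumptions

`goclique` post-processes gene-set enrichment output. Its only inputs are a
binary category-by-gene incidence matrix (row *i* is the gene set of
significant category *i*), optionally a category-by-experiment FDR matrix,
and optionally a total-genes list. It does not recompute enrichment and does
not consult the GO graph: redundancy is defined purely by gene-set overlap,
so two categories that are distant in the ontology but annotate the same
genes will (correctly, for visualization purposes) be merged.

### Similarity

For categories with gene sets *A*, *B* in a universe of size *N*, the
similarity score is the one-tail Fisher's exact p-value
*p = P(X ≥ |A∩B|)*, *X* ~ Hypergeometric(*N*, |*A*|, |*B*|). The
over-representation tail is used because the metric must score *shared*
genes as similarity; the under-representation tail would invert the
semantics. The tail is computed exactly for every table size by summing
hypergeometric terms in log space (log-gamma factorials, max-shifted
summation); no normal or chi-square approximation is ever applied, which is
affordable because enrichment runs involve tens of categories and at most a
few thousand genes. The `n11 = 0` case returns exactly 1 (the tail is the
whole support). Pairwise p-values receive no multiple-testing correction:
the threshold is user-steered through the merged-pairs count, and the
p-values act as a similarity ranking, not as hypothesis tests.

Two universe modes exist: `changed` (default) uses exactly the genes of the
membership matrix — the only self-contained choice — while `all` uses a
supplied total-genes list that must be a superset. A single pooled universe
is used per run, including in default mode where one similarity matrix is
derived from the integrative membership matrix (gene-set overlap, never FDR
values, defines similarity).

### Threshold and graph

The stringency knob is the *nominal number of merged pairs* k: the cutoff is
the k-th smallest off-diagonal p-value, and all pairs with p ≤ cutoff become
edges. Ties at the cutoff are all admitted, so the achieved pair count can
exceed the nominal one (it is reported in the manifest). k = 0 yields a
cutoff of 0 and an edgeless graph, since every p-value is strictly positive.
A direct `--p-threshold` bypass exists; the two flags are mutually
exclusive.

### Clustering

Clusters are grown under complete linkage: starting from one singleton
cluster per category, each cluster absorbs any category adjacent to every
current member, iterated to a fixpoint, after which identical clusters are
merged and strict subsets pruned. Each surviving cluster is a maximal clique
of the category graph, the clusters cover all vertices, and a category may
appear in several clusters. Three choices here were genuinely open and are
fixed as follows:

* **Initialization** — one singleton per category. This guarantees vertex
  cover and lets every vertex seed its own clique, which is what produces
  multi-membership.
* **Iteration order** — vertices and clusters are always visited in
  lexicographic category-name order, making the output a deterministic
  function of the graph alone and invariant under input permutation. Greedy
  clique growth is order-dependent in general, so a different visit order
  (e.g. another implementation's) may return a different — equally valid —
  subset of the maximal cliques on ambiguous graphs.
* **Subset pruning** — a strict-subset cluster is an artifact of the growth
  schedule, not a maximal clique, and is removed.

The production path never enumerates *all* maximal cliques (that is
exponential in the worst case); Bron–Kerbosch enumeration via networkx is
used only as an independent oracle in tests and in `verify`, alongside a
structural checker (`verify_decomposition`) that asserts clique-ness,
maximality by neighborhood intersection, cover and subset-freeness.

### Collapse and naming

Membership rows are merged by the arithmetic mean (a cell becomes the
fraction of group members containing the gene); FDR rows by the
per-experiment minimum (a group is as significant as its best member).
Groups are numbered 1..K in canonical order (lexicographic member tuples).
The representative is the member with the smallest minimum FDR across
experiments when FDR data is present, else the lexicographically first
member; ties break lexicographically. Displayed labels use
`representative:N` for multi-member groups (singletons keep their bare
name); the full member concatenation lives in `groups.tsv` because
concatenated names of five GO terms are unreadable in a heatmap. The META
CIM contains only multi-member groups — singletons carry no grouping
information — and its columns reuse the global group indices so they
cross-reference the `:N` suffixes of the reduced CIM directly. When an
externally derived grouping is applied to another matrix (default mode),
members absent from that matrix are dropped from their group with a logged
warning and fully absent groups are omitted; a group degraded to one member
is displayed with its bare name. Each output row is computed over its own
group's members, so a category present in several groups contributes to
several rows and the reduced CIM may in principle have more rows than the
input had categories.

### Ordering and rendering

Reduced and META CIMs are ordered by agglomerative average-linkage (UPGMA)
clustering on Euclidean distances, per axis. Dendrogram leaf order is
underdetermined, so the deterministic rule "subtree containing the smaller
original index first" is applied. Rendering maps 0 to yellow and 1 to red
for membership-style values and uses a continuous perceptual colormap for
FDR matrices; only the metric and linkage are contractual, the pixel
aesthetics are not. An optional size filter can drop very large generic
categories (gene count above a cutoff) before analysis; it is off by
default.

## Synthetic data generator

The generator emulates the redundancy structure of real enrichment output:
`n_groups` planted groups of `group_size` categories each share a group
core of `core_genes_per_group` genes; cores are pairwise gene-disjoint so
the ground truth is unambiguous and recovery can be scored by exact set
equality. Each planted category additionally switches on each non-core gene
with probability `jitter`; `n_background` independent categories are drawn
at `background_density` (re-drawn if empty). FDR values are uniform in
[0, 0.1] — uniformly significant — because the pipeline only min-pools them.

Defaults (chosen once, to match the scale of typical post-enrichment runs:
tens of categories, low-hundreds of genes): 120 genes, 4 groups × 3
categories, 8-gene cores, jitter 0.02, 10 background categories at density
0.05, 3 experiments. What the generator does **not** emulate: the GO DAG
(real redundancy is partly hierarchical and cross-group overlaps are
common), correlated gene membership, or realistic FDR structure. Passing
recovery tests therefore demonstrates the overlap→clique→collapse machinery,
not performance on any particular annotation release.

## Numerical and degenerate-input choices

* Fisher tails match exact rational enumeration to ≤ 1e-10 relative error
  over every feasible table with universe ≤ 60 (measured ~1e-13).
* TSV round trips are bit-exact for binary matrices and to 1e-6 per cell for
  real-valued ones (6 written decimals); tabs and decimal points only, no
  locale handling.
* Empty category rows, cells outside {0,1}, FDR outside [0,1], duplicate or
  empty labels are rejected at load with the offending coordinate named.
* One category: similarity is refused ("nothing to compare"). Edgeless
  graph: all singletons, reduced CIM equals the input, META CIM is empty
  (and renders nothing). Complete graph: one all-category group.
* An all-singleton run has compression ratio 1.00; zero output rows is an
  error.

## Problem sizes used in checks

The test-suite and acceptance-script workloads are sized for a laptop-class
single core: the exhaustive Fisher sweep covers all 631,655 feasible tables
with universe ≤ 60 (a few seconds), clique validation uses 200 random
graphs with ≤ 12 vertices across an edge-density grid, planted recovery
uses 50 seeds at zero jitter and 25 seeds per point on the jitter grid
{0, 0.02, 0.05, 0.1}, and the end-to-end synthetic run uses the generator
defaults (22 categories × 120 genes).

## Known limitations

* Greedy clique growth returns one deterministic clique cover, not a
  canonical or minimum one; on graphs with many interlocking cliques other
  covers exist, so exact group counts are reproducible only under this
  package's visit order.
* The clique count in the worst case grows exponentially with the merged-
  pairs level; the intended regime (tens of categories) keeps this trivial.
* Heatmap byte-determinism holds for a fixed matplotlib version only.
* Legacy enrichment-tool file dialects are not parsed; inputs must be in the
  canonical TSV formats described in the README.
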