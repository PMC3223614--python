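# goclique

De-replicate redundant functional categories in gene-set enrichment results.

## The problem

Gene Ontology (GO) enrichment of an expression experiment typically returns
dozens of significant categories, many of which are near-duplicates: almost
the same genes map to *cell adhesion*, *biological adhesion*, and half a
dozen of their relatives. The resulting clustered image map (CIM — a heatmap
of categories versus genes, or categories versus experiments) is cluttered
with rows that carry the same information. `goclique` merges those redundant
categories into de-replicated groups **after** enrichment, tuned to the
experiment at hand, instead of relying on a static pre-computed GO slim.

## The method

1. **Similarity.** For every pair of significant categories *A*, *B* with
   gene sets drawn from a universe of *N* genes, compute the one-tail
   (over-representation) Fisher's exact p-value of their overlap:
   *p = P(X ≥ |A ∩ B|)* with *X* hypergeometric given |A|, |B| and *N*.
   Small *p* means the two categories share far more genes than their sizes
   predict. Because the test conditions on both set sizes, two large dense
   categories do not look similar unless their overlap is genuinely
   surprising. The universe is either the genes mapped to at least one
   significant category (`changed`, the default) or a user-supplied total
   gene list (`all`).
2. **Thresholding.** The user picks a *nominal number of merged pairs* k;
   the p-value cutoff is the k-th smallest pairwise p-value (ties admit all
   tied pairs). Pairs at or below the cutoff become edges of an undirected
   category graph.
3. **Clustering.** Starting from one singleton cluster per category, each
   cluster repeatedly absorbs any category connected to *every* current
   member (complete linkage), iterated to a fixpoint, then deduplicated and
   pruned of strict subsets. Each surviving cluster is a maximal clique of
   the graph; every category is covered, and a category may belong to
   several clusters — that multi-membership is biologically meaningful and
   is the method's signature feature.
4. **Collapse.** Each cluster becomes one row of the reduced CIM: membership
   rows are averaged, FDR rows take the per-experiment minimum. Merged rows
   are labelled `representative:N` (the member with the smallest FDR, or the
   lexicographically first). A binary **META CIM** (categories × groups)
   records which categories went into which multi-member group.
5. **Ordering.** Rows/columns are ordered by average-linkage (UPGMA)
   hierarchical clustering on Euclidean distances and can be rendered as
   PNG heatmaps (0 yellow → 1 red for membership values).

## Worked example

Simulate a dataset with 4 planted groups of 3 near-identical categories
(no noise), then run the pipeline asking for 12 merged pairs — the number of
within-group pairs:

```sh
goclique simulate --out demo --jitter 0 --n-background 0 --seed 17
goclique run --membership demo/membership.tsv --fdr demo/fdr.tsv \
             --merged-pairs 12 --out demo/out
```

which logs

```
INFO threshold p<=1.19011e-12, achieved pairs=12
INFO done: 12 categories -> 4 groups (compression 3.00)
```

The 12 requested pairs translate into a p-value cutoff of about 1.2e-12
(identical 8-gene categories in a 120-gene universe overlap this
improbably by chance), and the 12 categories collapse into exactly the 4
planted groups — a compression ratio of 3.00. `demo/out/groups.tsv` lists
each group's representative and members:

```
index	representative	members
1	grp01_cat1	grp01_cat1,grp01_cat2,grp01_cat3
2	grp02_cat3	grp02_cat1,grp02_cat2,grp02_cat3
...
```

and `demo/out/meta_cim.tsv` is the binary categories-by-group META CIM
(here one 1 per row; with overlapping cliques a category shows a 1 in each
group it joined). `reduced_cim.tsv`, `reduced_fdr.tsv`, `similarity.tsv`
and `manifest.json` (all parameters, achieved pairs, compression ratio)
complete the output; `--render` adds heatmap PNGs.

`goclique default-run` derives one clustering pattern from an integrative
matrix and applies it consistently to any number of individual matrices;
`goclique verify` re-checks that the decomposition is a valid maximal-clique
cover.

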