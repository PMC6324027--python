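# orthohier

Bottom-up hierarchical orthology construction for comparative microbial
genomics.

Comparative databases face a scaling dilemma: genomes of the same
species keep accumulating, yet each new strain adds little new gene
repertoire, and a "standard" cross-range ortholog table built from one
representative genome per genus silently drops every gene the
representatives happen to lack (sporadically distributed genes such as
toxins are the classic casualty). `orthohier` implements the stepwise
alternative: build ortholog tables from the bottom up, collapsing each
level into a *pan-genome* of representative sequences so that the
top-level table covers the entire gene repertoire while the expensive
sensitive comparisons run only between compact pan-genomes.

The pipeline:

1. **Within species.** For each species with at least two genomes, run a
   fast (k-mer-seeded) all-against-all Smith–Waterman search and cluster
   the genes into a within-species ortholog table. Collapse the table to
   a species pan-genome: one representative gene segment per cluster,
   named `taxid:clustid`. Single-genome species pass through as raw
   genomes.
2. **Within genus.** Repeat over the species-level units of each genus
   to get within-genus tables and genus pan-genomes.
3. **Between genera.** Run the sensitive (full local alignment) search
   over the genus pan-genomes and cluster them into the standard
   ortholog table covering the whole taxonomic range.

Clustering is domain-aware: a gene whose hits fall into two
well-separated regions is split into domain segments that cluster
independently, so gene fusions land in both parent families instead of
corrupting one. Members are annotated as *fusion*, *fission* or
*outlier*; representatives are chosen among unflagged members with
length closest to the cluster median, so a pan-gene is structurally
typical of its group. Any high-level cluster can be *expanded* back to
every underlying gene, with domain boundaries mapped through the
representative alignments (missing positions filled by linear
interpolation) — expansion of the full standard table reproduces the
input gene set exactly.

On top of the tables the package derives per-column conservation ratios
(fraction of a genus' species carrying a cluster), extracts universally
conserved one-to-one core genes (eliminating gene-poor organisms when a
broad table leaves too few), and builds a concatenated-alignment
neighbor-joining phylogeny with a built-in progressive aligner.

A synthetic-data module generates genomes evolved along a known species
tree with gene gain/loss, duplication, fusion and fission, so the whole
toolkit is testable end to end without downloading anything.

## Worked example

```bash
orthohier simulate --seed 1 --out demo/data \
    --genera 2 --species 2 --genomes 2 --families 20
orthohier build-hierarchy demo/data --out demo/build
orthohier expand --build demo/build --genomes demo/data --cluster 00001
orthohier core-tree --build demo/build --genomes demo/data \
    --out-dir demo/tree --min-core 10
```

which prints (abridged):

```
simulated 8 genomes, 156 genes -> demo/data
4 species tables, 2 genus tables, 20 standard clusters -> demo/build
gene_id          domain_index  begin  end  organism
g01s01n01x00001  1             1      226  g01s01n01
g01s01n02x00001  1             1      226  g01s01n02
...
17 core clusters, alignment width 4211, tree -> demo/tree/tree.nwk
```

The 8 genomes carry 156 genes (20 families minus stochastic losses,
plus duplicates); the build produces a within-species table per
two-genome species, one within-genus table per genus, and a standard
table whose 20 clusters match the 20 simulated families. Expanding
cluster `00001` lists every raw gene of that family with its domain
coordinates, and the core-tree step aligns the 17 universally conserved
one-to-one families into a 4211-column concatenated matrix whose NJ
tree reproduces the simulated species tree.

The same steps are available as library calls
(`orthohier.simulate`, `orthohier.build_hierarchy`,
`orthohier.expand_cluster`, `orthohier.core_gene_tree`); see
`docs/methods.md` for the model and every tunable parameter.

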