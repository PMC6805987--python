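# stemwall

Expression-context profiling and context-based orthology for cell-wall
gene families in developing grass stems.

## The problem

Grasses build type II primary cell walls (glucuronoarabinoxylan-rich, little
pectin or xyloglucan), yet their genomes carry near-complete complements of
the genes for every wall polysaccharide. Whether a family member acts during
cell elongation (primary wall) or during secondary wall thickening cannot be
read off sequence similarity alone — grass genomes are heavily duplicated,
and whole subgroups (CslF, CslH) have no eudicot counterpart while others
(CslB) are eudicot-only. `stemwall` implements the analysis that resolves
this from stem internode RNA-seq: in a developing maize stem, lower
internodes 4 and 5 have stopped elongating and are depositing secondary
walls, while upper internodes 6 and 8 are still elongating (internode 7 is
excluded after housekeeping-gene QC). Comparing transcript abundance between
these two zones assigns each gene a developmental context, and sharing that
context with the closest *Arabidopsis* homolog — not similarity alone — is
the criterion for putative orthology.

## The method

For each gene, raw counts are scaled to reads per 20 M library reads.
Reads that map exactly to two duplicated loci are split between them
(evenly, by default). Three inclusive thresholds tier the genes:

* detected in an internode at ≥ 1 read per million (20 per 20 M);
* **expressed** if the normalized counts summed over the four internodes
  reach 95 per 20 M;
* **ratio-evaluable** at 500 per 20 M, qualifying the gene for the
  expression ratio

  `R = (n4 + n5) / (n6 + n8)`

  with `R ≥ 2` → **secondary** wall association, `R < 1` → **elongation**
  (primary wall), and `1 ≤ R < 2` → **transitional**.

Family structure comes from bootstrapped neighbor-joining trees
(Saitou–Nei on p-distances with pairwise gap deletion; 1,000 column
resamples by default). Genes are assigned to subgroups by their smallest
well-supported clade containing labeled anchor genes; clades lacking every
member of a species are flagged (the grass-only CslF/CslH pattern). A maize
gene's closest *Arabidopsis* homolog (maximum alignment identity) is a
*putative ortholog* when its annotated wall context (primary/secondary)
matches the maize gene's expression class; transitional maize genes are
reported as indeterminate. Family summaries count total, expressed, and
per-class genes — class counts cover only ratio-evaluable genes, so they can
sum to less than the expressed count.

A synthetic-data module generates aligned families with known subgroup
structure, duplicate pairs with ambiguous read counts, and internode count
profiles with known classes, so the whole chain is testable end to end
without any download.

## Worked example

```
$ stemwall simulate --outdir demo --n-families 2 --genes-per-family 8 --seed 42
fixture written to demo
$ stemwall profile --indir demo --outdir demo_out --n-reps 100 --seed 42
12 genes called; 2 family rows; outputs in demo_out
putative orthologs among secondary-class genes: 0/1 = 0.000
$ stemwall summarize --indir demo --outdir demo_sum --seed 42
fam1    6(6)    2       3       1
fam2    6(5)    4       1       0
```

The summary lines read: family, total genes (expressed genes), then counts
of elongation / transitional / secondary genes among the ratio-evaluable
ones. `demo_out/calls.tsv` holds the per-gene detail, e.g.

```
gene             n4      n5      n6       n8       tier             ratio   wall_class
zm_fam1_sg1_1_1  208.6   245.3   1181.5   1127.6   ratio_evaluable  0.197   elongation
zm_fam1_sg2_1_1  2712.4  1877.9  537.6    1386.0   ratio_evaluable  2.386   secondary
```

`zm_fam1_sg1_1_1` is five-fold stronger in the elongating internodes
(ratio 0.197 < 1 → elongation/primary wall); `zm_fam1_sg2_1_1` is more than
two-fold stronger in the secondary-wall internodes (2.386 ≥ 2 → secondary).
`demo_out/fam1.nwk` carries the bootstrapped family tree,
`fam1.subgroups.tsv` the anchored clade assignments, and
`orthologs.tsv` the per-gene context-match verdicts.

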