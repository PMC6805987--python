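# Methods

This note records the models, defaults, and numerical decisions behind
`stemwall`, and what the synthetic fixtures do and do not establish.

## Expression model

Counts come as raw unique reads per gene per internode, for internodes
4, 5 (post-elongation, secondary-wall forming) and 6, 8 (elongating).
Internode 7 is an input-level exclusion (it failed upstream housekeeping
QC); the container rejects any other internode label, including i7.

**Normalization.** Values are scaled linearly to reads per 20 M library
reads (`raw × 2e7 / library size`). The expression ratio is computed on
normalized values; with equal library sizes this reduces to the raw-count
ratio. The 95 and 500 thresholds are applied to the **sum** of normalized
counts over the four internodes — "from the four internodes" is read as an
aggregate criterion, which also keeps the hierarchy 20 (detection) < 95
(expression) < 500 (ratio evaluation) coherent. Whether the original
criteria were applied to raw or normalized sums is not documented; we
normalize first, and likewise split ambiguous reads before normalizing.

**Ambiguous reads.** Reads mapping exactly to two duplicated loci are
split 50/50 between the pair (fractional halves carried downstream); a
proportional-to-unique-counts split is available behind a flag. Pairs only,
never triples. Per-internode totals are conserved exactly.

**Thresholds and boundaries.** All tier boundaries are inclusive: a summed
95 per 20 M is expressed, 500 is ratio-evaluable. Class boundaries follow
the quoted criteria exactly: ratio ≥ 2 secondary, < 1 elongation, [1, 2)
transitional (so 1.0 is transitional, 2.0 secondary). A zero denominator
with positive numerator yields +infinity, classified secondary and logged
as degenerate; 0/0 cannot occur for a ratio-evaluable gene. All thresholds
live in a `Thresholds` dataclass and are configurable; the defaults are the
published values.

## Phylogeny

**Distances.** p-distance with pairwise deletion: differing residues over
columns where neither sequence is gapped. A pair with no comparable columns
gets distance 1.0 with a warning. The original trees were built inside
ClustalW, whose distance correction is unspecified; p-distance is
transparent and exactly testable, and identity (1 − p-distance) doubles as
the closest-homolog score. This also replaces the original BLAST
expect-value ranking for closest homologs — a documented divergence.

**Neighbor joining.** Standard Saitou–Nei agglomeration. Determinism: among
Q-minimizing pairs, the lowest (row, column) pair in the current working
order is joined. Negative branch-length estimates are clamped to zero with
the deficit moved to the sister branch, preserving the pair's summed
length. The output is unrooted (trifurcating root node). On additive
matrices the algorithm is exact, which the tests verify against generated
trees (the construction is the oracle) and cross-check against an
independent implementation (scikit-bio).

**Bootstrap.** Columns resampled with replacement; every replicate runs the
full p-distance + NJ path; an internal edge's support is the percentage of
replicates containing the same leaf bipartition. Default 1,000 replicates
(tests use 25–100 to stay fast). Bipartitions are canonicalized by the side
not containing the lexicographically smallest leaf.

**Subgroup assignment.** A non-anchor gene takes the label of the smallest
bipartition side that contains it and at least one anchor, *restricted to
sides whose edge support meets `min_support`* (default 50%); if the anchors
in that side carry mixed labels, the gene is unassigned. We filter by
support before minimizing size rather than after: NJ routinely produces
near-zero-length edges (e.g. at the root trifurcation) whose arbitrary,
weakly supported splits would otherwise veto genes that sit inside a
perfectly supported subgroup clade. Anchors always keep their own label.
When a species map is supplied, each subgroup is checked for species with
no member (the grass-only CslF/CslH versus eudicot-only CslB pattern).

## Orthology by context

A ratio-evaluable maize gene and its closest reference homolog are a
putative ortholog pair when maize class elongation meets reference context
primary, or secondary meets secondary. Opposite contexts are a mismatch.
Transitional maize genes yield "indeterminate": the source analysis calls
such genes homologous but stops short of orthology, and forcing either
verdict would over-read the evidence. Reference wall contexts are an input
annotation (established *Arabidopsis* discriminations), never recomputed.
`ortholog_fraction` reports numerator and denominator and can include or
exclude indeterminate verdicts from the denominator, since there is no
single defensible convention for where transitional genes belong.

## Family summaries

One row per family: total genes, expressed genes, and elongation /
transitional / secondary counts **among ratio-evaluable genes only**. The
restriction is forced by the published table's own arithmetic (rows exist
whose class counts sum to less than the expressed count — exactly the genes
between 95 and 500 per 20 M). Global totals equal column sums; genes with
calls but no annotation land in an "unannotated" overflow row with a
warning.

## Synthetic data

The generator emulates the study conditions, not real sequence data.

* **Families.** Each family splits into `max(2, genes_per_family // 4)`
  subgroups. Sequences evolve by per-site substitution (uniform replacement
  among 20 residues) from a family root: long edges (5 × `mutation_rate`,
  capped at 0.45) separate subgroup founders, anchor genes evolve from
  their founder at `mutation_rate`, and each maize gene evolves from a
  designated anchor at `mutation_rate / 3`, making the designated reference
  the recoverable closest homolog. The guide tree mirrors this process
  exactly and uses multifurcations wherever children evolved independently
  from one sequence — a forced binary resolution would claim splits no
  substitution supports. Join orders are shuffled per seed. The last
  subgroup of each family omits the reference species (grass-only pattern);
  it remains anchored by the second anchor species.
* **Duplicates.** A `dup_fraction` (default 0.25) of maize genes get a
  near-copy partner (rate `mutation_rate / 6`), grafted as a sister leaf.
  Partners share the true class; a fixed `ambiguous_fraction` (default 0.3)
  of the pair's reads per internode — drawn equally from both members — is
  emitted as ambiguous pair counts, so unique counts plus half the pair
  counts reconstruct each gene's simulated total exactly.
* **Counts.** Negative-binomial with variance `μ + φμ²` (default
  `φ = 0.05`); `φ = 0` is the deterministic limit (rounded means). Expected
  per-20M means encode the class: secondary genes have lower-internode
  means `effect_size` (default 4) times the upper ones, elongation the
  reciprocal, transitional a per-gene ratio uniform in (1, 2), and
  not-expressed genes a summed expectation (~40 per 20 M) safely below the
  95 threshold. Base expression is uniform in 300–2,000 per 20 M per upper
  internode, which keeps every expressed gene ratio-evaluable. Rounded
  means are clamped into the gene's own class band so that the noise-free
  limit classifies every gene correctly by construction; the realized
  expected ratio (after rounding) is written back into the truth table.
  Library sizes default to four values near 20 M (21.0, 19.0, 20.5,
  18.5 M); exact-equality tests use equal 20 M libraries, where counts
  equal their integer means.
* **Ortholog wiring.** Each reference anchor's wall context agrees with the
  class of its first directional (elongation/secondary) maize copy with
  probability `ortholog_concordance` (default 0.25, the observed share of
  secondary-wall maize genes with same-context *Arabidopsis* homologs taken
  as the study condition). Anchors with no directional copies get a random
  context. Because several maize genes can share one anchor, and genes in
  the reference-absent subgroup have no designated reference at all, the
  pipeline-level secondary-class ortholog fraction sits above the
  configured concordance; tests therefore check verdict correctness
  gene-by-gene against the truth table and the concordance rate within a
  binomial band on the designated-reference subset.

**What the fixtures do not show.** Replicate-free pooled libraries, real
residue substitution processes (no rate heterogeneity, no indels beyond
none at all — alignments are gapless), genomic multi-mapping beyond exact
two-locus pairs, and real between-gene expression correlation are all out
of scope. Passing tests demonstrate the pipeline's arithmetic and recovery
behaviour under the stated generative model, not performance on real
RNA-seq. The default dispersion is a free parameter chosen for realistic
overdispersion, not an estimate from data (the original study pooled
replicates before sequencing, leaving no variance information).

## Problem sizes

Tests and the acceptance script use sizes chosen to exercise every code
path while staying quick: 8-taxon matrices (100 draws) for the NJ oracle,
100 bootstrap replicates, 3-family fixtures for tree recovery, and 23
families × 12 genes (≥ 200 count-profiled maize genes) for class-recovery
rates. The pipeline default of 1,000 bootstrap replicates applies when the
CLI is run without overrides.
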