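# Methods

## Data model

The human side of the pipeline starts from *association records*: one row
per publication × gene × disease term, with a curated flag stating whether
the study found the gene positively associated (Y), not associated (N), or
made no determination (blank). Disease terms come from a controlled
vocabulary and may be absent. Only records that are both positively
associated and term-annotated enter the analysis; everything else is
treated as noise the filter must remove. Analysis is at the gene level
only — variant- and polymorphism-level information is out of scope.

The mouse side starts from gene–phenotype annotations: one row per gene ×
Mammalian Phenotype (MP) code, derived from individual mutant or knockout
models. These carry no replication semantics: a count attached to a mouse
(gene, phenotype) pair is a structural multiplicity of annotation rows,
never evidence strength, and the package treats it accordingly.

Human gene symbols are uppercased during counting; mouse symbols keep
their case. Cross-species joins are made explicitly through a
(mouse symbol, human symbol) ortholog table, never by symbol coincidence
(a case-insensitive fallback exists behind a flag, off by default, for
users without a map).

## Summaries, gene sets, distances

Co-occurrence counting produces per-gene summaries (a gene's terms with
counts, declining) and per-term summaries (a term's genes with counts).
The two are exact transposes; the package enforces this with a duality
invariant (identical (gene, term, count) triples) and a conservation
invariant (counts sum to the number of filtered records). Each record
contributes one count even if a publication appears twice; collapsing
duplicate (publication, gene, term) rows is available behind a flag since
curated archives do not document their own convention. Ties at equal
count order alphabetically, purely for determinism.

A disease term whose genes with count ≥ `min_count` number at least
`min_size` becomes a gene set. `min_count` defaults to 1 (any positive
association admits a gene); `min_size` defaults mirror the common 3-gene
and 10-gene cutoffs used when drawing large dendrograms. The distance
between sets is 1 minus the overlap coefficient (intersection over the
smaller set). Properties the tests rely on: symmetry, zero diagonal,
range [0, 1], invariance under relabeling genes, and zero exactly when
the smaller set is nested in the larger. The triangle inequality can fail
on subset chains; none of the downstream methods require it. Jaccard and
Dice variants exist only behind an explicit flag.

Pathway-level comparison projects a gene set onto the labels of
annotation sets (a GMT collection) sharing at least `k` genes with it
(default 1). This replaces an external enrichment service with a
transparent overlap rule: `k` is an explicit stand-in for an enrichment
cutoff, not a statistical test, and no p-values are computed.

## Trees

`nj_tree` is the standard Saitou–Nei neighbor-joining: Q-criterion
agglomeration with the classic limb-length and matrix-reduction updates,
finishing with the three-taxon closed form. On additive matrices it
reproduces the generating tree exactly (topology and all pairwise
distances), which the suite checks on hundreds of random binary trees.
Ties in the Q minimum join the pair whose clusters contain the
lexicographically smallest leaf labels; since the Q matrix can carry a
one-ulp asymmetry from float summation order, it is symmetrized with an
elementwise min before the argmin.

Tree fit is scored by the weighted least-squares criterion
Σ n (D − d)² / max(D, ε)^P over unordered leaf pairs, with P = 2
(Fitch–Margoliash weighting) or P = 0 (unweighted), and n a uniform
per-pair replicate count defaulting to 1. The ε floor (default 1e-6)
exists because duplicate or nested gene sets legitimately produce observed
distances of exactly 0, and P = 2 divides by D². Branch lengths on a
fixed topology are fitted by weighted linear least squares on the
pair-path incidence system; a rank-deficient system (degenerate topology)
raises rather than returning arbitrary lengths. Negative branch lengths —
a normal NJ artifact on non-additive matrices — are kept by default and
flagged with a warning at serialization.

A full topology search under the criterion is deliberately not attempted:
at hundreds of gene sets it is computationally prohibitive, and the
criterion's scoring semantics are preserved by evaluating it on NJ-proposed
or user-supplied topologies. Stability is assessed instead by re-running
NJ under seeded random permutations of the input order and comparing
replicates by Robinson–Foulds distance (symmetric difference of
non-trivial bipartitions; a replicate count of 100 is the CLI default).

## Ward clustering

Gene sets are vectorized as binary membership rows over the sorted union
universe. The inter-cluster distance is
D_KL = ‖x̄_K − x̄_L‖² / (1/N_K + 1/N_L), the between-cluster ANOVA sum of
squares, equal to the increase in within-cluster sum of squares caused by
the merge. The merge loop updates distances with the Lance–Williams
recurrence for Ward's method (O(n²) memory, no centroid recomputation);
the tests verify the recurrence against the direct centroid formula at
every step and the full merge sequence against a brute-force
implementation that recomputes within-cluster sums of squares from the
definition.

Two numerical choices matter. Equal-height ties merge the pair with the
smallest (min node id, max node id); and tie *detection* treats heights
within relative 1e-9 as equal, because mathematically identical heights
can differ in their final float bits between the recurrence and the direct
formula. For binary data at small n the heights are rationals with small
denominators whose genuine gaps are far larger than 1e-9, so the tolerance
cannot conflate genuinely different heights at the scales the package
clusters. Feature vectors are unweighted memberships by default — a
count-weighted variant is available behind `allow_nonbinary=True` — and
the cluster count k at cut time is a user parameter; the package does not
attempt automatic model selection.

## Synthetic data

The generator emulates the structure of a curated association archive
with planted ground truth. K groups own disjoint pools of
`core_genes_per_group` genes; each term draws each core gene of its group
with probability `p_in` and each background gene (genes in no core) with
probability `p_bg`. Every drawn (gene, term) pair is emitted r times,
r ~ Zipf(`count_law`, default exponent 1.5, capped at 100), matching the
heavy-tailed replication pattern of real summaries; `count_law=None`
forces r = 1 for degenerate-parameter tests. Signal records are flagged
Y; distractor records with random gene–term pairs and N/blank flags are
appended so Y records make up `frac_flag_Y` of the table (negative
reports are separate publications — they do not erase positive ones), and
`frac_mesh_missing` of records lose their term. Defaults
(frac_flag_Y = 0.26, frac_flag_N = 0.03, frac_mesh_missing = 0.06) give a
table in which roughly 29% of records carry a flag and roughly a quarter
are positive with an annotation, the gross proportions of the emulated
archive. The default structural parameters (5 groups × 8 terms, 30-gene
cores, p_in = 0.6, p_bg = 0.02, 600 genes) are the planted-recovery study
conditions; a `small` preset (4 groups × 5 terms, 15-gene cores, 300
genes) keeps end-to-end CLI runs fast.

The mouse generator emits an MP-style ontology (one root, class-level
parents, one leaf code per phenotype) plus a gene–phenotype report using
the same planted logic without replication. Orthology is the case
transform Gene#### ↔ GENE#### over a seeded `coverage` fraction of genes,
so expected cross-species row counts are computable exactly.

What the generator does *not* emulate: real archives have correlated
publication behavior (hot genes attract studies across many diseases),
hierarchical disease vocabularies, non-disjoint disease etiologies, and
symbol aliasing/curation errors. Passing the planted-recovery tests
therefore demonstrates that the pipeline's machinery recovers group
structure present as gene sharing; it does not certify performance on the
messier dependence structure of literature data.

## Problem sizes and determinism

The validation suite runs at desk scale by design: 200 random trees of
5–12 leaves for NJ consistency, 50 random instances for the
least-squares-fit oracle, 100 binary matrices of ≤ 7 rows for the Ward
brute-force oracle (the oracle is exponential in spirit and cubic in
practice, so small n is where it is trustworthy), 1000 small record
tables for duality, and 20 simulation seeds × 40 terms for planted
recovery. All randomness flows from explicit integer seeds through
numpy Generators; fixed seeds give byte-identical outputs, including
Newick serializations.

## File formats

Record tables and phenotype reports are tab-delimited with a header row
and order-free, name-addressed columns (delimiter and column names
configurable) — disease terms contain commas and parentheses, so
comma-delimiting is never the default. The OBO reader consumes only id,
name and is_a; dangling parents are kept as codes without entries. GMT
lines are label, description, members. The PHYLIP writer emits the square
dialect; labels that exceed the classic 10-character limit (most disease
names do) are replaced by stable unique tokens with a `<path>.names`
sidecar mapping tokens back to full labels, which the reader applies
transparently. Newick output quotes labels containing spaces or
punctuation and writes lengths at fixed precision (default 6 decimals);
parsing goes through dendropy and collapses a degree-2 root so trees stay
unrooted. All round trips are lossless on valid inputs and are property-
tested as such.

## Known limitations

- The Fitch–Margoliash criterion is evaluated, never globally optimized;
  reported trees are NJ topologies with (optionally) LS-refitted lengths.
- Cluster count k and dendrogram cut criteria are user choices; the
  package offers no automatic selection.
- Mouse phenotype counts are structural, so mouse analyses are unweighted
  regardless of the `min_count` machinery available on the human side.
- Cross-species rows pair term *lists*, not term meanings: no semantic
  matching between human disease vocabulary and MP terms is attempted.
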