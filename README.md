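# phenoshare

Gene-sharing analysis of disease and phenotype gene sets.

Common complex diseases are highly pleiotropic: the same genes turn up in
association studies of related — and sometimes surprisingly unrelated —
disorders, and the same mouse genes produce overlapping mutant phenotypes.
`phenoshare` turns curated association records (one row per publication ×
gene × disease term, flagged Y/N for a positive or negative finding) and
mouse gene–phenotype annotations (Mammalian Phenotype ontology codes) into
*disease gene sets*, and then asks how diseases relate to each other purely
through the genes they share: no imposed hierarchy, no ontology-driven
grouping — only gene overlap.

It is aimed at researchers who want to compare disease phenotypes within
and across species through literature-scale genetic evidence: building
per-disease gene sets, drawing dendrograms of hundreds of diseases,
clustering them, and joining human disease genes with mouse phenotype genes
through an ortholog map.

## The method

1. **Filter and count.** Keep records that are positively associated (Y)
   *and* carry a disease-term annotation. Count co-occurrences of each
   (gene, term) pair; sorting counts in declining order per gene gives the
   GENE→disease summaries, and the exact transpose gives the DISEASE→gene
   summaries.

2. **Gene sets and distances.** Each disease term with at least
   `min_size` genes becomes a gene set `C_k` with `N(C_k)` members. The
   distance between two sets is one minus the overlap coefficient:

       d_ij = 1 − |C_i ∩ C_j| / min(N(C_i), N(C_j))

   0 for identical (or nested) sets, 1 for disjoint ones. It is a
   dissimilarity, not a metric — which is all the downstream methods need.

3. **Dendrograms.** Neighbor-joining (Saitou–Nei) builds an unrooted tree
   over the gene sets; on an additive matrix it reproduces every pairwise
   distance exactly. Fit quality on any topology is scored by the weighted
   least-squares criterion

       Σ_pairs n (D − d)² / D^P

   where `D` is the observed distance, `d` the tree path distance, `n` the
   replicate count per pair (1 in the simple case), and `P` the weighting
   power: 2.0 for the Fitch–Margoliash weighting, 0.0 for the unweighted
   variant. A full topology search under this criterion is combinatorially
   prohibitive at hundreds of gene sets, so `phenoshare` evaluates the
   criterion and fits optimal branch lengths on NJ-proposed (or
   user-supplied) topologies, and assesses stability with randomized
   input-order NJ replicates compared by Robinson–Foulds distance.

4. **Ward clustering.** Gene sets are vectorized as binary membership
   vectors over the union gene universe and clustered agglomeratively under
   Ward's minimum-variance criterion, with inter-cluster distance

       D_KL = ‖x̄_K − x̄_L‖² / (1/N_K + 1/N_L)

   — the increase in within-cluster sum of squares caused by merging K and L.

5. **Cross-species comparison.** Per-gene human summaries and per-gene
   mouse phenotype summaries are joined through a (mouse symbol, human
   symbol) ortholog table, yielding one row per orthologous pair with
   evidence in both species.

A synthetic-data generator plants known disease-group structure (disjoint
core gene pools shared within groups, Zipf-distributed replication counts,
configurable flag/annotation noise) so the whole pipeline can be validated
end to end without any database access.

## Worked example

Four disease gene sets, each holding the eight most-replicated genes of a
disease (three transcribed cardiovascular lists plus an illustrative
respiratory one):

```python
import phenoshare as ps
from phenoshare.io_formats import newick_string

hyp  = ps.GeneSet("Hypertension",
                  frozenset({"ACE","AGT","NOS3","CYP11B2","GNB3","ADD1","AGTR1","ADRB2"}))
mi   = ps.GeneSet("Myocardial Infarction",
                  frozenset({"NOS3","ACE","SERPINE1","ITGA2","LPL","APOE","GP1BA","F7"}))
cor  = ps.GeneSet("Coronary Disease",
                  frozenset({"ACE","NOS3","PON1","APOB","APOE","LPL","AGT","SERPINE1"}))
asth = ps.GeneSet("Asthma",
                  frozenset({"ADRB2","IL13","CD14","IL4R","CCR5","TNF","IL13RA1","CHI3L1"}))

coll = ps.GeneSetCollection([hyp, mi, cor, asth])
m = ps.distance_matrix(coll)
print(m.values)
tree = ps.nj_tree(m)
print(newick_string(tree))
print(ps.fm_criterion(tree, m, ps.FMConfig(power_P=2.0)))
```

prints

```
[[0.    0.75  0.625 0.875]
 [0.75  0.    0.375 1.   ]
 [0.625 0.375 0.    1.   ]
 [0.875 1.    1.    0.   ]]
(Asthma:0.593750,('Coronary Disease':0.156250,'Myocardial Infarction':0.218750):0.218750,Hypertension:0.281250);
0.0062
```

Hypertension and myocardial infarction share exactly {ACE, NOS3} of their
eight genes, so their distance is 1 − 2/8 = 0.75; myocardial infarction and
coronary disease share five genes (0.375) and sit as neighbors in the tree,
while asthma — sharing at most one gene with the cardiovascular sets — hangs
off the longest branch. The criterion value 0.0062 (P = 2) says the
four-leaf tree reproduces the six observed distances almost exactly. Ward
clustering of the same collection merges the two coronary sets first and,
cut at k = 2, separates cardiovascular from respiratory:

```python
M, genes = ps.membership_matrix(coll)
dend = ps.ward_cluster(M, labels=coll.labels)
print(ps.cut_dendrogram(dend, 2))   # [0, 0, 0, 1]
```

The same analysis runs from the shell:

```
phenoshare simulate --preset small --seed 7 --out-dir sim/
phenoshare summarize --records sim/records.tsv --axis by_term --out by_term.tsv
phenoshare genesets  --summary by_term.tsv --min-size 3 --gmt-out sets.gmt
phenoshare distance  --gmt sets.gmt --matrix-out D.phy
phenoshare tree      --matrix D.phy --reps 100 --seed 17 --newick-out trees/
phenoshare cluster   --gmt sets.gmt --k 4 --out clusters.tsv
```

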