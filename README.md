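# halocog

Comparative-genomics toolkit for prokaryotic genome collections:
construction of clusters of orthologous genes (COGs) with iterative
paralogy-aware refinement, selection of universal marker genes into a
concatenated supermatrix, maximum-likelihood reconstruction of gene gain
and loss histories on a species tree, and extraction of clade-specific
gene signatures. A ground-truth synthetic evolution simulator makes every
stage testable at desk scale, without downloading genome databases.

It is aimed at microbial comparative genomicists who want the standard
"cluster → markers → supermatrix → gain/loss → signatures" workflow as a
single reproducible, scriptable package, and at methods developers who
need a simulator with known cluster memberships and event histories to
validate such workflows.

## The models

**Clustering.** Proteins are compared all-vs-all by local alignment
(BLOSUM62, gap open/extend 11/1) behind a shared-k-mer prefilter; hits
require fractional identity ≥ 0.5 and bidirectional coverage ≥ 0.5.
Greedy longest-centroid clustering seeds the clusters, which are then
refined for up to five rounds: cluster profiles displaying full-length
similarity are merged; each multi-member cluster gets a neighbour-joining
gene tree (distance −ln identity), midpoint rooted; and the tree is
recursively parsed into subtrees maximising

    ratio(S) = coverage(S) / paralogy_index(S) = |genomes(S)|² / |S|,

splitting off a clade only when both it and its complement improve on the
current ratio. This separates paralogous subfamilies while keeping
orthologous sets intact.

**Supermatrix.** Markers are clusters present in every genome with at
most 4 extra paralogs in total; one index ortholog per genome is chosen
by BLOSUM62 score against the cluster consensus; columns are filtered by
gap fraction (≤ 0.667) and consensus-normalised homogeneity (≥ 0.05),
then concatenated with a partition map for external ML tree inference.

**Gain/loss.** Presence/absence of each gene family evolves along the
rooted species tree as a two-state Markov chain with gain rate *g* and
loss rate *l* per unit branch length; for a branch of length *t* with
*r = g + l*, P(0→1) = (g/r)(1−e^(−rt)) and P(1→0) = (l/r)(1−e^(−rt)).
Family likelihoods come from Felsenstein pruning (conditioned on the
family being observable in ≥ 1 genome), rates are fitted by bounded ML
with the root prior at stationarity, presence posteriors come from the
up-down recursion, and a gain (loss) is called on an edge when the
posterior increases (decreases) by more than 0.5. Summing posteriors over
families gives expected ancestral genome content at every node.

## Worked example

```python
from halocog import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo", seed=7, n_genomes=10, n_families=20,
                     clade=["G0001", "G0002"])
report = run_pipeline(cfg)
print(report["stages"]["clustering"]["n_clusters"],
      report["stages"]["clustering"]["adjusted_rand_vs_truth"])
print(report["stages"]["supermatrix"])
print(report["stages"]["gainloss"]["n_gains"],
      report["stages"]["gainloss"]["n_losses"])
```

prints

```
18 1.0
{'n_markers': 9, 'n_columns': 1080, 'columns_removed': 0}
1 8
```

meaning: the 20 simulated families yielded 18 non-singleton clusters that
reproduce the true families exactly (adjusted Rand index 1.0; the
remaining families surface as singletons), 9 of them qualify as universal
single-copy markers giving a 1080-column supermatrix with no columns
removed by filtering, and the gain/loss reconstruction calls 1 gain and
8 losses on the species tree. The same run writes per-genome FASTA, the
species tree, cluster membership, the supermatrix (FASTA/PHYLIP +
partitions), per-node posteriors, event calls, ancestral content and
clade signature tables under `demo/`, all byte-reproducible under the
same configuration.

The equivalent shell interface:

```
halocog run --outdir demo --seed 7        # full pipeline, defaults
halocog simulate --n-genomes 10 --seed 7 --outdir sim
halocog gainloss --matrix sim/true_matrix.tsv \
                 --tree sim/species_tree.nwk --outdir gl
```

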