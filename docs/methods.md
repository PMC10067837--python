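# Methods

This note records the models implemented in `halocog`, the choices made
where the design was genuinely open, and what the synthetic validation
does and does not demonstrate.

## Synthetic evolution model

The simulator generates the three objects every downstream stage needs —
a species tree, a gene-content history, and protein sequences — with the
full event history retained as ground truth.

**Species tree.** A Yule process: starting from two lineages, a
uniformly chosen lineage splits until the requested number of genomes is
reached. Every branch length is drawn independently from an Exponential
distribution with mean 0.1, giving a 20-leaf tree a total length around
3.8 and leaf-to-leaf paths mostly below ~3. Leaves are labelled
`G0001…`, internal nodes `N1…` in preorder; the whole tree is a pure
function of `(n_genomes, seed)`.

**Gene content.** Each family is present at the root with probability
`root_presence_prob`. Along a branch of length *t* a present family is
lost with probability 1−e^(−l·t); an absent family is gained with the
two-state-chain probability (g/(g+l))(1−e^(−(g+l)·t)). Families absent
from every leaf are unobservable — real cluster construction requires
members — so they are dropped from the matrix and reported in a counter;
this is exactly the ascertainment the gain/loss module corrects for.
Note the loss probability is the pure-death form rather than the
two-state entry (l/r)(1−e^(−rt)); at the branch lengths used here the
two differ by ~g·t/2 (a couple of percent), which is visible as a small
upward bias in fitted loss rates and is well inside the validation
tolerances.

**Duplications** add Poisson(dup_rate·t) extra copies and are applied on
terminal branches only, to families present at both ends of the branch.
This is a deliberate simplification: it makes every duplication event
correspond to exactly one extra copy in exactly one genome (so the truth
bookkeeping identity "duplication events = Σ(copy count − 1)" holds
exactly), while still producing the multi-copy clusters that paralogy
parsing needs. Internal-branch duplications inherited by several
descendants are not modelled.

**Sequences.** One root sequence per family, uniform over the 20 amino
acids. Per site, along a branch of length *t*, a residue is substituted
with probability 1−e^(−d·t) by a uniformly chosen different residue
(*d* = `within_family_divergence`; a 20-state Jukes–Cantor-like model
with no rate heterogeneity). Every family carries a latent sequence at
every node, evolved along the whole tree; a lineage that regains a
family emits that latent sequence. This keeps within-family divergence a
function of tree distance alone and avoids an arbitrary re-seeding rule
for gains. Paralogs re-evolve independently from the sequence at the top
of their terminal branch. Between unrelated families the expected
identity is the 1/20 background.

**What the simulator does not emulate:** realistic amino-acid
composition, codon/GC structure, indels (all family members have equal
length, so alignment columns are trivially homologous), rate variation
across sites, domain-level homology between families, and horizontal
transfer between contemporaneous lineages (gains are branch-local state
flips). Consequently, passing the cluster-recovery tests shows the
pipeline machinery is correct under clean identity contrast; it does not
show robustness to domain sharing, fragmented gene calls, or
composition bias found in real proteomes.

## Clustering

* **Similarity search**: exact local alignment (biotite, BLOSUM62, gap
  open 11 / extend 1). A hit requires identity ≥ 0.5 over aligned
  columns and alignment span ≥ 0.5 of both sequences, mirroring the
  `--min-seq-id`/coverage semantics of fast clustering tools. A
  shared-k-mer prefilter (k = 5, ≥ 1 shared k-mer) limits which pairs
  are aligned; tests verify the prefilter changes nothing on simulated
  data, and `prefilter=False` forces the exhaustive search.
* **Greedy clustering**: proteins sorted by descending length (ties by
  id); the longest unassigned protein becomes a centroid and absorbs its
  unassigned hits. Singletons are excluded from the cluster set but kept
  in a side list for ortholog-coverage accounting.
* **Cluster alignment**: center-star progressive alignment (center = the
  member with the highest summed pairwise score), merged under
  once-a-gap-always-a-gap. An `aligner` hook accepts an external MSA
  tool; the internal aligner keeps the test suite dependency-free.
* **Profile merging**: cluster profiles are columns of residue
  frequencies; the column-pair score is f_aᵀ·B62·f_b and profiles are
  aligned globally with a linear gap penalty of 5. Two clusters merge
  when the alignment covers ≥ 0.8 of both profiles with a mean
  aligned-column score ≥ 0.5; connected components merge together. The
  span threshold operationalises "full-length similarity"; both numbers
  are configurable because no canonical values exist.
* **Gene trees**: neighbour joining (scikit-bio) on d = −ln(max(identity
  over shared non-gap columns, 0.01)); negative NJ branch lengths are
  clamped to zero. A `tree_builder` hook accepts an external
  (approximate-ML) program.
* **Midpoint rooting** is implemented in-package: the longest leaf-leaf
  path (ties: lexicographically smallest endpoint pair) is found
  explicitly and the root inserted at its midpoint. The bundled
  `root_at_midpoint` of the tree library mishandles the two-leaf case,
  and refinement needs a deterministic tie-break.
* **Subtree parsing**: for a leaf set S define ratio(S) = |genomes(S)|²/|S|
  (taxonomic coverage over paralogy index). A clade is split off when
  both it and its complement strictly improve the current ratio; among
  admissible cuts the one maximising the smaller part ratio wins (ties:
  larger clade, then smallest leaf label); recursion continues on both
  parts. The recursion and tie-breaks are this package's construction —
  the objective fixes what is optimised, not the search — and an
  exhaustive single-cut search bounds its behaviour in the tests. One
  consequence worth knowing: for a fused pair of families where one
  family lacks several genomes, a balanced impure cut can legitimately
  score above the clean separation; exact family recovery is implied by
  the objective only for full-complement families.
* **Refinement** iterates align → merge → tree → parse until a round
  performs zero merges and zero splits, capped at 5 iterations (the cap
  also breaks the rare merge/split oscillation the objective permits).
  Alignments are cached by member set, so converged rounds are cheap.
* **AAI** between two genomes is the mean percent identity over mutually
  non-gap MSA columns of their index orthologs, across all shared
  clusters.

## Supermatrix

Markers must contain every genome with total extra copies ≤ 4
("additional paralogs" read as a total across genomes; a per-genome
reading is available via `per_genome=True`, since the source phrasing
supports either). The index ortholog per genome maximises the summed
BLOSUM62 score against the cluster consensus (majority residue, ties
alphabetical; gap columns contribute nothing; ties between paralogs go
to the smallest protein id).

Column homogeneity is defined here as the consensus-normalised mean
substitution score: h = mean over non-gap residues r of
B62(r, c)/B62(c, c) for consensus residue c, giving 1.0 for a pure
column, ~0 for unrelated residues, and slightly negative values for
anti-conserved columns — a scale on which the 0.05 threshold is
meaningful. This formula is a documented surrogate: the filtering
convention it reproduces states its thresholds (gap fraction 0.667,
homogeneity 0.05) but not the formula, so both the formula and
thresholds are configurable. Columns are filtered per marker on the
index-ortholog sub-alignment, then concatenated in sorted cluster order;
partition intervals are 0-based half-open in memory and written 1-based
inclusive in the RAxML-style partition file. Species-tree ML inference
itself is out of scope: the supermatrix is written as FASTA and relaxed
PHYLIP for external tools, and the internal NJ tree can stand in for
testing.

## Gain/loss reconstruction

A single global (gain, loss) pair with the root prior fixed at the
stationary distribution g/(g+l); mixture/rate-variation extensions were
considered and deliberately left out — the per-edge posterior-difference
rule, which is the part downstream analyses consume, is preserved
exactly. Copy counts are binarised at ≥ 1; duplications are not part of
this model.

* Likelihood: Felsenstein pruning, vectorised over families, with
  per-node scaling (no underflow at extreme rates). Unique patterns are
  collapsed with multiplicities before optimisation.
* Ascertainment correction (on by default, toggleable): the likelihood
  is divided by 1 − P(absent in every leaf), matching the simulator's
  dropping of unobservable families.
* Fitting: L-BFGS-B on (ln g, ln l) bounded to [−6, 6], deterministic
  start g = l = 1. With all-present data the loss rate runs to the lower
  bound, with a warning.
* Posteriors: up-down (outside) recursion; leaf posteriors equal the
  observations; node posteriors are invariant to the likelihood scaling.
* Event calls: gain if P(child) − P(parent) > 0.5, loss if < −0.5 —
  strictly greater, so a change of exactly 0.5 is not called. Any call
  necessarily flips the >0.5 presence state across its edge; note that
  full gain/loss alternation along a path is only guaranteed when
  posteriors never drift across 0.5 without a call, which holds in
  sparse-event regimes but not universally.
* Ancestral content: Σ over families of P(present at node), reported raw
  and rounded.

## Signatures

Pure set queries on the binarised matrix: clade core (present in every
clade genome), clade-specific gains (core ∩ absent outside), and
clade-specific absences of common genes, where "common" defaults to
present in ≥ 2/3 of the outgroup — a threshold chosen here because the
source convention leaves it unspecified; it is configurable. Ortholog
coverage counts a genome's clustered proteins whose cluster reaches a
designated reference genome set, over clustered + singleton proteins.

## Numerical and reproducibility choices

* All randomness flows from integer seeds through `numpy` generators;
  separate streams (seed, 1) and (seed, 2) decouple content from
  sequence simulation so changing one stage cannot reorder another's
  draws.
* Deterministic tie-breaks throughout: lexicographic protein/cluster
  ids, sorted genome orders, explicit midpoint and cut tie-breaks; no
  iteration over unordered sets reaches an output file.
* Midpoint placement tolerates 1e−12 numerical slack; the two root-side
  path halves agree to < 1e−9 by construction.
* Tabular outputs carry `#` headers with the tool version, a hash of the
  scientific parameters (output paths excluded), and the seed. FASTA and
  Newick are written headerless so standard parsers consume them
  unchanged. Wall time appears only in `report.json`, keeping all data
  files byte-identical across reruns.
* Validation problem sizes: exhaustive likelihood checks on trees of 2–6
  leaves over all 2^n patterns; rate recovery and event detection on
  5,000 families × 20 genomes; cluster recovery on 20 genomes × 50 and
  × 500 families. These sizes give tight binomial error bars while
  keeping the whole suite a desk-scale run.

## Known limitations

* The profile merge step scores frequency vectors without position
  weighting or secondary structure, so it is blunter than HMM-HMM
  comparison on remote homology.
* The center-star aligner is adequate for the simulator's indel-free
  families; real data should use the external-aligner hook.
* Single global gain/loss rates; no per-family or per-branch rate
  variation, no stochastic mapping of event counts.
* The subtree-parsing objective can prefer impure cuts for families with
  patchy genome complements (see above); this is a property of the
  objective, not of the search.
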