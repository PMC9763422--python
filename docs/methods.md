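# Methods

## Coordinate system and data model

All profiles index into a `BinnedGenome`: a 0-based, half-open BED-style
tiling of each chromosome into fixed-width windows (1 Mb for bulk
SNP-array-grade profiles, 5 Mb for shallow scWGS). The last bin of a
chromosome is the remainder and may be shorter. Missing bins are rejected
on ingest rather than imputed: upstream CN callers emit complete per-bin
calls, and any imputation rule would be invented biology.

The chromosome-count estimate of a profile is the sum over chromosomes of
the mean CN of that chromosome's bins, so a uniformly diploid genome of K
chromosomes scores exactly 2K. Bins count equally within a chromosome by
default (remainder bins are not down-weighted — at genome scale bins are
near-uniform and the simple mean is reproducible without a length table);
`length_weighted=True` switches to a base-pair-weighted mean. Sex
chromosomes are ordinary chromosomes; no ploidy special-casing.

Clonal proportions are reported as percentages rounded half-up to one
decimal, matching how such counts are conventionally quoted.

## Clonal decomposition

Cells are embedded with t-SNE (perplexity 30, Euclidean metric on the CN
vectors, PCA initialization, fixed seed — determinism is required for
testing; at least `3 x perplexity` cells are demanded as a guard).
Spectral clustering then partitions the 2-D embedding; a flag allows
clustering the raw CN matrix instead. The affinity is an RBF kernel with
width `gamma = 1 / Var(X)` (total variance): t-SNE coordinates have an
arbitrary scale, and a fixed-width kernel or a sparse k-NN graph can
disconnect when a tight clone collapses to a near-point, which silently
breaks the spectral embedding. When the cluster count is not supplied it
is chosen by the eigengap heuristic on the normalized Laplacian of the
same affinity, over k in [2, 12] — the same range a practitioner would
scan for a handful of clones.

Cluster profiles are per-bin means over member cells; integer character
states for the phylogeny are the half-up rounding of those means (a fixed,
testable rule; 2.5 rounds to 3). As an independent cross-check of the tree
groupings, cluster profiles can be agglomerated under the Canberra
distance (sum_i |x_i − y_i| / (|x_i| + |y_i|), 0/0 terms = 0) with
complete linkage; on clean fixtures the closest Canberra pair coincides
with the closest Mb-metric pair.

## Segment merging

Adjacent bins where every cluster keeps a constant state are merged into
maximal segments (a breakpoint wherever *any* cluster changes, plus
chromosome boundaries), so merged segments remain vertically comparable
across clusters. Segments with identical states across all clusters are
then discarded: they carry no heterogeneity and cannot affect the tree.
Merging is lossless for the Mb metric — distances computed on the merged
table equal the bin-level recomputation for every cluster pair, because
filtered segments contribute zero by construction. This is asserted
exactly in the tests.

## Maximum-parsimony phylogeny

Characters are the merged segments; states are non-negative integer copy
numbers; the tree is rooted at a fixed copy-number-neutral diploid anchor
(state 2 on every segment). The default criterion is *unordered*
(Fitch-like): any state-to-state change costs 1, i.e. the score counts
state changes. A *Wagner* mode (cost |ΔCN|) is available behind a flag for
sensitivity analysis; magnitude-weighted costs change optima exactly where
multi-copy jumps occur (a 2→4 change costs 1 vs 2), and the unordered
reading is the default because the criterion is a count of changes.

The search is exact. Topologies over the cluster leaves are enumerated by
sequential leaf insertion (every rooted binary topology once); each is
scored by Sankoff dynamic programming vectorized across segments, with the
anchor's state fixed at 2. Up to 7 leaves the enumeration is exhaustive
((2n−3)!! ≤ 10395 topologies); above, branch-and-bound prunes insertion
branches whose partial-tree score already exceeds the best complete score
(valid because parsimony score is monotone under leaf addition), seeded
with a greedy stepwise-addition upper bound. Equal-score ties are kept and
broken by the lexicographically smallest canonical leaf-label sequence.
Beyond 12 leaves the search refuses with a clear error — the intended
instances have at most ~8 clusters per passage, and correctness is
preferred over heuristics. Internal states come from the Sankoff
backtrace, top-down; among minimum-cost states the one nearest the parent
state is chosen, then the smallest — deterministic, and biased toward
gradual change.

Edge lengths are genomic, not change counts: the summed `length_bp` of
segments whose state differs across the edge, divided by 1e6 (megabases).
A cluster's distance to the root is the path sum of edge lengths. Trees
serialize to Newick with Mb branch lengths and internal-node labels.

### Late-passage attachment

Late clusters do not enter the search; they are attached greedily. Early
and late cluster profiles are re-segmented jointly so their state vectors
are comparable. Set A holds unplaced late clusters, set B the placed leaf
clusters; each iteration attaches the globally minimal-distance pair
(x ∈ A, y ∈ B), making x a daughter of y with edge length d(x, y), and
moves x to B. Ties take the smallest (x label, y label). B contains
leaves only — internal nodes are inferred ancestors, not observed
clusters, so an observed late cluster should pair with an observed
cluster. The early tree's topology, states and edge lengths are never
modified by attachment; attached leaves carry their states on the joint
segmentation (`joint_table` / `joint_states` on the returned tree), since
a per-early-segment state need not be constant over a refined joint
segment. Early *internal* states are not re-expressed on resurrected
segments (segments invariant among early clusters but variable once late
clusters arrive): they are not needed for leaves-only attachment, and
forcing them would conflict with the fixed all-2 root.

## Culture shift

The per-bin delta track is `late − early` on population-averaged profiles.
Two Mb summaries are shipped because a real-valued averaged profile admits
more than one defensible rule: `span` counts a bin's full length once
|delta| exceeds the threshold (default 0.5 copies — a majority of cells
shifted); `copyweighted` (the default, threshold 0) weights each bin's
length by the copy change, so partial clonal takeovers contribute
proportionally. Swapping the passages swaps gains and losses exactly, and
span totals are monotonically non-increasing in the threshold.

## Gene dosage

RPKM = count / (total reads in millions) / (gene length in kb). The
per-gene fold change log2((RPKM_A + c)/(RPKM_B + c)) uses a pseudocount
c = 0.1 to guard silent genes; the symmetric form keeps
log2FC(A,B) = −log2FC(B,A). Genes map to the 1 Mb bin containing their
start coordinate (the simplest deterministic rule; overlap-weighting would
change little at 1 Mb against typical gene sizes), and bins average their
genes' fold changes unweighted; empty bins are NaN and are dropped
pairwise before correlation. The CN track is log2((CN_A + ε)/(CN_B + ε)),
ε = 0.1 copies, on the same bins. The Pearson r and its two-sided p (t
transform, n − 2 df) are reported with the bin count used; a zero-variance
track raises instead of returning NaN. GSEA is not reimplemented — a
ranked (gene, log2FC) list is exported for pre-ranked GSEA tools.

## Synthetic data

The generator emulates the features the analysis relies on, with defaults
chosen to mirror the study conditions it stands in for:

- **Clones** are a tree of whole- and partial-chromosome events (signed
  integer copies) on a diploid baseline; realization applies events along
  the tree and rejects negative copy numbers.
- **Cells** draw a clone per passage-specific proportions (e.g. a minor
  clone at 8.7% of 705 early cells expanding to 40.7% of 744 late cells),
  then add "intermittent" sub-clonal noise: independent per-(cell, bin)
  ±1 flips at rate 0.05 by default. This is the simplest model that
  reproduces scattered single-cell gains/losses; a Poisson read-count mode
  (`noise_model="poisson"`) is available but not default.
- **Expression**: genes are placed uniformly over the genome; per sample,
  log2 RPKM = baseline + coefficient × log2(CN/2) + N(0, σ), with per-gene
  baselines (mean 5, sd 1 in log2 RPKM) shared between samples so the fold
  change isolates the dosage term. `calibrate_noise_sd` solves σ in closed
  form for a chosen population-level bin correlation r, from the variance
  of the log2 CN-ratio track and the mean genes-per-bin
  (r = c·sd(x) / sqrt(c²var(x) + 2σ²/g)).
- The default demo genome is 6 chromosomes of 100–250 Mb at 5 Mb bins
  (200 bins) — small enough for fast, deterministic tests while keeping
  whole- vs partial-chromosome structure; an hg19 length table is included
  for realistic-scale runs.

All generators are reproducible from (spec, seed).

What passing tests on this generator show — and what they do not: the
noise model is independent across bins and cells, with no GC/mappability
waves, no amplification artifacts, no doublets, and no segmentation error
correlation; expression noise is i.i.d. normal in log space with no
trans-regulation structure. Recovery results here therefore demonstrate
the correctness of the algorithms under the stated model, not their
robustness to every artifact of real scWGS or RNA-seq data.

## Problem sizes and numerical choices

The shipped verification runs use 705/744-cell mixtures on the 200-bin
demo genome, 30–50 random parsimony instances of 4–7 leaves × 10 segments
(states 0–5), and a 2500-bin × 25 000-gene dosage simulation — sizes at
which the exhaustive search remains an oracle for branch-and-bound while
the whole suite completes in about a minute. Percentages are rounded
half-up to one decimal; integerization of mean profiles is half-up; all
tie-breaks (topology, internal states, attachment order) are documented
deterministic rules, so repeated runs are bit-identical.

## Known limitations

- Cluster-level trees only: no per-cell phylogenies, no allele-specific
  CN, no SNVs, no likelihood/Bayesian models or bootstrap support.
- The exact search refuses above 12 leaves by design.
- The eigengap choice of k can be fragile when clone sizes are extremely
  unbalanced or clones differ by very few bins; k can always be set
  explicitly.
- Attachment assumes the late clusters descend from (or alongside) placed
  clusters; a genuinely novel late clone still attaches to whatever is
  closest.
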