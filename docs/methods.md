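# Methods

`bidcg` implements an iterative two-way (coupled) biclustering procedure for
gene-expression matrices, built on an ultrametric clustering engine driven by
regulated random walks (a DCG-style "data cloud geometry" tree). This note
records the model, the numerical choices, and what the synthetic benchmarks
do and do not demonstrate.

## The clustering engine: regulated walks on a potential graph

Given items with pairwise distances `d(i,j)`, the engine treats the data as a
weighted graph whose edge potential is `d(i,j)^p` (default `p = 2`, the heat
kernel; `p = 1` gives a plain exponential kernel). At temperature `T` a
Markov walk moves from `i` to `j` with probability proportional to
`exp(-d(i,j)^p / T)`. Row-stabilisation (subtracting each row's minimum
off-diagonal potential inside the exponent, which cancels under
normalisation) keeps low temperatures numerically meaningful instead of
underflowing.

The walk is *regulated*: a node is retired once it has been visited
`removal_threshold` times (default 5), and the walk continues on the
remaining nodes until all are retired. At trapping temperatures the walk
empties one potential well before escaping to the next, so the removal order
is well-contiguous and the waiting times between removals (recurrence times)
spike when a fresh well is entered. Each walk is segmented at those spikes;
spikes are detected with a minority-constrained two-group variance split
(1-D Otsu) over the recurrence times, excluding the first removal (warm-up,
not escape) and requiring the two groups' means to differ by a factor of 3.

`walks_per_temp` walks (default 40) are aggregated into a co-occurrence
matrix: the fraction of walks in which two items fall into the same segment.
Cluster count and membership are read off this ensemble by average-linkage
clustering of `1 - co-occurrence`. Candidate cuts are restricted to merge
heights of at least `1 - theta` (default `theta = 0.45`: clusters must
disagree in a majority of walks) and to at most 20 clusters; runt clusters
(single items) are absorbed into their highest-affinity sibling. A
candidate is only eligible if its silhouette on the *original* distances
clears `silhouette_floor` (default 0.1) — a free high-temperature walk
dilutes co-occurrence uniformly and must read as one cluster. Among
eligible candidates the one that best fits the walk evidence itself (the
silhouette on the co-occurrence dissimilarities) is selected, so a
better-separated coarse reading cannot shadow genuine fine structure at a
low temperature. The winning membership is then polished by reassigning
each item to its nearest cluster in mean distance (two synchronous
rounds), which repairs the "straggler" artefact in which outlying items
retired in walk tails co-occur into phantom groups.

Temperatures form a geometric grid of `n_temps` points (default 15) between
`0.1 x` the 5th and `2 x` the 95th percentile of the positive pairwise
potentials. The cluster-count profile `K(T)` is median-smoothed over three
points; every maximal plateau yields a candidate tree level, whose
membership comes from the plateau-averaged ensemble. Candidate levels are
screened (frozen-regime fragmentation with more than `n/2` blocks is
discarded; levels whose silhouette falls below 80% of the best
level's are dropped; near-identical partitions, adjusted Rand index > 0.9,
are deduplicated onto the better-separated one) and assembled into a chain
of strictly decreasing block counts. Nestedness is enforced finest-first:
the finest level is kept verbatim and each coarser level is rebuilt as the
majority-vote grouping of the finer blocks, which lets fine-scale evidence
correct stray coarse assignments. Plateau-onset temperatures become the
level heights; they induce an ultrametric (height of the lowest shared
block, zero within the finest level). If the coarsest retained level is not
a single block, a closing root is appended above the grid so every pair has
a finite ultrametric height.

All randomness flows from one seed; identical inputs and seed give identical
trees.

## The iterative two-way loop

Rows are genes, columns are samples (conditions). The loop maintains a
collection of sample classes, seeded either by user labels (supervised) or
by the best-separated level (highest silhouette) of a DCG-tree over the
samples on all genes. For each class `C`:

1. a tree over **all genes** is built with features restricted to the
   columns of `C`;
2. every proper block of that tree with at least `min_gene_group_size`
   genes is a candidate subgroup `g`; for each, a tree over **all samples**
   is built with features restricted to `g`;
3. the pair `(g, b)` is accepted as a bicluster if the sample tree contains
   a branch `b` aligned with `C` — at least `branch_purity` (default 0.5)
   of `b`'s members belong to `C`, `b` is a proper subset of the samples of
   size at least `min_branch_size`, and, when `coverage_fraction` is set,
   `b` covers that fraction of `C`. Among qualifying branches the one
   sharing the most samples with `C` wins (ties to the purer, then the
   larger). Accepted rectangles must additionally be *active*: mean
   expression inside must exceed the matrix grand mean, the gene group's
   mean over the remaining columns, and the branch's mean over the
   remaining rows. Without this filter the branch test also accepts
   complement groups (e.g. all background genes of a class, which isolate
   it by their shared silence); it can be disabled
   (`require_elevated=False`) when down-regulated signatures matter.

After a full sweep, near-duplicate pairs (gene- and sample-Jaccard both
above 0.9) are merged, and rectangles competing for the same cells (overlap
of at least half the weaker's cells) are resolved in favour of the higher
contrast (inside mean minus the larger outside mean), then the larger.
Classes for the next sweep are the accepted branches themselves — which may
overlap, as overlapping modules require — plus unions of branch pairs that
share samples or genes (widening probes: a probe spanning more than one
module yields no coherent gene group and dies out), plus the initial blocks
of any unclaimed samples. The loop stops when the accepted collection is
stable between sweeps, after `max_sweeps` (default 10), or when the fit's
work budget is spent (`max_tree_work`, the sum of item counts squared over
all trees built, default 1e6 ~ one hundred 100-item trees — noisy inputs
can otherwise keep proposing fresh probe classes indefinitely); hitting a
limit is reported, never raised. Candidate gene groups smaller than the
rank-correlation minimum, and feature subsets whose restricted profiles
are constant under Spearman, are skipped with a log entry rather than
raised mid-loop. Gene- and sample-axis trees are cached by
feature subset, and per-tree seeds are derived deterministically from the
run seed and the subset identity, so results are independent of visiting
order and reproducible.

Orientation is symmetric: `orientation="genes"` transposes the matrix,
swaps the two metrics, and swaps the axes back in the result.

## Distances

Euclidean distance is the default on both axes and is used for all
synthetic benchmarks. The Spearman distance `1 - rho_s` (Pearson
correlation of average ranks) is provided for real expression data, where
only the monotone shape of a profile is trusted; constant restricted
profiles raise an error rather than silently scoring zero. The
`(1 - rho)/2` variant can be obtained by halving, and a Pearson mode is
deliberately not offered as a first-class metric.

## Synthetic benchmarks

The generator plants `n_modules` transcription modules — a set of genes
regulated by one transcription factor crossed with the conditions in which
that factor is active — along the diagonal of an activation x regulation
design; consecutive modules share `overlap` genes and `overlap` conditions.
Defaults mirror the classic benchmark layout: 10 modules of 10 genes x 5
conditions (100 x 50 matrix) for the noise studies, and 10 modules of
10 x 10 with overlap up to 8 (a `(100-9d) x (100-9d)` matrix) for the
overlap studies.

Two renderings are produced. *Constant*: binary, 1 inside any module.
*Additive*: background cells are uniform integers on [0, 9], module cells
are 10 plus a uniform integer on [0, 9], and the matrix is rescaled by the
difference of the two means (10), so the mean module-over-background
contrast is exactly 1 — the same contrast as the constant rendering. The
shared Gaussian-noise axis (sd 0 to 0.6) therefore perturbs both renderings
comparably; rescaling by the maximum instead would halve the additive
contrast and make the two noise axes incommensurable. Cells belonging to
two modules are drawn once (membership union), preserving the guarantee
that every module cell exceeds every background cell before noise. Noise is
added element-wise to the whole matrix, after rescaling.

The generator emulates planted block structure with homoscedastic Gaussian
noise only. It does not emulate intensity-dependent variance, missing
spots, probe effects, or realistic class imbalance, so passing benchmarks
demonstrates correct recovery of planted structure under the stated noise
model — not performance on raw microarray data.

## Match scores

Relevance and recovery are average best-match Jaccard scores between the
found and the true collections: relevance averages, over found biclusters,
each one's best Jaccard match among the truths; recovery swaps the roles.
Matching is on gene sets by default; a cell-set mode (gene x sample
rectangles) is provided, and sample-set collections are scored by placing
sample sets in the gene-set role. An empty found collection reports zero
with a logged note.

Where a count of "correctly identified" modules is needed, found
biclusters are assigned one-to-one to true modules greedily by gene-set
Jaccard; exact identification demands Jaccard 1.0, and identification under
heavy overlap uses 0.5 (an output must cover its module at least as well as
the module's own neighbours do).

## Known limitations

- At high noise on the additive rendering (sd around 0.4, i.e. noise
  comparable to 40% of the module contrast) the full-feature pairwise
  distances on either axis retain almost no class signal (true-partition
  silhouette about 0.02), the seeding step cannot bootstrap, and recovery
  collapses well below the moderate-noise regime. This is a property of
  distance-based two-way clustering at that signal-to-noise ratio, not of
  the tree machinery; methods that threshold individual cells degrade more
  gracefully there.
- At overlap 8 the union-of-modules matrix is a diagonal band that admits
  many equally coherent maximal rectangles (e.g. 16 genes x 4 conditions)
  besides the implanted 10 x 10 windows. The widening probes recover the
  implanted reading where their chains reach it, but not everywhere, so a
  subset of the ten modules is typically identified exactly and the rest
  approximately.
- Runtime is dominated by the number of distinct feature subsets explored
  (one tree per subset); the defaults (15 temperatures x 40 walks) keep a
  100 x 50 benchmark run in the ten-second range on one core while holding
  the Monte-Carlo error of co-occurrence fractions near 0.08.
- Statistical significance of individual biclusters is not assessed, and
  no annotation-based (e.g. ontology enrichment) validation is included.
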