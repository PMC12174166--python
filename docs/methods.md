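# Methods

This note records the models implemented in `oads`, the choices made where
the design was genuinely open, and what the bundled synthetic data does and
does not establish.

## Semantic similarity

Term similarity is the Wang edge-based measure. For a query term *t*, the
semantic contribution S(a) at *t* itself is 1; following an edge to a parent
multiplies the contribution by the relation's factor, and an ancestor
reachable by several paths keeps the maximum product. Factors default to 0.8
(`is_a`) and 0.6 (`part_of`) — the standard Wang constants — and must lie
strictly in (0, 1); relations without a configured factor do not propagate
contribution. Similarity of two terms is the sum of both terms' S-values
over their common ancestors, divided by the sum of the two total semantic
values, which is symmetric, bounded by [0, 1], and exactly 1 for identical
terms. S-value maps are computed by iterating max-product relaxations over
the ancestor closure to a fixpoint (the closure is shallow and factors < 1,
so this converges in a few sweeps even for DAGs whose BFS layering is not a
topological order), and cached per term. Summations run in sorted-ancestor
order so that s(a, b) and s(b, a) agree to the last bit.

The same machinery is applied to every ontology consumed (gene function,
phenotype, cell type). For the cell-type ontology this is a stated proxy:
no separate cell-specific similarity measure is implemented.

Obsolete terms are dropped at load (with a logged count); their
`replaced_by` pointers are kept so annotations can be remapped, and
annotations to unresolvable terms are discarded. Term ids are compared
case-sensitively as exact strings. Cyclic input is rejected, naming a cycle
member.

## Disease-level similarity

FunSimAvg is the symmetric best-match average: the mean of the row-wise best
matches and the column-wise best matches of the term-similarity block,
averaged. Weighted profiles (transcriptomic dysregulation magnitudes,
cell-type proportions) min-max rescale each disease's weights to [0, 1]
(a constant weight vector becomes all ones, so uniform weights reduce
*exactly* to the unweighted score — this holds to < 1e−12 and is tested) and
the two directional means become weight-weighted means.

Where the weights enter was an open design point. Three variants are
implemented behind `weight_scope` / `weight_mode`:

* `mean_only` (default): weights act only on the outer means. A term with
  weight 0 contributes nothing to its own disease's mean; best-match values
  themselves stay on the term-similarity scale.
* `max_and_mean` with geometric (`√(w_t w_u)`) or arithmetic
  (`(w_t + w_u)/2`) coupling: term-pair similarity is additionally
  multiplied inside the max operator.

`mean_only` is the default because the in-max coupling multiplies every
matched pair by a factor whose expectation is well below 1 under rescaled
weights, deflating the entire weighted score scale by roughly half. That
breaks cross-modality comparability — the analysis explicitly compares
similarity *distributions* across modalities — and makes the expected
ordering of modality means impossible to realise. With `mean_only`, weights
re-apportion influence among a disease's terms without changing the scale.

Differential co-expression (dC) weights may be negative Z-scores; they are
taken as magnitudes (|Z|) before rescaling, treating dysregulation strength,
not direction, as the weight. The top-20-terms rule applies to
transcriptomic profiles only; genetic and phenotypic profiles keep all
mapped terms (configurable via `top_k`). Ties at the top-k boundary break
lexicographically by term id, and duplicate terms merge by maximum weight.
Gene-to-term mapping is a plain lookup table supplied as input; no
over-representation test is performed at this step.

Drug-based similarity substitutes drug–drug Tanimoto similarity
(|a∩b|/|a∪b| on fingerprint bit sets, or a precomputed matrix) for term
similarity inside the same FunSimAvg aggregation; it serves as the
independent benchmark against which the other matrices are correlated
(Pearson r over off-diagonal upper-triangle entries on shared diseases).

## Permutation significance

The null shuffles the disease–term bipartite assignment: all (term, weight)
slots are pooled, permuted, and re-dealt so every disease keeps its term
count and the global term multiset is conserved exactly; duplicate terms
landing in one disease are repaired by swapping slots between diseases,
which preserves both invariants. One shared permutation stream scores all
pairs on each of the N shuffled datasets (default N = 500), and
p = (1 + #{null ≥ observed}) / (1 + N) — the add-one estimator — so p is
never 0 and the smallest attainable p is 1/(N+1). A practical consequence:
with fewer than 20 permutations no pair can reach p < 0.05, and the network
stage fails with an explanatory error. Calibration under an exchangeable
null (single community, no noise) is tested: p-values are uniform
(KS < 0.1) and the empirical type-I error at the 0.05 level lies within its
binomial band.

## Networks, topology, WiND, degree regime

An edge requires similarity strictly greater than the configured percentile
(default 90th) of all off-diagonal upper-triangle scores *and* p below
alpha (default 0.05). Isolated diseases are dropped from the graph but
reported. Path-based metrics (average shortest path, diameter) are computed
on the largest connected component with the component count logged; k-core
is reported as the maximal k with a non-empty core plus that core's size.

WiND of a member subset is the mean hop-count shortest-path length over the
subset's connected pairs, measured in the full network; disconnected pairs
are excluded from both the sum and the pair count k, so WiND is finite on
disconnected networks, and WiND over all nodes of a connected network equals
the average shortest path length (tested to 1e−12). Because k could also be
read as the number of *directly* linked member pairs, the direct-link count
is computed and reported alongside.

Degree distributions are diagnosed with the Clauset–Shalizi–Newman recipe:
xmin by KS minimisation over candidate cutoffs leaving ≥ 10 tail points,
alpha by discrete maximum likelihood (Hurwitz-zeta normalisation, bounded
search on (1.01, 8)), then Vuong-normalised likelihood-ratio comparisons
against a discretised exponential and a discrete lognormal fitted on the
same tail. The call is "random-like" only when an alternative fits better
with p < 0.1; otherwise "scale-free". This deliberately conservative rule
matches common practice: preferential-attachment graphs are not rejected
merely because a lognormal is statistically indistinguishable.

## Communities and consensus

Ward clustering runs on the 1 − similarity distance matrix; the number of
clusters, when not given, is set to the Leiden community count of the same
modality so the two methods are comparable. Leiden uses the
RBConfiguration (modularity-with-resolution) objective at resolution 1.0
with a recorded seed. Partition agreement uses the standard pair-counting
adjusted Rand index; rank consistency across modalities uses Kendall tau-b.

Robust communities are the connected components of the co-clustering graph
in which two diseases are linked iff they share a cluster in *every*
supplied partition — the strictest natural reading of "consistently
clustered" — with an any-k-of-m alternative available; components need at
least `min_size = 4` members. The result is invariant to the order
partitions are supplied.

Feature enrichment per community builds the 2×2 table of members/non-members
× with/without feature and applies the one-sided (greater) Fisher exact
test, since the question is over-representation; Benjamini–Hochberg runs
within each community's tested features by default (global adjustment
available). Features absent from a community are skipped rather than tested.

## Fusion and trajectories

SNF converts each similarity matrix to an affinity kernel
(scaled-exponential on distance 1 − sim with a K-nearest-neighbour local
bandwidth, μ = 0.5; raw affinities available behind `use_kernel=False`),
then runs the canonical cross-diffusion: each view's full kernel is
propagated through its own K-NN local kernel against the average of the
other views, with identity regularisation and symmetrisation each of t
iterations and row normalisation at entry and exit. Defaults K = 10,
t = 20. The fused matrix is rescaled to [0, 1] with unit diagonal for
downstream thresholding. Fusion is exactly invariant to input order. Note
that cross-diffusion intentionally sharpens cluster structure: fusing two
copies of one matrix preserves block membership and neighbourhoods, not the
exact per-row similarity ranking.

The MST stage applies the same top-percentile + p < alpha filter, defines
distance = 1 − similarity on surviving pairs only, and grows a Prim tree per
connected component (a spanning forest when the filtered graph is
disconnected, with the component count logged). Equal-weight edges break
ties by lexicographic disease-id pair, making the output deterministic; a
Kruskal construction is the independent optimality check in tests. A
bracketed Newick-like export is provided for tree viewers.

## Classification repository

Binary ACS sums +1/−1 over AD/AID labels. For ACS_norm the denominator
includes, optionally, sources that cover a disease without polarising it
(s = 0 with their weight) — the `covering_sources` argument — while sources
not covering the disease are excluded; the default computes over labelled
sources only, since coverage information is often unavailable. A disease
labelled both ways by one source contributes net 0 to ACS and is contested
regardless of score. Contested diseases keep their scores for reporting but
are excluded from AD/AID tallies. Cross-source id harmonisation is an input
requirement, not a computation: rows must share one id namespace.

## Synthetic data

The generator emulates the *structure* of the real inputs: a single-rooted
random DAG whose non-root terms attach to 1–`max_parents` earlier terms of
their branch (acyclic by construction); per-disease term sets drawn from
community pools that are ontology subtrees, so hierarchical similarity —
not mere overlap — separates communities; half-normal dC magnitudes for
transcriptomic weights; Dirichlet cell-type proportions concentrated on the
community's own cell types; and seven label sources that agree with a
disease's true polarity with a configurable probability, flip it or omit
the disease otherwise.

Default scenario: 5 communities × 20 diseases, 200 ontology terms, 8 terms
per disease, pool overlap 0.2, per-term noise 0.05, source agreement 0.8,
AD prior 0.8 (matching the roughly 4:1 AD:AID ratio of curated
repositories). Per-modality pool tightness (transcriptomic 0.35,
phenotypic 0.6, genetic 1.0 of the community pool) reproduces the expected
ordering of modality mean similarities. Generation is fully deterministic
under a fixed seed.

What the synthetic data does *not* emulate: realistic expression matrices,
annotation sparsity and bias of curated databases, ontology depth profiles
of GO/HPO, or inter-source correlation structure in labels. Passing tests
therefore establish correctness of the algorithms and calibration of the
statistics under known ground truth — not that real AIID networks will show
the same effect sizes.

## Problem sizes in the test-suite

The suites run the full pipeline at the default 100-disease scenario with
60–200 permutations, calibration at 46 diseases × 200 permutations (1035
pairs), power-law recovery at n = 2000 draws and 1000-node graphs, and
fusion/MST checks at 10–30 instances of 5–20 diseases; these sizes keep the
whole suite under a minute while leaving every statistical acceptance band
comfortably non-trivial.

## Known limitations

* Wang similarity treats all configured relations as contribution-carrying;
  cross-ontology links and regulatory relations are out of scope.
* The permutation null preserves term counts exactly but not per-term
  degree sequences conditional on weights; weights travel with their slots.
* The power-law classifier's verdict at small n (< ~50 positive degrees) is
  underpowered, as is inherent to the method.
* SNF assumes all views are informative enough to build a meaningful K-NN
  kernel; with K approaching n the local and global kernels coincide.
* Robust-community consensus with many partitions becomes conservative
  quickly; the any-k rule is provided for that case.
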