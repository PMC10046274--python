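# Methods

This note records the models and procedures `chemclust` implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Representation and similarity

Molecules are hashed circular-substructure (Morgan) fingerprints, radius 2
over 1024 bits by default, computed through RDKit; the package treats the
bit matrix as the clustering feature set and is agnostic to how it was
produced (precomputed fingerprint TSVs are accepted). Tanimoto similarity
T(a,b) = |a∧b|/|a∨b| and distance d = 1 − T. Two conventions the standard
definition leaves open:

- **All-zero fingerprints.** T(0,0) is defined as 0 (logged at debug
  level): an empty fingerprint shares no substructure with anything, so it
  is treated as maximally dissimilar rather than identical to another empty
  fingerprint.
- **Nearest-neighbor ties** resolve to the lowest molecule index, for
  determinism.

Pairwise distances are computed in row blocks (default 512 rows) so peak
extra memory is O(block·n); the condensed upper-triangle vector is the only
full-size allocation, and a float32 storage switch exists for billion-pair
scales. The nearest-neighbor profile streams the same blocks and retains
only the n per-molecule maxima, never materializing the condensed matrix.

## Outlier filter

A molecule is an outlier at similarity cutoff c when its nearest-neighbor
similarity is ≤ c. The profile used for filtering is computed once on the
full set; it is **not** recomputed iteratively after removals (the filter
is a single pass, so re-running it on the retained set can in principle
flag further molecules whose only close neighbor was removed — the scan
reports counts rather than hiding this). `histogram_gap_cutoff` places the
cutoff at the midpoint of the widest gap in the sorted nearest-neighbor
similarities; it is intended for data with two separated similarity modes
(cluster members vs. isolated molecules) and is not meaningful on unimodal
profiles. The cutoff-scan experiment re-clusters the retained molecules at
each cutoff with a baseline Ward clustering and reports the three indices;
rows whose retained set cannot be clustered (fewer than 2 molecules or a
single cluster) carry NaN sentinels, never fabricated numbers.

## Clustering

**Ward hierarchical.** Implemented from the Lance–Williams recurrence on
squared distances; two singletons merge at their input distance, and merge
heights are asserted non-decreasing on every run (drifts below 1e−9 are
clamped). Pair selection ties resolve to the lexicographically smallest
active pair. Cutting the tree follows the cophenetic-distance criterion
(all merges at height ≤ cutoff are applied); flat labels are numbered in
order of first leaf appearance. The implementation agrees with independent
references (a brute-force greedy transcription of the recurrence, and
scipy's Ward linkage) in the test suite. Complexity is O(n³) time worst
case with an O(n²) working matrix — adequate for the desk scales this
package targets (tested to a few thousand molecules).

**Taylor–Butina.** Neighbor lists use genuine similarity semantics: j is a
neighbor of i iff T(i,j) ≥ cutoff. Each round the unassigned molecule with
the most *unassigned* neighbors (recomputed per round; ties to lowest
index) becomes a centroid and absorbs its unassigned neighbors; leftovers
are singletons even if they had neighbors. Consequence of these semantics:
*lowering* (relaxing) the similarity cutoff grows the exclusion spheres and
merges molecules into fewer clusters, so cluster count (singletons
included) is non-decreasing in the cutoff. Implementations in the wild
sometimes accept a *distance* threshold instead, which flips the direction
of that trend — when comparing against such tools, pass 1 − cutoff.

**UMAP + agglomerative.** The embedding is delegated to `umap-learn`
(re-implementing the manifold optimizer is a non-goal); defaults are
n_components = 2, Jaccard metric on the binary rows, and seed 42 recorded
in all outputs — the embedding is reproducible only for a fixed seed and
environment. The embedded points are then Ward-agglomerated under Euclidean
distance (reusing the in-package linkage) and cut to exactly k clusters,
which the tests show matches scikit-learn's Ward `AgglomerativeClustering`.

## Evaluation

Silhouette, Calinski–Harabasz and Davies–Bouldin are implemented from their
definitions; the tests verify equivalence with naive transcriptions (100
random instances, n ≤ 200, k ≤ 10, tolerance 1e−9) and with scikit-learn.
Degenerate cases are explicit rather than silent: k = 1 is a validation
error; a singleton cluster contributes silhouette 0 (the mean intra-cluster
distance is undefined for a one-member cluster); zero within-dispersion
(CH) and coincident centroids with positive scatter (DB) return +inf
sentinels with a warning. The dispersion decomposition satisfies
tr W + tr B = total scatter about the grand centroid (checked to 1e−9).

**Feature space.** Validity indices need a vector space. For Ward/Butina
clusterings of fingerprints the indices are computed on the binary matrix
under Euclidean geometry; for the UMAP route, on the embedding coordinates.
Both spaces are supported through an explicit `metric_space` argument, and
reports record which was used — absolute index values are comparable only
within one space (embedding-space scores are typically orders of magnitude
more favorable).

The average similarity matrix holds the mean Tanimoto similarity between
molecules of cluster i and cluster j; diagonal entries average over
*distinct* within-cluster pairs only and are NaN for singletons, whose
within-cluster mean is undefined. Cluster-size summaries report mean,
sample std (ddof = 1), min, max and the {10, 17, 20, 25, 50, 75} percentile
set with linear interpolation between order statistics.

## Hyperparameter tuning

Grid search over (n_neighbors, min_dist) at fixed k scores every cell with
the three indices on the embedding; a cell "wins" an index by attaining its
optimum (max silhouette, max CH, min DB), the winner takes the most wins,
and ties break to smallest n_neighbors then smallest min_dist. Failed
embeddings are flagged and excluded. The elbow step freezes the winning
embedding, builds one Ward tree and cuts it at every k in the range, so the
clusterings are nested and distortion (within-cluster SSE against assigned
centroids) is provably non-increasing in k — asserted on every curve.

Knee detection is a Kneedle-style rule: x and y are rescaled to [0, 1], the
decreasing curve is flipped, and the knee is the k maximizing
(1 − yₙ) − xₙ. If that maximum falls below `sensitivity` × mean x-spacing
(sensitivity 1.0 by default) the curve is declared elbow-free and None is
returned — an exactly linear curve always yields None, and the rule is
invariant to positive rescaling of the scores. Silhouette-scored curves
return the argmax k. On strongly separated clusters the normalized rule can
land one step before the planted count (the curve is already nearly flat
there); the procedure is intended to narrow the k search, not to certify a
single value.

## Synthetic data

Each planted cluster has a centroid with bits on independently at density
p = 0.05 over 1024 bits (~51 set bits, matching sparse Morgan
fingerprints); members clear each centroid on-bit with probability eps_off
and set each off-bit with probability eps_on. Outliers are independent
Bernoulli fingerprints at their own density, appended with the sentinel
label −1. One pseudo-random stream per call, seed mandatory.

The default preset (4 clusters × 100 members, eps_off = 0.19,
eps_on = 0.010, 20 outliers at density 0.05) was calibrated once by
simulation so the pre-filter nearest-neighbor similarity median falls near
0.6 — the regime of a large, structurally diverse screening panel — and
then frozen. The lower-noise setting (eps_off = 0.1, eps_on = 0.005) used
by the recovery benchmarks produces well-separated clusters where exact
recovery is the correct expectation.

What the generator does **not** emulate: real fingerprint bits are
correlated (substructures overlap and collide under hashing), cluster sizes
and densities are heterogeneous, and real panels contain near-duplicates
and activity cliffs. Passing the planted-recovery tests therefore shows the
algorithms are implemented correctly and behave as designed on separable
data; it does not show that any method will cluster a real screening panel
well — on real data the indices and the similarity matrix are the evidence
to inspect, which is the point of the pipeline.

## Pipeline and problem sizes

The pipeline runs two scenarios (all molecules; non-outlier molecules) for
every enabled method/cutoff, writes per-run quality tables, assignments,
size summaries and similarity matrices, and a final comparison table whose
best-per-column flags exclude sentinel values. The representative run per
method/scenario in the comparison table is the one with the best mean
silhouette among that method's cutoffs — a documented convenience, not a
recommendation to ignore the full table. Wall-clock runtimes are logged for
information only; they are hardware-dependent and excluded from any
comparison. Shipped defaults operate at desk scale (a few hundred
molecules, one embedding per scenario, k ranges to ~25), the size at which
the whole protocol runs in seconds to minutes on one CPU; all components
accept larger inputs, with the O(n²) distance stage and the Ward linkage
the practical limits.
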