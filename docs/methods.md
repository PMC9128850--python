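# Methods

This note records the models implemented in `crowdclust`, the parameter
choices that matter, and what the synthetic components do and do not
emulate.

## Data model

A dataset is an `N × F` numeric matrix (`F ≤ 6` for the annotation
workflow) with per-point labels; `-1` is the reserved noise label. Planted
clusters are described by `ClusterSpec`s: a subspace (2 to `F` distinct
dimensions), a size, and per-dimension mean and variance vectors.
Cluster points are drawn from an axis-aligned multivariate normal inside
the subspace; every off-subspace coordinate is uniform over the global
data range `[0, 10]`, so a cluster is statistically invisible in any
projection that misses its subspace. This is the property that makes
subspace search necessary and makes the 2-D annotation views informative
only for the right dimension pairs.

Two clusters that share at least one dimension must satisfy the Manhattan
separation rule on the shared dimensions:
`distMan(mean1, mean2) > distMan(0, cov1 + cov2)`, i.e. the L1 distance of
the means must exceed the L1 norm of the summed variance vectors. Specs
are rejection-sampled against this rule (cap: 10 000 attempts per cluster,
then a hard error suggesting a looser configuration). Defaults — means
uniform in `[1, 9]` per dimension, variances uniform in `[0.05, 0.3]` —
put cluster footprints at roughly 2–4 grid cells per dimension at the
default grid resolution, comfortably above the uniform background density.
The reference configuration (6 clusters, ≈2000 points, 6 dimensions, 5%
noise) mirrors the published benchmark layout: cluster sizes jitter ±5%
around the equal split, subspace sizes are drawn uniformly from [2, 6]
with replacement, and `round(0.05 × cluster points)` uniform noise points
are appended — exactly, which the tests assert.

## Puzzles and coverage

A puzzle is a uniform random sample (without replacement, independent
across puzzles) of `n` points, presented as one stage per unordered
dimension pair in a per-puzzle shuffled order; stage coordinates are
min-max rescaled to the unit square (a constant axis maps to 0.5). With
`P` puzzles the expected per-point exposure is `P·n/N`; the reference
operating point `P = 50, n = 100, N = 2000` gives exactly 2.5 appearances
per point. `n` defaults to 100, the order of magnitude a mobile screen
renders comfortably.

## Simulated annotators

The simulator stands in for a live crowd, which the package does not
require. Per stage, with probability `fidelity` a player anchors on a
planted cluster restricted to the stage's points — chosen among the
visible clusters (≥ 3 points present) with probability proportional to
the compactness (inverse total variance) of its projection — and then
flips each stage point's membership with probability `flip_rate`.
Otherwise the answer is a random circular blob on the display square
(radius uniform in [0.05, 0.3]). Selections are never empty. A fraction
`oversize_players` of players inflates every selection by a factor drawn
uniformly from [3, 6] (capped at the stage size), emulating the
bigger-cluster-scores-more misconception that the average-cluster-size
filter targets.

Compactness-*proportional* (rather than argmax) cluster choice is
deliberate: a deterministic "most compact wins" rule permanently starves
any planted cluster that is second-most-compact in every view — e.g. two
clusters sharing one subspace — so no faithful crowd could ever reveal it,
which contradicts the purpose of the noiseless limit. With proportional
choice, the noiseless limit still guarantees every answer is exactly a
planted cluster's stage-restricted point set.

What the simulator does not model: learning across a player's history,
fatigue, timers and score-chasing strategies, screen-resolution effects,
and systematically correlated errors between players. Passing tests
therefore show that the algorithms extract the signal a *conditionally
independent* noisy crowd provides; they do not certify behaviour under
adversarial or strongly correlated annotation.

## Selection statistics and the ACS filter

`W(x) = f_clustered(x) / N_appeared(x)` counts stage-answers: every
answered stage of a puzzle containing `x` is one exposure. Points never
shown have undefined weight and are later imputed with the mean observed
weight (not 0 — unexposed regions are not evidence of absence); with no
observations at all the weights degenerate to 1 and the weighted pipeline
is, by construction, the unweighted CLIQUE baseline.

The average-cluster-size (ACS) filter removes, per player, selections
whose size is at least `mean + 2·std` (population std) of that player's
selection sizes, and repeats the trim until stable, which makes the filter
idempotent — a single pass is not, because removing one outlier can expose
another under the recomputed threshold. Players with fewer than five live
selections, or zero size spread, are left untouched: with a handful of
answers the size distribution carries too little information to call
anything an outlier. Note the filter is intentionally per-player and
relative; a player who inflates *every* selection uniformly shifts their
whole distribution and is invisible to it.

## hubCLIQUE

Primitive subspaces are two-dimensional (the projections annotators saw).
Each dimension pair's projection is cut into a `ξ × ξ` grid over the
observed ranges (last bin closed); a cell is dense when its weighted point
mass reaches `τ · Σw / ξ²`, i.e. `τ` times the uniform expectation.
Defaults `ξ = 10`, `τ = 2.0` are the CLIQUE family's classic knobs; the
relative threshold keeps weighted and unweighted runs comparable, since
scaling all weights cancels. Dense cells are grouped into connected
components under shared-edge adjacency (corner contact does not connect),
and components become subspace-tagged candidate clusters.

Candidates are joined level by level: two `K`-dimensional candidates
sharing exactly `K−1` dimensions and at least one point yield a
`(K+1)`-dimensional candidate on their point intersection. No
coverage-based (MDL-style) pruning is applied — low-coverage subspaces may
be fragments of a larger solution — but duplicates are emitted once. The
candidate pool for aggregation contains all levels, 2-D through `F`-D.

Aggregation is two-phase. Phase 1 walks the candidates in decreasing
(subspace size, point count) priority; when a lower-priority candidate
overlaps a higher one by at least `θ_merge` of its own size (default 0.5)
and the subspaces are nestable (one contains the other, or the smaller
shares all but one of its dimensions), they merge into (union subspace,
intersection points); any other overlap strips the contested points from
the lower candidate. Phase 2 repeatedly re-sorts the surviving candidates,
assigns the head's points a fresh cluster id, and deletes them from the
rest; unclaimed points stay unassigned (`-1`). All orderings carry
deterministic tie-breaks (subspace tuple, then smallest member id), so the
whole pipeline is reproducible without any randomness.

## CloCworks

For each dimension pair, the co-selection network weights an edge `(u, v)`
by (stage-answers on that pair selecting both) / (stage-answers showing
both). The denominator is co-appearances rather than all presentations of
the stage: under puzzle subsampling two points are often not shown
together, and counting those presentations would deflate frequencies for
no informational reason. Pairs never shown together get no edge at all.

Each pair network is partitioned with seeded Louvain modularity
maximization (networkx's implementation of the Blondel multi-level
algorithm); communities of at least 3 points (smaller ones are
noise-prone) become candidates tagged with the dimension pair, and the
phase-1/phase-2 aggregation runs with relaxed settings: `θ_merge = 0.25`
and any shared dimension counts as compatible. A `summary` mode is also
provided — element-wise mean of the pair networks over defined entries,
partitioned once — because the per-pair and summary readings are both
coherent designs; `per_pair` is the default as it preserves subspace
information.

### Direct network inputs

The same machinery runs on externally supplied weighted networks (the
simulated SBM replicates below). Here the default protocol is *consensus*:
Louvain partitions each replicate network, the partitions are aggregated
into a co-association network (edge weight = fraction of replicate
partitions co-clustering the pair — the same frequency-averaging the
summary construction applies to raw selections, applied to partition
indicators), and the consensus network is partitioned once. The
alternative `average` protocol (edge-wise mean of the replicates, one
partition) is available; it is markedly easier, because the union topology
of 15 sparse replicates is well connected, and its errors reduce to the
background nodes alone. The consensus default was chosen as the closest
analogue of aggregating per-stage observations and is the protocol behind
`scripts/acceptance.py` and the sparsity sweep.

## Weighted SBM generator

Nodes are split into planted communities plus `n_noise` background nodes
(the reference layout: sizes 338/328/334/340/335/339 with
`round(0.05 × 2014) = 101` background nodes). Each pair gets an edge
independently with its class probability — `p_intra` within a community,
`p_inter` between communities, `p_noise` for any pair touching a
background node — and each realised edge draws its weight from a normal
with the class mean (0.8 / 0.4 / 0.1) and sd `sigma = 0.1`, truncated to
[0, 1] since weights model selection frequencies. All replicates share
one node layout; everything is driven by a single seed through spawned
generators, so replicate sets are byte-reproducible.

At the sparse reference operating point (`p_intra = 0.01`,
`p_inter = 0.005`) a ~330-node community gives each member roughly three
intra-community edges per replicate while background edges carry a large
share of total edge weight, so single replicates are far below the
detectability comfort zone — recovery hinges on combining the 15
replicates. The consensus protocol recovers the layout to a mean micro-F1
of ≈0.96 (five replicate sets; the residual errors are background nodes
absorbed into communities plus a small fraction of community points lost
in fragmented replicate partitions). The sparsity sweep over
`p_intra ∈ {0.005, 0.05, 0.5}` (tested at a 1/5-scale layout to keep the
suite fast) is monotone: ≈0.21 / ≈0.98 / ≈0.98.

## Stage scoring

Validity indices are computed on the two-block partition {selection,
complement} of the stage's display coordinates: mean silhouette width;
Dunn = min inter-block distance / max block diameter; S_Dbw = average
relative block scatter + between-centroid relative density
(Halkidi–Vazirgiannis construction, lower better). A selection is one
cluster, not a partition, so the two-block reading is the minimal faithful
way to apply partition indices to it.

Raw indices are normalized against reference distributions harvested
once per dataset family: random stages are partitioned by KMeans
(k ∈ {2,3,4}) and spectral clustering (k ∈ {2,3}), and every resulting
cluster contributes one raw value per index. The normalized value is the
fraction of reference samples that are strictly worse (orientation-aware),
hence in [0, 1] and monotone in the raw score. The desk-scale default is
200 stages (a few thousand reference clusters); the production-scale
15 000 stages is a config value away and changes only the smoothness of
the normalization.

`Cons` is `|prev ∩ cur| / |cur|` — normalizing the raw conserved-point
count by the current selection size is required for it to mix with the
[0, 1] quality term. On the first stage (no previous selection) the score
degenerates to `Qual` alone. `DCC` fits a Gaussian KDE (Scott bandwidth)
to the stage, takes the fraction `r` of stage points whose density is
below the selection's mean density, and returns
`clip(2(r + shift) − 1, −1, 1)` — shift 0 by default; a shift of
magnitude 1 saturates the coefficient, and the shift magnitude sets how
strongly multi-modal density within one selection is penalized.
`score = (α·Qual + (1−α)·Cons) · (1+DCC)/2` with `α = 0.8`; the puzzle
score is the stage-score sum, so it lives in `[0, #stages]`.

## Evaluation

Micro-averaged F1 aligns predicted to planted clusters with an optimal
injective (Hungarian) assignment on the contingency table, then pools
globally: TP = points whose mapped prediction equals their true cluster;
FP = any labelled point whose mapped prediction differs, including every
prediction on a noise point; FN = true-cluster points unassigned or
mismatched. Unassigned predictions are "no prediction" (pure FN), and
noise is "no cluster" (never a mapping target). The Hungarian mapping is
verified against exhaustive enumeration of all injective mappings on
instances with ≤ 8 points. High-/low-dimensional subgroup scores restrict
the pooled counts to points whose true cluster lives in a ≥ 4- or
< 4-dimensional subspace, respectively.

The elbow heuristic runs KMeans for `k = 1..k_max` and returns the `k`
maximizing the second difference of inertia (ties to the smallest `k`).
The benchmark harness calls the standard scikit-learn baselines (KMeans,
Ward, GMM, DBSCAN, MeanShift, affinity propagation) with `k` from the
elbow where required; GMM is averaged over seeded replicate fits (desk
default 50, production 1000) and reported with its standard deviation,
since single GMM fits are unstable.

## Problem sizes used by the shipped experiments

The acceptance script runs the full-size reference layout (2115 nodes, 15
replicates, five replicate sets, ≈3 minutes on one CPU). The test suite
uses the full layout for the headline network experiment and the
crowd-vs-baseline comparison (≈2000 points, 50 puzzles × 100 points, ten
fidelity-1 players, five seeds), and 300–800-point datasets elsewhere.

## Known limitations

* Phase 1's merge keeps the *intersection* of the merged point sets; under
  heavy fragmentation this is conservative and leaves many points
  unassigned — visible in the absolute F1 of the grid pipeline — though
  the crowd-weighted variant consistently outperforms its unweighted
  baseline under the same settings.
* The exact aggregation used for replicate network partitions is a design
  choice (consensus co-association); alternatives (edge-wise averaging,
  destructive overlap resolution) bracket it from above and below on
  recovery quality.
* Cluster orientation is axis-aligned in the generator; rotated
  covariances would weaken the printed separation rule's guarantee and are
  not implemented.
* The annotator model is first-principles synthetic; none of its
  parameters were fit to human data.
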