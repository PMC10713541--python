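# Methods

`painnet` analyzes a structural brain network in which nodes are brain
areas and directed, weighted edges are axonal projections quantified by
normalized projection volume (segmented axonal signal in the target
divided by injection-site volume, as in mesoscale anterograde-tracing
atlases). This note records the model, the conventions behind every
measure, the synthetic-data generator, and the numerically or
scientifically open choices we made.

## Data model and preparation

A projection table holds one record per `(source, target, hemisphere,
experiment)` with a nonnegative volume; an area catalog holds acronym,
name, anatomical group (CH cerebrum, BS brain stem, CB cerebellum) and a
3-D injection coordinate. Replicate experiments are combined by
arithmetic averaging per `(source, target, hemisphere)`; aggregation is
idempotent. Missing pairs mean zero strength, not missing data, because
tracing matrices are dense down to a false-positive floor.

Two thresholds with different jobs:

* **detection threshold** (default `1e-4`) — the minimal true-positive
  level; used only for the laterality *count* (what fraction of
  detectable connections is ipsi- vs contralateral). The ipsi:contra
  *volume ratio* instead totals all volumes, unthresholded.
* **edge threshold** (default `0.01`) — projections weaker than this are
  not considered connections when building the graph.

The graph collapses hemispheres: by default the ipsilateral and
contralateral strengths of an ordered pair are summed before
thresholding (the most inclusive reading; an ipsi-only rule is
available). Self-projections are dropped; every catalog area is a node,
so isolated areas still count toward |V|.

## Topology measures

All graph algorithms are implemented in this package directly on a
minimal digraph container (generic graph libraries appear in the test
suite only, as independent oracles). Conventions, which matter on a
directed graph:

* **Shortest paths** are unweighted hop counts everywhere by default
  (diameter, mean distance, closeness, betweenness); a weighted variant
  (weights as lengths) exists but is off by default, because reported
  hop-style diameters of such networks are integers.
* **Density** D = |E| / (|V|(|V|−1)); **reciprocity** is the fraction of
  directed edges whose reverse exists.
* **Diameter / mean distance** run over reachable ordered pairs only;
  the number of unreachable pairs is reported alongside.
* **Closeness** of v is 1/Σ d(v,u) over targets reachable from v (NaN
  when v reaches nothing). **Betweenness** is Brandes' accumulation over
  ordered pairs, unnormalized.
* **Clustering and assortativity** are computed on the undirected
  skeleton. This matches the behavior of the standard implementations
  for directed input and explains why a directed Erdős–Rényi graph with
  edge probability p shows mean clustering ≈ 1−(1−p)², the skeleton
  density. Mean clustering averages nodes with skeleton degree ≥ 2 (a
  global-transitivity variant is provided). Assortativity is the Pearson
  correlation of skeleton degrees across edge endpoints (both
  orientations), undefined on regular graphs.
* **Top-k rankings** break ties lexicographically by acronym, for
  deterministic reports.
* The **Lorenz curve** of the degree sequence is computed on the
  ascending-sorted degrees; a k-regular graph traces the diagonal.

## Community detection

Walktrap (random-walk agglomeration) is implemented from scratch. On the
undirected weighted skeleton (antiparallel weights summed), the t-step
transition matrix P^t (t = 4, the customary default) defines vertex
distances r_ij = sqrt(Σ_k (P^t_ik − P^t_jk)² / d_k) with d_k the
weighted degree. Communities are merged agglomeratively — always the
*adjacent* pair minimizing the Ward-style increase in within-community
squared distance, ties broken by smallest id pair — and the returned cut
is the dendrogram level with maximal weighted modularity
Q = Σ_c (w_c/W − (s_c/2W)²). The procedure is fully deterministic.
Restricting merges to adjacent communities makes disconnected components
independent; isolated nodes end as singletons. Edge weights enter as
stored (raw volumes); a log-rescaled option exists for sensitivity
checks, since with strengths spanning >1e5-fold a single heavy edge can
dominate the walk.

## Null models

Three matched comparison models, all seeded and deterministic:

* **Erdős–Rényi G(n, m)**: exactly m directed edges uniformly without
  replacement — matching "same density" exactly rather than in
  expectation.
* **Watts–Strogatz**: undirected ring lattice, `nei` neighbors per side
  (default `round(m/2n)`, matching skeleton density; the natural
  alternative — mean total degree — is exposed as a parameter), each
  lattice edge rewired with probability 0.05; converted to mutual
  directed pairs, hence reciprocity exactly 1.
* **Barabási–Albert**: growth with attachment probability
  ∝ degree^0.5 + 1 (the +1 keeps degree-0 nodes reachable),
  `round(m/n)` draws per new node collapsed to simple edges, all edges
  newborn→older: acyclic, reciprocity exactly 0. Collapsing makes the
  realized edge count approach m from below.

## Robustness

Following the error-and-attack-tolerance protocol: remove a fraction f
of nodes — uniformly at random, or by repeatedly deleting the currently
highest-total-degree node (degrees recomputed after each removal, ties
broken uniformly at random; an initial-degree variant exists) — and
track (i) the mean distance of the remainder, (ii) the largest weakly
connected cluster S as a fraction of the *original* node count, and
(iii) the mean size ⟨s⟩ of the non-largest clusters (0 when none).
Each (f, mode) cell averages 100 replicates; everything is reproducible
bit-for-bit under a fixed seed. Mean distance is averaged over reachable
ordered pairs only, so it stays finite under fragmentation — the price
is that once an attack shatters the network, the reachable-pair average
*drops* by construction. The attack-vs-random distance comparison is
therefore meaningful in the pre-shattering regime (we evaluate it for
f ≤ 0.2, where the network remains dominated by one large cluster),
while the fragmentation comparison (S) is evaluated for f ≥ 0.2.
Components are weakly connected: fragmentation ignores edge direction.

## Spatial analyses

Pairwise area distances are Euclidean distances between injection
coordinates (optionally max-normalized). The 2-D layout uses classical
(Torgerson) multidimensional scaling: double-center −D²/2,
eigendecompose, scale the top two eigenvectors by √eigenvalue;
configurations that are exactly 2-D embeddable are reconstructed to
numerical tolerance, and a degenerate spectrum triggers a warning rather
than an error. Strength–distance fits correlate log10 strength (floor
1e-6 added before the log; zero-strength pairs excluded) with distance,
per source area, requiring ≥ 3 positive targets. Source/target profile
correlations are Pearson correlations of log10-floored outgoing rows /
incoming columns with self-entries masked (pairwise-complete, hence
symmetric); zero-variance profiles yield NaN. The log scale is a
declared choice: with >1e5-fold strength ranges, raw-scale correlation
is dominated by a handful of edges.

## Synthetic connectome generator

The generator emulates the statistical signatures of the study system so
the full pipeline is testable without downloads. Defaults (chosen once,
as the generator's definition of "pain-like"): 49 areas in groups
18 CH / 21 BS / 10 CB, each group a Gaussian spatial cluster (jitter
0.25 around centers ~1.2 units apart, units abstract); log10 base
strength N(−1.0, 2.5) shared between the two hemispheres of a pair
(bilateral projections are strongly correlated in tracing data), giving
a >1e5-fold strength range; ipsilateral strengths multiplied by
10^(−1.0·distance), contralateral strengths distance-free; block
structure = anatomical groups with within-p 0.6 / between-p 0.25; a
reciprocity-forcing step (one-way pairs gain their reverse with
probability 0.63); and a per-area log-normal connectivity propensity
(log-sd 1.2, unit mean) multiplying connection probabilities.

The propensity term is what gives the generated networks a right-skewed
degree distribution — a few hub areas, a sparse periphery — without
which hub attack cannot fragment the network the way it fragments the
real one; it was calibrated against those qualitative behaviors
(fragmentation under attack at f ≥ 0.2, attack-dominant mean distance
for f ≤ 0.2) across seeds before being frozen. The contralateral scale
is auto-calibrated per realization so the total ipsi:contra volume ratio
hits its target (3.5 by default) exactly; passing an explicit scale
disables the calibration. Volumes below 1e-7 are floored to zero to
mimic detection limits. Everything is deterministic given the seed.

What the generator does *not* emulate: ontology-correlated strength
patterns, censoring at the segmentation limit, per-experiment injection
variability, or any likelihood-based fit to real atlas data. Passing
tests on synthetic data therefore demonstrate algorithmic correctness
and qualitative behavior under the stated statistical conditions, not
quantitative agreement with any particular real connectome.

## Problem sizes and determinism

Simulation-based checks use the sizes natural to the system: 49-node
graphs, 100 robustness replicates per fraction, 200 Erdős–Rényi draws
for null-model expectations, 50 generator seeds for partition recovery.
All randomness flows through explicit seeds (NumPy `default_rng`);
reports are byte-stable across runs at fixed seed (up to echoed file
paths in the configuration block).

## Known limitations

* Real-data quantities (e.g. hub identities, the observed diameter)
  depend on the deposited projection tables; the package computes them
  from CSVs via `painnet run` but ships no real data.
* Walktrap on raw weights is sensitive to extreme edge weights; use
  `--log-weights` to probe that sensitivity.
* The Watts–Strogatz neighborhood and Barabási–Albert step size matched
  to a reference graph are conventions (density matching); clustering
  and assortativity of those models should be read qualitatively.
* Betweenness and closeness are unweighted; strength-aware centralities
  are out of scope.
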