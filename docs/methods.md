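# Methods

## Model

Each sample is summarized as the stationary distribution of a mass-action
random walk on a fixed, shared interaction graph. The walk's transition
probability from gene *i* to neighbor *j* is proportional to *j*'s
expression, `p_ij = x_j / Σ_{k∈N(i)} x_k`, which assumes (a) the
interaction topology is the same for every sample, only the weights
change; (b) expression values are strictly positive and already
normalized to a comparable scale (e.g. variance-stabilized counts —
normalization itself is out of scope here); and (c) interaction intensity
grows with the partner's expression, the same premise as differential
co-expression analysis, but applicable to a single sample.

For this specific chain the stationary measure is available in closed
form, `π_i ∝ x_i Σ_{j∈N(i)} x_j`, so no linear solve is needed per
sample; the closed form is the production path. Stationarity is an exact
algebraic identity, which is why the test suite demands `‖πP − π‖∞ ≤
1e−10` rather than a loose numerical tolerance.

Samples are compared with the Wasserstein-1 distance between their
stationary measures, with the hop count as ground metric. Three LP
formulations are implemented: the coupling (primal) LP, the edge-flux
min-cost-flow LP, and the Kantorovich dual over node potentials. The flux
LP is the production solver — its variable count is the edge count *m*
(2*m* after splitting |u| into nonnegative parts), versus *n²* for the
coupling LP, a saving of three orders of magnitude on interaction-network
sparsity. The other two exist purely as cross-checking oracles; equality
of all three on random instances is a strong-duality test that exercises
the entire LP pathway.

## Numerical choices

- **LP backend**: `scipy.optimize.linprog` with the HiGHS solver on
  sparse constraint matrices. Solutions are accepted only if the
  constraint residual is ≤ 1e−7 — ample, since downstream thresholds act
  at the 1e−2 scale.
- **Mass balance**: the two measures must agree in total mass to 1e−9;
  both are renormalized to exactly 1 before solving (logged if drift
  exceeds 1e−9). Unequal masses make the flux LP infeasible and the dual
  unbounded, so they are rejected up front.
- **Edge orientation** of the incidence matrix is arbitrary in principle;
  it is fixed as head = smaller node index, with edges enumerated in
  sorted index order, so fluxes serialize reproducibly.
- **Dual degeneracy**: potentials are invariant under an additive
  constant; the first node's potential is pinned to 0.
- **Eigensolver oracle**: power iteration with tolerance 1e−12 and a cap
  of 1e5 iterations, run on the lazy chain (P + I)/2. The lazy chain has
  the same stationary vector but is aperiodic, whereas plain iteration of
  P oscillates indefinitely on bipartite graphs (trees, even cycles),
  which do occur among random test topologies.
- **Node ordering** everywhere is the sorted gene-id list; all vectors,
  matrices and files share it, making pipeline outputs byte-reproducible.
- **Degenerate inputs**: self-loops are dropped on ingest (they would
  silently change both P and π); duplicate gene ids are an error unless
  an explicit policy (first/sum/max) is configured; non-positive
  expression is an error naming the gene unless an epsilon floor
  (a configured multiple of the sample's smallest positive value) is
  opted into, in which case the substitution is logged.
- **Thresholding rule** is strict: a distance exactly equal to the
  threshold binarizes to 1 (not close).

## Design choices where the design was open

- **Clusters and outliers are made algorithmic.** Thresholded heat maps
  are usually read by eye. Here clusters are defined as connected
  components of the graph joining sample pairs with distance strictly
  below the threshold, and a sample is an outlier when its mean distance
  to all others exceeds the cohort mean of such means by k·SD (default
  k = 2). Both are the simplest rules consistent with the visual
  practice, and they make recovery claims testable.
- **Pipeline split into prepare / distances / analyze.** The pairwise
  stage costs s(s−1)/2 LPs for s samples (a 292-sample cohort means
  ~42,000 solves), so it checkpoints each solved pair and resumes.
- **"Redundant genes"** in upstream data are interpreted as duplicate
  identifiers, with an explicit, configurable resolution policy
  (default: error). Component-size ties in the largest-connected-
  component step break to the component containing the lexicographically
  smallest gene id.

## The synthetic-data generator

Real inputs (an interaction database and a normalized tumor-expression
cohort) require external downloads, so the package generates stand-ins
with the statistical structure the method assumes:

- **Topology**: the largest connected component of a preferential-
  attachment graph (default 500 nodes, 4 edges per node ≈ 2000 edges),
  whose heavy-tailed degrees mimic protein-interaction networks (median
  degree below the mean, as in the real networks this models).
- **Cohort**: baseline log-expression is Gaussian per gene (mean 6, SD 1,
  a variance-stabilized-like scale); each of two groups (default 20 + 20
  samples) adds a +1.5 log-unit shift on its signature — a *connected*
  BFS ball covering 10% of the nodes, because the transport metric is
  topology-aware and spatially coherent signatures are exactly the signal
  it is built to separate; per-sample log-normal noise has σ = 0.2; one
  outlier sample carries a 3× shift on a third, disjoint ball. All values
  are exponentiated, hence strictly positive, and every draw is
  deterministic given the seed. Signature seeds after the first are
  placed to maximize hop distance from already-placed signatures.

What the generator does **not** emulate: count noise and library-size
effects (profiles are log-normal, not negative-binomial counts run
through a variance-stabilizing transform), correlated co-expression
modules beyond the planted signatures, batch effects, and any
directionality or sign structure on interactions. Passing recovery tests
therefore shows the pipeline separates topologically localized expression
shifts under log-normal noise — not that it will cluster any particular
real cohort, where signal geometry and noise are less obliging.

## Problem sizes used in the checks

The automated checks run the stationarity identity on 100 random
connected graphs (n ≤ 50), strong duality on 200 random instances
(n ≤ 12), the delta-measure/hop-metric identity on 20 graphs (n ≤ 10),
metric axioms on 100 random triples, and the full pipeline on the default
500-node, 41-sample cohort — sizes chosen so the whole battery completes
in about a minute on a single CPU while still exercising every code path
at the default study conditions.

## Known limitations

- The coupling LP is guarded to ≤ 200 nodes; it is an oracle, not a
  production path.
- No entropic/Sinkhorn approximation and no W_p for p ≠ 1; only the exact
  LP route is implemented.
- No hierarchical, spectral or k-means clustering and no significance
  testing of cluster separation; the thresholded-components rule is the
  only clustering offered.
- Expression normalization (e.g. VST of raw counts) must happen upstream;
  the pipeline validates positivity but cannot detect unnormalized input.
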