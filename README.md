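# graphemd

Expression-cohort comparison and clustering by **optimal transport on a
gene interaction network**.

Bulk expression profiles are usually compared gene-by-gene, ignoring how
genes interact. `graphemd` instead treats every sample as a probability
distribution over the nodes of a shared protein–protein interaction
network and compares samples by how much "work" it takes to transport one
distribution into the other along the network's edges — the Wasserstein-1
(Earth Mover's) distance. Because the metric is topology-aware, two
samples differ a little when their expression differences sit on
neighboring genes and a lot when they sit in distant network regions.
The intended users are computational biologists clustering tumor or
patient cohorts on a fixed interaction scaffold.

## The model

Given an undirected connected interaction graph with node set
$\{1,\dots,n\}$, neighbor sets $N(i)$, and a strictly positive expression
vector $x$ for one sample:

1. **Mass-action random walk.** Edge weights follow mass action — the
   intensity of an interaction grows with the expression of the partner:

   $$p_{ij} = \frac{x_j}{\sum_{k \in N(i)} x_k}, \qquad j \in N(i),$$

   so $P = [p_{ij}]$ is a row-stochastic matrix supported on the edges.

2. **Invariant measure.** The stationary distribution $\pi P = \pi$ of
   this particular chain has a closed form,

   $$\pi_i = \frac{1}{Z}\, x_i \sum_{j \in N(i)} x_j,$$

   with partition function $Z$: a gene is important when it is highly
   expressed *and* its interaction partners are. $\pi$ is the sample's
   network-aware summary.

3. **Earth Mover's Distance.** Two samples' measures $\rho^0, \rho^1$ are
   compared by

   $$W_1(\rho^0,\rho^1) = \min_{u \in \mathbb{R}^m} \Big\{ \sum_{e=1}^m |u_e| \;\Big|\; \rho^0 - \rho^1 - Du = 0 \Big\},$$

   a min-cost-flow linear program over signed edge fluxes $u$, with $D$
   the oriented incidence matrix and the hop count as ground metric. This
   formulation has $m$ (edge-count) variables instead of the $n^2$ of the
   classical coupling LP — decisive on sparse biological networks. The
   coupling LP and the Kantorovich dual
   ($\max_f f\cdot(\rho^0-\rho^1)$ s.t. $|f_i - f_j| \le 1$ on edges) are
   implemented as independent cross-checking oracles.

4. **Cohort analysis.** The symmetric pairwise $W_1$ matrix is binarized
   at a threshold (0 where distance < threshold), clusters are the
   connected components of the resulting closeness graph, and a sample is
   an outlier when its mean distance to the rest exceeds the cohort mean
   by $k$ standard deviations (default $k=2$).

## Worked example

```python
import numpy as np
from graphemd import *

net = GeneNetwork.from_edges([("A", "B"), ("B", "C")])
x = ExpressionProfile("tumor_1", np.array([1.0, 2.0, 3.0]))

P = build_transition_matrix(net, x)       # mass-action walk
pi = stationary_closed_form(net, x)       # invariant measure
print(pi.pi, pi.z)                        # [0.125 0.5 0.375] 16.0

y = ExpressionProfile("tumor_2", np.array([3.0, 2.0, 1.0]))
pi2 = stationary_closed_form(net, y)      # [0.375 0.5 0.125]
d, flow = w1_flux(net, pi, pi2)
print(d, flow.u)                          # 0.5  [-0.25 -0.25]
```

From B's viewpoint neighbor C (expression 3) receives 0.75 of the
probability and A (expression 1) only 0.25; the invariant measure
concentrates on B, the hub. Mirroring the expression vector mirrors the
measure, and turning one into the other means carrying 0.25 of mass from
C to A — two hops, hence $W_1 = 2 \times 0.25 = 0.5$. The negative fluxes
record that the optimal flow runs against both edges' fixed orientations.

A small synthetic cohort, end to end:

```python
spec = CohortSpec(n_nodes=120, edges_per_node=3, group_sizes=(6, 6), seed=11)
network = generate_topology(spec)
cohort = generate_cohort(network, spec)
measures = [stationary_closed_form(network, p) for p in cohort.profiles]
dm = pairwise_distance_matrix(network, measures)
s = cohort_summary(dm, cohort.labels)
print(s.within_mean)        # {'A': 0.1679, 'B': 0.1622, 'outlier': None}
print(s.between_mean)       # 1.2176
print(flag_outliers(dm))    # ['OUT1']
```

Within-group distances (~0.16) are an order of magnitude below the
between-group mean (~1.22), so thresholding the matrix splits the cohort
into the two planted groups, and the planted outlier's extreme mean
distance gets it flagged.

sklearn-style estimators wrap the same pipeline
(`MassActionMeasures` → `GraphWasserstein` → `ThresholdClustering` /
`MeanDistanceOutlierDetector`), composing with sklearn tooling on
precomputed distance matrices.

## Command line

```bash
graphemd simulate --out sim --seed 42                     # synthetic inputs
graphemd prepare  --network sim/network.tsv \
                  --expression sim/expression.tsv \
                  --labels sim/labels.tsv --out run
graphemd distances --prepared run/prepared --out run      # resumable LP stage
graphemd analyze  --distances run/distances.csv \
                  --labels sim/labels.tsv --out run \
                  --thresholds 0.075,0.1
```

`prepare` intersects the network with the expression genes, resolves
duplicate identifiers, and keeps the largest connected component;
`distances` checkpoints every solved pair so an interrupted run resumes
without re-solving; `analyze` writes binarized matrices, cluster
assignments, group summaries, outlier calls, heat maps and histograms.

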