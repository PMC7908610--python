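# Methods

This note documents the models and procedures implemented in `healthnet`,
the conventions adopted where several were defensible, and what the synthetic
generator does and does not emulate.

## Gravity model

The directed attraction from region *i* to region *j* is

    Y_ij = K_ij · ∛(P_i H_i G_i) · ∛(P_j H_j G_j) / (D_ij / (g_i − g_j))²,
    K_ij = R_i / (R_i + R_j),

with *P* medical visits, *H* total health expenditure, *G* GDP, *g* GDP per
capita, *R* tertiary-hospital count and *D* inter-capital distance. Units
cancel only inside each factor, so *Y* is treated as a dimensionless score;
all comparisons are within-row, so only relative magnitudes matter.

Conventions:

* The cube root is taken of the **product** P·H·G (the standard composite
  "mass" reading), not of each factor separately.
* The squared composite distance makes the sign of `g_i − g_j` irrelevant;
  `g_i = g_j` is an **error** by default because the economic distance
  vanishes. An optional `economic_distance_floor` substitutes a small ε for
  |g_i − g_j| when a user's data genuinely contains ties; the synthetic
  generator instead guarantees pairwise-distinct *g*.
* `K_ij` is undefined when `R_i + R_j = 0` (raised as an error). `R_i = 0`
  with `R_j > 0` is legal and gives `Y_ij = 0`.
* Self-gravity `Y_ii` is undefined (zero geographic and economic distance);
  the diagonal is fixed at 0 and excluded from all row statistics.

**Binarization.** Row *i*'s benchmark is the arithmetic mean of its N−1
off-diagonal gravity values; `m_ij = 1` iff `Y_ij ≥ t_i` (ties meet the
benchmark, so a row of equal values keeps every arc). Because the benchmark
scales with the row, multiplying a row by a positive constant never changes
the binary network, and every row with a positive entry keeps at least one
arc — no province is isolated by construction.

The arc `i → j` is read as *i*'s health economy orienting toward *j*
(patient outflow direction). Hence in-degree > out-degree marks a **benefit**
province, out-degree > in-degree a **spillover** province, equality
**balance**.

## Whole-network indices

All four are Krackhardt's graph-theoretical dimensions, each in [0, 1]:

* **Density** `L / (N(N−1))` over ordered pairs.
* **Connectedness** `1 − V / (N(N−1)/2)`, V = unordered pairs with no path
  in the underlying undirected graph.
* **Hierarchy** `1 − (symmetrically reachable ordered pairs) / (reachable
  ordered pairs)` on directed reachability. A digraph whose reachability is
  symmetric (any cycle) scores 0; an out-tree scores 1. When no pair is
  reachable the reachability relation is trivially symmetric and the index
  is defined as 0.
* **Efficiency** on the underlying undirected graph:
  `1 − M / max(M)` with `M = Σ_components (edges − (n_c − 1))` and
  `max(M) = Σ_components (n_c(n_c−1)/2 − (n_c−1))`. A forest scores 1 (also
  when `max(M) = 0`, i.e. all components have ≤ 2 nodes).

## Centrality

* **Degree centrality** `100 · |out-neighbors ∪ in-neighbors| / (N−1)`:
  distinct alters, so a reciprocated tie counts once. This is the only
  counting rule consistent with combining separate in/out-degrees into a
  single percent.
* **Closeness** `100 · (N−1) / Σ_j d_ij`. Default mode is **symmetrized**
  (geodesics on the underlying undirected graph, the convention of the
  classic UCINET workflow on a connected symmetrization); a `directed` mode
  is available. A node with any unreachable alter gets NaN rather than a
  rescaled score — the measure presumes a connected network.
* **Betweenness** `100 · Σ_{j<k} b_jk(i) / ((N²−3N+2)/2)` in symmetrized
  mode, where `b_jk(i)` is the fraction of j–k geodesics with *i* interior;
  the directed variant divides by `(N−1)(N−2)` over ordered pairs. Geodesic
  computations are delegated to networkx; the test suite cross-checks them
  against a hand-written brute-force path enumerator on all small graphs.
* **Ranks** are dense (ties share a rank, no gaps) on values rounded to the
  3-decimal printing precision, so provinces that print identically rank
  identically.

## CONCOR blockmodel

Each node's profile is its row and column of the adjacency. The initial
correlation between nodes *i* and *j* is the Pearson correlation of their
profiles **restricted to the other N−2 nodes** (both diagonal entries and
the mutual ties are excluded pairwise). This is the classical
structural-equivalence treatment; it is exactly invariant to node
relabeling, which a fixed-length "row plus column minus own diagonal"
concatenation is not (the coordinates of two such profiles misalign).
Zero-variance profiles correlate 0 with a warning.

The correlation matrix is then repeatedly replaced by the correlation matrix
of its own columns until every off-diagonal entry is within the
`criterion` of ±1 (`|c| ≥ 1 − criterion`; default criterion 0.2, the value
passed through from the published UCINET setting) or `max_iter = 25` is
reached, and nodes split by the sign of the converged first row. The split
is deterministic given input order; when iteration stops before a clean
±1 block structure emerges, the two-part assignment can depend on node
order — on structured (convergent) inputs it is order-invariant, and the
test suite verifies recovery of planted partitions and 2-level hierarchies.

Recursion applies the same split to the submatrix of the **original**
adjacency restricted to each part, to the requested depth (default 2 → up
to 4 blocks); parts of size < 2, or parts the split fails to separate, stay
whole. Blocks are numbered contiguously from 1 in depth-first split order.

### Block accounting and roles

For each block: arcs are tallied inside/outside by source and target;
`expected_ratio = 100(n_b − 1)/(N − 1)` is the internal share a member's
ties would have if ties ignored block structure, and
`actual_ratio = 100 · send_inside/(send_inside + send_outside)` the realized
share. The four-way role rule (with E, Ax the expected and actual ratios,
r, s the external receive/send counts, θ = 2, ρ = 0.3):

1. `Ax ≥ E` and `r > θ·s` → **net_beneficial**;
2. `Ax ≥ E` and both r and s above the mean external flow across blocks →
   **bidirectional_spillover**;
3. `Ax < E` and `r ≥ ρ·s` → **broker**;
4. otherwise → **net_spillover**.

The rule is a codification of qualitative role descriptions, and blocks near
a boundary (a beneficiary that also sends moderately; a pure source whose
return flow just clears ρ) can legitimately be read either way — this is why
`role_overrides` accepts explicit per-block labels, and why downstream use
should treat the labels as interpretive, not as a statistic.

### Density, image and fit

`density[a][b]` = realized fraction of possible a→b arcs (`n_a·n_b`
off-diagonal, `n_a(n_a−1)` diagonal; a singleton block's internal density is
reported as 0 with a warning). The image matrix is 1 where density strictly
exceeds the cutoff, which defaults to the whole-network density. `fit_r2` is
the squared Pearson correlation between the off-diagonal adjacency entries
and the density of their block pair — the usual blockmodel goodness-of-fit;
it depends only on the block-level arc counts, not on where individual arcs
fall within a block pair.

## Synthetic generator

The generator emulates a 2017-style Chinese provincial system at these
default magnitudes (chosen once as field-realistic):

| quantity | distribution | unit |
|---|---|---|
| population | LogNormal(log 3500, 0.6) | 10⁴ persons |
| GDP G | LogNormal(log 20000, 0.8) | 10⁸ CNY |
| health expenditure H | 0.06 · G · LogNormal(0, 0.2) | 10⁸ CNY |
| visits P | 4.5 · population · LogNormal(0, 0.15) | 10⁴ visits |
| hospitals R | 1 + Poisson(60 · G / 20000) | count |
| g | G / population · LogNormal(0, 0.01), nudged pairwise distinct | 10⁴ CNY |
| coordinates | uniform on the unit square | — |

Under `core_periphery`, 25% of provinces (at least one) have G and H
multiplied by 3 (which also triples their expected R and their g) and their
capitals clustered in a disc of radius 0.08 — a stylized east-coast core.
Distance decay then reinforces core attraction: across seeds the core's mean
in-degree exceeds the periphery's, and most benefit-classified provinces are
core.

What the generator does **not** emulate: real geography (actual inter-capital
distances and coastal adjacency), serial dependence across years, reporting
artifacts in yearbook data, and any within-province heterogeneity. Passing
tests on synthetic systems therefore validate the *mechanics* of the pipeline
and the qualitative core-periphery signal, not the published point values
for 2017, which depend on the unpublished raw attribute table.

## Published reference tables and the rebuilt 2017 network

The packaged fixtures transcribe the published per-province centrality
table, block accounting, inter-block density/image matrices, block
membership, and the province population/bed-utilization table. Multiplying
the published inter-block densities by each block pair's arc capacity
(block sizes 3/5/12/11) recovers an integer arc-count matrix whose margins
reproduce the published send/receive totals and the 209-arc total exactly.
`reconstructed_network()` realizes these counts as a concrete digraph
(deterministic fill, or shuffled within block pairs by seed). Every
block-level statistic — density 0.2247, mean degree 6.742, expected ratios
6.667/13.333/36.667/33.333%, actual ratios 22.222/22.222/6.849/1.220%,
18 internal vs 191 inter-block arcs, the full image matrix, and the
blockmodel fit R² = 0.434 — is invariant to the within-block-pair placement
and is recomputed from this network by the acceptance script. Path-based
quantities (hierarchy, efficiency, closeness, betweenness) are **not**
determined by block-level counts and are deliberately not claimed for the
rebuilt network.

## Numerical choices and problem sizes

* Row benchmarks compare with ≥, so exact ties produce arcs.
* Percentages are written to 3 decimals and [0,1] indices to 4 in report
  CSVs; in-memory values keep full precision; matrix CSVs round-trip at 15
  significant digits.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  configuration and seed give byte-identical output files.
* Test and acceptance runs use 31-province systems for pipeline checks,
  N ≤ 5 exhaustive-style draws (500) for the centrality brute-force
  cross-check, 20-node planted partitions (20 seeds) for CONCOR recovery,
  and 10 seeds for the core-periphery inflow property.

## Known limitations

* The gravity kernel is fixed; no exponential-decay or calibrated power-law
  variants.
* CONCOR is the only equivalence clustering offered (no REGE, no
  optimization blockmodeling), and its two-part sign split inherits the
  classical method's order sensitivity on non-convergent inputs.
* The role typology is heuristic by construction; see above.
* Closeness in directed mode is withheld (NaN) for any node with
  unreachable alters rather than using a harmonic or component-scaled
  variant.
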