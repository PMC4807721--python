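# Methods

This note documents the models, metric conventions, numerical choices and
known limitations of `connectogen`, in the spirit of the methods sections
that accompany simulation packages.

## Spatial embedding

Nodes receive independent uniform positions in a cube of side 7 mm
(configurable).  This side length is a stand-in for a real rodent-brain
parcellation: the inter-nodal distance distribution of a 7 mm cube closely
resembles that of region centroids at mesoscale, and models run on either
embedding behave comparably.  Coordinates may instead be loaded from a CSV
(`node_id,x,y,z`, millimetres, 0-based contiguous ids).  Coincident points
are not excluded — a probability-zero event under the continuous draw, and
harmless to every algorithm (a zero distance just maximizes the attachment
weight).

All randomness flows through explicitly passed `numpy.random.Generator`
objects; no function touches global RNG state.  Ensemble runs derive child
seeds (< 2³¹) from one master seed via `SeedSequence`, with a per-model
offset so that adding a model to an experiment does not shift the streams
of the others.

## Growth models

Every model adds one edge per step until `K` edges exist.  The shared
machinery:

* **Attachment weights.**  `exp(−d/L)` with `d` the Euclidean distance in
  mm.  With `d ≤ 7√3 ≈ 12.1 mm` and `L ≥ 0.1 mm` the most negative
  exponent is ≈ −121, comfortably representable in double precision, so
  weights are formed directly and normalized by their sum at each draw
  (no log-space tricks needed).  `L = inf` means uniform weights and is
  how the purely topological SG/TA variants are implemented.
* **Self-connections.**  Degree-weighted variants (SGPA, TAPA,
  total-degree) initialize every node with one self-connection so that a
  node with no real edges still has selection weight 1.  Self-connections
  contribute one to the relevant degrees during growth but are excluded
  from `K`, from the emitted edge set, and from every metric.
* **Saturation.**  A node that already connects to all `n − 1` others (the
  self-connection not counting) is excluded from source selection, which
  is exactly the condition under which target selection would find no
  available partner; this makes deadlock impossible and forced completions
  (e.g. n=3, K=3 undirected must be the triangle) exact.
* **Duplicate suppression.**  The weight of an already-present edge is
  zero, implemented by zeroing entries of a masked weight matrix as edges
  form; each categorical draw is an O(n) cumulative sum + binary search.

Model-specific rules:

* **PA (undirected / directed)** — source uniform among unsaturated nodes;
  partner `∝ exp(−d/L)` among non-linked nodes.  The undirected variant
  forbids duplicate unordered pairs and targets `K = 7804` pairs; the
  directed variant forbids only the identical ordered pair and targets
  `K = 8820` edges.
* **SGPA** — source `∝ k_out` (self-connection included) among nodes below
  maximal out-degree, then target as in PA.
* **TAPA** — the exact mirror: target `∝ k_in`, then source
  `∝ exp(−d/L)`.  Because Euclidean distance is symmetric this is
  distributionally identical to SGPA with every edge reversed, and is
  implemented that way.  One consequence worth knowing: the *mean* nodal
  efficiency of a graph equals that of its transpose (the sum of inverse
  directed distances over ordered pairs is transpose-invariant), so SGPA
  and TAPA ensembles share that statistic exactly — consistent with their
  reported near-identical values.
* **Total-degree SGPA** — source `∝ (k_in + k_out)^γ` (self-connection
  contributes one to each).  `γ = 0` recovers directed PA; `γ = 1` and
  `γ = 1.67` produce increasingly correlated in/out degrees.
* **SG / TA only** — SGPA / TAPA with uniform partner choice (`L = inf`).
* **Node-by-node SGPA** — nodes arrive sequentially with uniform cube
  positions, each instantiated with a self-connection.  From the second
  arrival onward every existing edge — self-connections included —
  independently branches with probability `p_branch = 0.016`; a branch
  keeps its source and draws a target `∝ exp(−d/L)` over the nodes present
  (source excluded); a branch that duplicates an existing edge is
  discarded.  After growth, nodes outside the giant undirected component
  (typically a handful) are removed.  The self-connection branching is the
  bootstrap: before any real edge exists, nothing else could branch.  Of
  the candidate readings of the branching rule, this is the only one whose
  final edge count lands near 8820 at the default parameters (≈ 8.5k on
  average; including the source in the target weights gives ≈ 5.3k because
  the zero-distance self weight dominates and is always discarded, and
  renormalizing over free targets instead of discarding gives ≈ 35k).
  The final edge count is stochastic by construction.

## Reference graphs

Generated with networkx.  `k_sw` counts ring-lattice neighbours **per
side**, so the small-world graph `watts_strogatz_graph(n, 2·k_sw, p)` has
initial degree `2·k_sw = 36` at the default — matching the mean undirected
degree 2·7804/426 ≈ 36.6 of a connectome-scale graph.  This per-side
reading, rather than total initial degree 18, is the one that reproduces
all three published small-world summary metrics (clustering ≈ 0.359, path
length ≈ 2.13, efficiency ≈ 0.507) at p = 0.23; total-degree-18 gives
0.333 / 2.63 / 0.41.  The classic, possibly disconnecting rewiring is
used; path-length statistics fall back to reachable pairs with a warning.

The scale-free graph is Barabási–Albert with attachment count 18
(networkx convention: growth seeded by a star on `k_sf + 1` nodes).  The
directed Erdős–Rényi graph includes each ordered pair independently with
p = 0.0487, matching 8820 directed edges in expectation.

The undirected degree-preserving shuffle uses networkx double-edge swaps
(default 10 × edge-count attempts, a standard mixing heuristic) and
conserves the degree sequence exactly.  The directed shuffle re-pairs
source and target stubs by whole-array permutation; stubs whose pairing
would create a self- or duplicate connection are re-permuted among
themselves for at most 20 rounds and then discarded, so the in/out
sequences are conserved only up to the few lost edges (about 5% at
connectome density in a single pass; far less after the bounded retries).

## Metric conventions

* Undirected metrics (clustering, characteristic path length, global
  efficiency) are computed on the **undirected cast**: an undirected edge
  wherever at least one direction exists.
* Clustering is undefined (NaN) for nodes with undirected degree < 2 and
  such nodes are excluded from averages and fits.
* Characteristic path length averages over reachable ordered pairs and
  warns if the cast is disconnected; efficiencies assign unreachable pairs
  a contribution of zero, so a node with no outgoing edges has nodal
  efficiency exactly 0.
* **Reciprocity** is the number of reciprocated unordered pairs divided by
  the undirected edge count, equivalently `(K_dir − K_und)/K_und`.  A
  literal ordered-pair sum would count each reciprocated pair twice and
  double the value; the unordered convention is the one consistent with
  reported connectome values (e.g. 0.13 from 8820 directed / 7804
  undirected edges).
* **Clustering–degree power law**: per-graph unweighted OLS of `log10 C_i`
  on `log10 k_i` over nodes with `k ≥ 2` and `C > 0` (zeros have no
  logarithm); ensembles report the mean exponent and the median R².
* **Per-node mean edge length** is the mean Euclidean length of a node's
  *outgoing* edges (`mean_projection_length`).  The choice is not forced:
  averaging over undirected-cast edges, over all incident directed edges,
  or over outgoing edges are all defensible, and they give systematically
  different clustering–edge-length correlations in SGPA ensembles
  (median Spearman ρ ≈ −0.56, −0.54 and −0.44 respectively at the default
  scale).  The outgoing reading is adopted because in anterograde-tracer
  data a region's measured edges are its outgoing projections; note that
  published values for this correlation can plausibly sit anywhere in the
  above range depending on the convention.
* The reciprocal/nonreciprocal edge-length comparison uses the
  pooled-variance two-sample t statistic and Cohen's d with the pooled
  standard deviation; if either sample has fewer than two edges the
  statistics are NaN.

## Lesioning

Targeted attack operates on the undirected cast: repeatedly remove the
highest-degree node, with ties broken uniformly at random under a passed
seed, and record giant-component size, global efficiency and connection
density of the remaining induced subgraph (denominators use the remaining
node count; density is NaN below two nodes).  Degrees are re-ranked after
every removal by default; `recompute=False` freezes the initial ranking,
since published attack analyses do not always state which was used.  The
trace includes the intact state, so it has `n + 1` rows.

## Tracer tables and mirroring

A tracer table lists projections from one hemisphere's regions into both
hemispheres (`ipsi:`/`contra:` prefixes on targets).  Binarization keeps
projections with `p < threshold` (strict inequality) and mirrors them
under bilateral symmetry into the block adjacency `[[X, Y], [Y, X]]`,
giving 2m nodes with an empty diagonal; the result is invariant under the
hemisphere-swap permutation, and thresholding commutes with mirroring.
Self-projections are dropped at load.  The fixture generator plants
unordered region pairs (a configurable fraction cross-hemispheric),
marking a planted pair reciprocal with the frequency needed to hit a
requested reciprocity, and adds an equal number of non-significant decoy
rows; it hits requested edge counts and reciprocities within ~1% at
connectome scale.  Fixture tables are synthetic stand-ins; they share only
the schema, not any measured connectivity.

## What the synthetic world does and does not establish

Generated ensembles reproduce model-side statistics exactly as defined
(they *are* the model), so green ensemble tests establish correctness of
the algorithms and metrics, not anything about real anatomy.  Statistics
of real connectomes (empirical clustering, in/out distributions, the
empirical reciprocity or its power-law exponent) require real tracer data,
which this package deliberately does not ship or download; the metric
calls support such data once a user supplies a tracer table or adjacency.

## Known limitations

* Growth occupies a static space; tissue growth in an expanding space is
  out of scope.
* Connection strengths are binary; weighted generalizations are not
  implemented.
* The node-by-node variant's youngest nodes have very low degree and
  degenerate clustering, as expected for late arrivals under branching
  growth.
* The directed shuffle conserves degree sequences only approximately
  (discarded conflicting stubs), by design.
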