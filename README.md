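# connectogen

Generative growth models for spatially embedded directed brain networks,
together with the graph-metric suite, reference null graphs and
targeted-attack lesioning analysis used to evaluate them.

## The scientific problem

Mesoscale connectomes — directed connectivity maps among anatomically
defined brain regions — show structure that standard random graphs fail to
capture: broad out-degree but narrow in-degree distributions, above-chance
reciprocity, low-degree nodes that are highly clustered, and strong
dependence of connectivity on physical distance.  `connectogen` implements
a family of growth models that reproduce these features from two simple
rules, and the statistics needed to test them:

* **Proximal attachment (PA).**  The partner of a new edge is chosen with
  probability decaying exponentially in Euclidean distance,
  `P(target = j | source = i) ∝ exp(−d_ij / L)`, with a single length
  constant `L` (mm).  Nodes are embedded in a cube (7 mm side by default)
  or at user-supplied coordinates.
* **Source growth (SG).**  The source of each new directed edge is chosen
  proportionally to its current out-degree, `P(source = i) ∝ k_i^out` — a
  rich-get-richer rule for outgoing connections.  **Target attraction
  (TA)** is the exact mirror on in-degree.

Combining the rules gives the **SGPA** and **TAPA** models; variants
include purely geometric PA (directed or undirected), purely topological
SG/TA, source selection by total degree raised to a power
(`P ∝ (k_in + k_out)^γ`), and a sequential node-by-node version in which
existing edges branch with a fixed probability as nodes arrive.  All
growth runs until `K` edges exist (8820 directed / 7804 undirected at the
connectome-matched scale of n = 426 nodes) and is bit-reproducible from a
seed.

The metric suite implements undirected clustering `C_i = 2t_i/(k_i(k_i−1))`,
characteristic path length, global efficiency (mean inverse undirected
shortest-path length), directed nodal efficiency
`E_i = (1/(n−1)) Σ_j 1/d_ij`, the reciprocity coefficient (fraction of
connected node pairs linked in both directions), clustering–degree
power-law fits `C ∝ k^γ`, reciprocal/nonreciprocal edge-length statistics,
and targeted-attack robustness curves (giant component, efficiency,
density under removal of highest-degree nodes).  Comparison graphs —
Watts–Strogatz small-world, Barabási–Albert scale-free, directed
Erdős–Rényi and degree-preserving shuffles — are built through networkx.
A tracer-table module binarizes projection tables at a p-value threshold
and mirrors them bilaterally into a 2m × 2m adjacency, with a synthetic
fixture generator standing in for real atlas data.

## Worked example

```python
from connectogen import GrowthParams, grow_sgpa, compute_report

g = grow_sgpa(GrowthParams(n=426, K=8820, L=0.725, seed=1))
rep = compute_report(g)
print(f"edges: {g.n_edges}")
for k, v in rep.scalars().items():
    print(f"{k}: {v:.3f}")
```

prints

```
edges: 8820
mean_clustering: 0.351
characteristic_path_length: 2.157
global_efficiency: 0.503
mean_nodal_efficiency: 0.383
reciprocity: 0.129
density_directed: 0.049
density_undirected: 0.086
```

One SGPA network at the connectome-matched scale: 8820 directed edges on
426 nodes (density ≈ 4.9%), about 13% of connected node pairs reciprocal
— the length constant L = 0.725 mm is the value at which the model's
reciprocity matches a mesoscale connectome's — clustering far above the
≈ 0.09 expected for a density-matched random graph, and short undirected
paths (≈ 2.2 hops on average).  Ensemble means over many seeds are
available through `connectogen.experiments` or the CLI:

```bash
connectogen table1 --repeats 20 --seed 0 --out-dir out/
connectogen sweep-reciprocity --repeats 20 --seed 0 --out-dir out/
connectogen grow --model TAPA --n 426 --k 8820 -L 0.725 --seed 3 --out-dir out/
```

## Acceptance script

`scripts/acceptance.py` regrows the model ensembles from scratch and
recomputes the headline ensemble statistics: mean SGPA/TAPA reciprocity at
L = 0.725 mm, the mean clustering-vs-degree power-law exponent for the
SGPA and purely geometric PA models, mean nodal efficiency for SGPA, PA
and directed Erdős–Rényi ensembles, and the median Spearman correlation
between clustering and mean projection length in SGPA.  Run it from the
repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes under a minute on one CPU and writes one JSON object with a
`value` and problem size `n` per statistic.

## Layout

```
src/connectogen/
  spatial.py        node coordinates, distances, coordinate CSV I/O
  growth.py         PA / SGPA / TAPA / SG / TA / total-degree / node-by-node
  reference.py      small-world, scale-free, directed ER, shuffles
  metrics.py        degrees, clustering, efficiencies, reciprocity, fits
  lesioning.py      targeted-attack robustness traces
  connectome_io.py  tracer tables, binarization, bilateral mirroring
  experiments.py    seeded ensemble experiments (tables, sweeps)
  cli.py            `connectogen` command-line interface
docs/methods.md     model and metric definitions, numerical choices
tests/              pytest suite (unit, property and ensemble-level tests)
```
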