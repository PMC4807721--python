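"""Generative growth models for spatially embedded directed networks.

All models add edges one at a time until a target edge count ``K`` is
reached, combining up to two rules:

* **proximal attachment (PA)** — the partner of a new edge is chosen with
  probability proportional to ``exp(-d/L)`` where ``d`` is the Euclidean
  distance between the two nodes and ``L`` a length constant in mm;
* **source growth (SG)** — the source of a new directed edge is chosen
  proportionally to its current out-degree ("rich get richer" for outgoing
  connections); **target attraction (TA)** is the exact mirror, selecting
  the target proportionally to in-degree.

Degree-weighted variants (SGPA, TAPA, SG/TA-only, total-degree SGPA)
initialize every node with one self-connection so that zero-degree nodes
retain a nonzero selection probability.  Self-connections count one toward
each degree during growth but are excluded from ``K``, from the emitted
edge set and from every metric.

A node is *saturated* when it already sends (receives) edges to (from) all
``n - 1`` other nodes; saturated nodes are excluded from source (target)
selection so growth cannot deadlock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from connectogen.graph import DirectedSpatialGraph
from connectogen.spatial import pairwise_distances, sample_cube_positions
from connectogen.utils import as_rng


class Variant(str, Enum):
    PA_UNDIRECTED = "PA_UNDIRECTED"
    PA_DIRECTED = "PA_DIRECTED"
    SGPA = "SGPA"
    TAPA = "TAPA"
    SG_ONLY = "SG_ONLY"
    TA_ONLY = "TA_ONLY"
    TOTAL_DEGREE_SGPA = "TOTAL_DEGREE_SGPA"
    NODE_BY_NODE_SGPA = "NODE_BY_NODE_SGPA"


class SourceSaturatedError(RuntimeError):
    """Raised when a node has no remaining valid partner."""


@dataclass
class GrowthParams:
    """Parameters that fully determine a generated ensemble.

    Attributes
    ----------
    n : node count (>= 2).
    K : target edge count — directed edges for directed variants,
        undirected pairs for ``PA_UNDIRECTED``.  Ignored by the
        node-by-node variant, whose edge count is stochastic.
    L : length constant in mm; ``math.inf`` disables distance dependence.
    variant : which growth rule to run.
    gamma_total : exponent for ``TOTAL_DEGREE_SGPA`` source selection,
        ``P(source=i) ∝ (k_in + k_out)^gamma``.
    p_branch : per-edge branch probability for ``NODE_BY_NODE_SGPA``.
    side : cube side (mm) used when coordinates are sampled internally.
    seed : RNG seed.
    """

    n: int = 426
    K: int = 8820
    L: float = 0.725
    variant: Variant = Variant.SGPA
    gamma_total: float = 1.0
    p_branch: float = 0.016
    side: float = 7.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not (self.L > 0):  # also rejects NaN; inf allowed
            raise ValueError(f"L must be positive (inf allowed), got {self.L}")
        if not (0.0 <= self.p_branch <= 1.0):
            raise ValueError(f"p_branch must lie in [0, 1], got {self.p_branch}")
        cap = self.n * (self.n - 1)
        if self.variant is Variant.PA_UNDIRECTED:
            cap //= 2
        if self.variant is not Variant.NODE_BY_NODE_SGPA and not (0 < self.K <= cap):
            raise ValueError(
                f"K={self.K} outside (0, {cap}] for variant {self.variant.value}"
            )


def _edge_weights(D_row: np.ndarray, L: float) -> np.ndarray:
    """exp(-d/L) weights for one node's distances; uniform when L is inf."""
    if math.isinf(L):
        return np.ones_like(D_row)
    return np.exp(-D_row / L)


def target_selection_probabilities(
    source: int, graph: DirectedSpatialGraph, L: float
) -> np.ndarray:
    """Probability of each node being the target of a new edge from ``source``.

    ``P(target=j | source) ∝ exp(-d_sj / L)`` over nodes ``j != source`` with
    no existing edge ``source -> j``; already-connected targets and the
    source itself get probability zero.  With ``L = inf`` the choice is
    uniform over available targets.

    Raises
    ------
    SourceSaturatedError
        If the source already connects to every other node.
    """
    if not (L > 0):
        raise ValueError("L must be positive (inf allowed)")
    n = graph.n_nodes
    if not 0 <= source < n:
        raise ValueError(f"source {source} out of range for n={n}")
    available = ~graph.adjacency[source]
    available[source] = False
    if not available.any():
        raise SourceSaturatedError(f"node {source} has no available target")
    if math.isinf(L):
        w = available.astype(float)
    else:
        d = np.linalg.norm(graph.coords - graph.coords[source], axis=1)
        w = np.exp(-d / L) * available
    return w / w.sum()


def _resolve_coords(
    params: GrowthParams, coords: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    if coords is None:
        coords = sample_cube_positions(params.n, params.side, rng)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (params.n, 3):
        raise ValueError(f"coords shape {coords.shape} != ({params.n}, 3)")
    return coords


def _masked_weight_matrix(coords: np.ndarray, L: float) -> np.ndarray:
    """exp(-D/L) with the diagonal zeroed; entries are zeroed as edges form."""
    n = coords.shape[0]
    if math.isinf(L):
        W = np.ones((n, n))
    else:
        W = np.exp(-pairwise_distances(coords) / L)
    np.fill_diagonal(W, 0.0)
    return W


def _categorical(cumw: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportional to weights given their cumulative sum."""
    total = cumw[-1]
    if total <= 0:
        raise SourceSaturatedError("no positive selection weight remains")
    return int(np.searchsorted(cumw, rng.random() * total, side="right"))


def _grow_directed_engine(
    params: GrowthParams,
    coords: np.ndarray,
    rng: np.random.Generator,
    source_mode: str,
) -> DirectedSpatialGraph:
    """Shared loop for PA_DIRECTED / SGPA / SG_ONLY / TOTAL_DEGREE_SGPA.

    ``source_mode`` selects the source-weight rule: ``uniform`` (pure PA),
    ``out_degree`` (SG; the self-connection contributes 1), or
    ``total_degree`` (``(k_in + k_out)^gamma``, self-connection contributing
    one to each).  Targets are always drawn from the masked exp(-d/L) row of
    the chosen source.
    """
    n, K = params.n, params.K
    Wmask = _masked_weight_matrix(coords, params.L)
    A = np.zeros((n, n), dtype=bool)
    out_off = np.zeros(n, dtype=np.int64)  # off-diagonal out-degree
    in_off = np.zeros(n, dtype=np.int64)
    for _ in range(K):
        if source_mode == "uniform":
            sw = (out_off < n - 1).astype(float)
        elif source_mode == "out_degree":
            sw = (out_off + 1).astype(float)
            sw[out_off == n - 1] = 0.0
        else:  # total_degree
            sw = (out_off + in_off + 2).astype(float) ** params.gamma_total
            sw[out_off == n - 1] = 0.0
        s = _categorical(np.cumsum(sw), rng)
        t = _categorical(np.cumsum(Wmask[s]), rng)
        A[s, t] = True
        Wmask[s, t] = 0.0
        out_off[s] += 1
        in_off[t] += 1
    return DirectedSpatialGraph(A, coords)


def _grow_pa_undirected(
    params: GrowthParams, coords: np.ndarray, rng: np.random.Generator
) -> DirectedSpatialGraph:
    # Undirected PA: the source is uniform among unsaturated nodes; the
    # target weight of any already-linked pair is zero.  The result is
    # returned as a symmetric DirectedSpatialGraph (both directions set).
    n, K = params.n, params.K
    Wmask = _masked_weight_matrix(coords, params.L)
    U = np.zeros((n, n), dtype=bool)
    deg = np.zeros(n, dtype=np.int64)
    for _ in range(K):
        sw = (deg < n - 1).astype(float)
        s = _categorical(np.cumsum(sw), rng)
        t = _categorical(np.cumsum(Wmask[s]), rng)
        U[s, t] = U[t, s] = True
        Wmask[s, t] = Wmask[t, s] = 0.0
        deg[s] += 1
        deg[t] += 1
    return DirectedSpatialGraph(U, coords)


def grow_pa(
    params: GrowthParams,
    coords: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """Purely geometric proximal-attachment growth.

    A source node is picked uniformly at random; the partner with
    probability ``∝ exp(-d/L)`` among nodes not already linked.
    ``PA_UNDIRECTED`` forbids duplicate unordered pairs and returns a
    symmetric graph; ``PA_DIRECTED`` retains edge direction and forbids
    only the identical ordered pair.
    """
    if params.variant not in (Variant.PA_UNDIRECTED, Variant.PA_DIRECTED):
        raise ValueError(f"grow_pa cannot run variant {params.variant.value}")
    rng = as_rng(rng if rng is not None else params.seed)
    coords = _resolve_coords(params, coords, rng)
    if params.variant is Variant.PA_UNDIRECTED:
        g = _grow_pa_undirected(params, coords, rng)
    else:
        g = _grow_directed_engine(params, coords, rng, "uniform")
    g.meta = _meta(params)
    return g


def grow_sgpa(
    params: GrowthParams,
    coords: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """Source-growth proximal-attachment growth.

    Each step selects a source ``i`` with ``P ∝ k_i^out`` among nodes below
    maximal out-degree (the initial self-connection contributes 1, so new
    nodes stay reachable), then a target ``j`` with ``P ∝ exp(-d_ij/L)``
    among nodes not already targeted by ``i``.  Repeats until ``K`` directed
    edges exist; self-connections are stripped from the output.
    """
    if params.variant is not Variant.SGPA:
        raise ValueError(f"grow_sgpa cannot run variant {params.variant.value}")
    rng = as_rng(rng if rng is not None else params.seed)
    coords = _resolve_coords(params, coords, rng)
    g = _grow_directed_engine(params, coords, rng, "out_degree")
    g.meta = _meta(params)
    return g


def grow_tapa(
    params: GrowthParams,
    coords: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """Target-attraction proximal-attachment growth.

    Exact mirror of SGPA: the target is selected ``∝ k^in`` among nodes
    below maximal in-degree, then the source ``∝ exp(-d/L)`` among nodes
    without an existing edge to that target.  Because Euclidean distance is
    symmetric, this equals SGPA growth with all edges transposed, which is
    how it is implemented.
    """
    if params.variant is not Variant.TAPA:
        raise ValueError(f"grow_tapa cannot run variant {params.variant.value}")
    rng = as_rng(rng if rng is not None else params.seed)
    coords = _resolve_coords(params, coords, rng)
    g = _grow_directed_engine(params, coords, rng, "out_degree")
    out = DirectedSpatialGraph(g.adjacency.T.copy(), coords, _meta(params))
    return out


def grow_nonspatial(
    params: GrowthParams,
    coords: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """Purely topological source-growth / target-attraction growth.

    Identical to SGPA / TAPA except the partner is chosen uniformly among
    available nodes — equivalent to ``L = inf``.  Coordinates are still
    attached (sampled if absent) so that spatial metrics remain defined.
    """
    if params.variant not in (Variant.SG_ONLY, Variant.TA_ONLY):
        raise ValueError(f"grow_nonspatial cannot run variant {params.variant.value}")
    rng = as_rng(rng if rng is not None else params.seed)
    coords = _resolve_coords(params, coords, rng)
    inner = GrowthParams(
        n=params.n, K=params.K, L=math.inf,
        variant=Variant.SGPA, side=params.side,
    )
    g = _grow_directed_engine(inner, coords, rng, "out_degree")
    if params.variant is Variant.TA_ONLY:
        g = DirectedSpatialGraph(g.adjacency.T.copy(), coords)
    g.meta = _meta(params)
    return g


def grow_total_degree_sgpa(
    params: GrowthParams,
    coords: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """SGPA with source selection ``P(source=i) ∝ (k_i^out + k_i^in)^gamma``.

    The self-connection contributes one to each degree.  ``gamma_total=0``
    reduces to directed PA in distribution; the values 1 and 1.67 induce
    increasingly strong in/out-degree correlation.
    """
    if params.variant is not Variant.TOTAL_DEGREE_SGPA:
        raise ValueError(
            f"grow_total_degree_sgpa cannot run variant {params.variant.value}"
        )
    rng = as_rng(rng if rng is not None else params.seed)
    coords = _resolve_coords(params, coords, rng)
    g = _grow_directed_engine(params, coords, rng, "total_degree")
    g.meta = _meta(params)
    return g


def grow_node_by_node_sgpa(
    params: GrowthParams,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """Sequential-addition SGPA: nodes arrive one at a time and edges branch.

    Nodes are added with uniform cube positions until ``n`` exist.  Each
    node is instantiated with a self-connection (the bootstrap: before any
    real edge exists, only self-connections can branch).  On every addition
    from the second onwards, each existing edge — self-connections included
    — independently branches with probability ``p_branch``; a branch keeps
    its source and draws a new target ``∝ exp(-d/L)`` over the nodes present
    so far (the source itself excluded).  If the drawn edge already exists
    the branch is discarded.  After growth, nodes outside the giant
    undirected component are removed (typically only a few), so the output
    node count can be slightly below ``n`` and the edge count is stochastic
    (~8820 at the default n=426, L=0.725 mm, p_branch=0.016).
    """
    if params.variant is not Variant.NODE_BY_NODE_SGPA:
        raise ValueError(
            f"grow_node_by_node_sgpa cannot run variant {params.variant.value}"
        )
    rng = as_rng(rng if rng is not None else params.seed)
    n = params.n
    # positions are drawn node-by-node; a single upfront draw is equivalent
    coords = sample_cube_positions(n, params.side, rng)
    W = _masked_weight_matrix(coords, params.L)  # diagonal zero: no self target
    A = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(A, True)  # self-connections, stripped at the end
    sources = [0]  # source node of every edge, self-connections included
    for t in range(1, n):
        src_arr = np.asarray(sources)
        branching = np.nonzero(rng.random(len(src_arr)) < params.p_branch)[0]
        for e in branching:
            s = int(src_arr[e])
            cumw = np.cumsum(W[s, : t + 1])  # nodes present, newcomer included
            if cumw[-1] <= 0:
                continue
            j = _categorical(cumw, rng)
            if not A[s, j]:
                A[s, j] = True
                sources.append(s)
        sources.append(t)  # the new node's self-connection
    np.fill_diagonal(A, False)
    keep = _giant_component_nodes(A | A.T)
    g = DirectedSpatialGraph(A[np.ix_(keep, keep)], coords[keep], _meta(params))
    g.meta["n_removed_outside_giant"] = int(n - keep.size)
    return g


def _giant_component_nodes(U: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(csr_matrix(U), directed=False)
    counts = np.bincount(labels)
    return np.nonzero(labels == counts.argmax())[0]


_GROWERS = {
    Variant.PA_UNDIRECTED: grow_pa,
    Variant.PA_DIRECTED: grow_pa,
    Variant.SGPA: grow_sgpa,
    Variant.TAPA: grow_tapa,
    Variant.SG_ONLY: grow_nonspatial,
    Variant.TA_ONLY: grow_nonspatial,
    Variant.TOTAL_DEGREE_SGPA: grow_total_degree_sgpa,
}


def grow(
    params: GrowthParams,
    coords: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedSpatialGraph:
    """Dispatch to the grower for ``params.variant``."""
    if params.variant is Variant.NODE_BY_NODE_SGPA:
        if coords is not None:
            raise ValueError("node-by-node growth samples its own coordinates")
        return grow_node_by_node_sgpa(params, rng)
    return _GROWERS[params.variant](params, coords, rng)


def _meta(params: GrowthParams) -> dict:
    d = {k: getattr(params, k) for k in
         ("n", "K", "L", "gamma_total", "p_branch", "side", "seed")}
    d["variant"] = params.variant.value
    return d
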