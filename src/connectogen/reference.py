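"""Standard comparison graphs: small-world, scale-free, directed ER, shuffles.

Constructions delegate to networkx; the parameter defaults reproduce the
usual connectome-matched settings (n = 426; k = 18 to match mean degree /
edge count; Watts–Strogatz rewiring p = 0.23 to match mean clustering;
directed Erdős–Rényi edge probability 0.0487 to match the directed edge
count in expectation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from connectogen.graph import GraphLike, as_adjacency
from connectogen.utils import as_rng


@dataclass
class ReferenceParams:
    """Parameters for the standard comparison graphs.

    ``k_sw`` counts ring-lattice neighbours *per side*, so the initial
    small-world degree is ``2 * k_sw`` — with the default 18 that is 36,
    matching the mean undirected degree of a 426-node, 7804-edge
    connectome (2·7804/426 ≈ 36.6).
    """

    n: int = 426
    k_sw: int = 18          # ring-lattice neighbours per side (degree 2*k_sw)
    p_rewire: float = 0.23  # Watts-Strogatz rewiring probability
    k_sf: int = 18          # Barabasi-Albert attachment count
    p_er: float = 0.0487    # directed ER edge probability
    n_swaps: int | None = None  # shuffle swap attempts; default 10x edges
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < 2 * self.k_sw < self.n):
            raise ValueError(f"need 0 < 2*k_sw < n; got k_sw={self.k_sw}")
        if not (0.0 <= self.p_rewire <= 1.0):
            raise ValueError(f"p_rewire must lie in [0, 1], got {self.p_rewire}")
        if not (1 <= self.k_sf < self.n):
            raise ValueError(f"k_sf must lie in [1, n), got {self.k_sf}")
        if not (0.0 < self.p_er < 1.0):
            raise ValueError(f"p_er must lie in (0, 1), got {self.p_er}")


def _int_seed(seed) -> int | None:
    # networkx accepts ints or numpy Generators directly
    return seed


def small_world_graph(params: ReferenceParams) -> nx.Graph:
    """Watts–Strogatz ring-lattice rewiring graph with degree ``2 * k_sw``.

    The classic (possibly disconnecting) rewiring is used; path-length
    statistics on a disconnected instance fall back to reachable pairs.
    """
    return nx.watts_strogatz_graph(
        params.n, 2 * params.k_sw, params.p_rewire, seed=params.seed
    )


def scale_free_graph(params: ReferenceParams) -> nx.Graph:
    """Barabási–Albert preferential attachment; minimum degree ``k_sf``."""
    return nx.barabasi_albert_graph(params.n, params.k_sf, seed=params.seed)


def directed_er_graph(params: ReferenceParams) -> nx.DiGraph:
    """Directed Erdős–Rényi: each ordered pair present independently w.p. ``p_er``."""
    return nx.fast_gnp_random_graph(params.n, params.p_er, seed=params.seed, directed=True)


def degree_preserving_shuffle(
    graph: GraphLike,
    directed: bool = False,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> nx.Graph | nx.DiGraph:
    """Randomize a graph by repeated double-edge swaps.

    The undirected version uses networkx double-edge swaps and preserves the
    degree sequence exactly (``n_swaps`` attempts, default 10x edges).  The
    directed version randomly re-pairs source and target stubs: all targets
    are permuted against the sources at once, stubs whose pairing would
    create a self- or duplicate connection are re-permuted among themselves
    for a bounded number of rounds, and whatever still conflicts is
    discarded rather than retried indefinitely — so the in/out-degree
    sequences are preserved only up to the few edges lost to self/double
    connections.
    """
    rng = as_rng(seed)
    A = as_adjacency(graph, directed=directed)
    n = A.shape[0]
    if directed:
        edges = np.argwhere(A)
        if len(edges) < 2:
            warnings.warn("graph too small to shuffle; returning a copy", stacklevel=2)
            return nx.from_numpy_array(A, create_using=nx.DiGraph)
        src, tgt = edges[:, 0].copy(), edges[:, 1].copy()
        taken: set[tuple[int, int]] = set()
        kept: list[tuple[int, int]] = []
        for _ in range(20):  # bounded re-pairing rounds
            if src.size == 0:
                break
            tgt = rng.permutation(tgt)
            ok = np.ones(src.size, dtype=bool)
            for i, (s, t) in enumerate(zip(src, tgt)):
                e = (int(s), int(t))
                if s == t or e in taken:
                    ok[i] = False
                else:
                    taken.add(e)
                    kept.append(e)
            src, tgt = src[~ok], tgt[~ok]
        G = nx.DiGraph()
        G.add_nodes_from(range(n))
        G.add_edges_from(kept)
        return G
    # undirected: exact degree-preserving double-edge swap from networkx
    G = nx.from_numpy_array(A)
    n_edges = G.number_of_edges()
    if n_edges < 2 or max(dict(G.degree()).values(), default=0) >= n - 1:
        if n_edges < 2:
            warnings.warn("graph too small to shuffle; returning a copy", stacklevel=2)
            return G
    if n_swaps is None:
        n_swaps = 10 * n_edges
    if n_swaps > 0:
        nx_seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(G, nswap=n_swaps, max_tries=100 * n_swaps, seed=nx_seed)
        except nx.NetworkXError as err:  # e.g. complete graph: no swap possible
            warnings.warn(f"shuffle stopped early: {err}", stacklevel=2)
    return G
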