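"""Targeted-attack lesioning of the undirected cast of a network.

Nodes are removed one at a time in order of decreasing degree (ties broken
uniformly at random with a seeded RNG); after each removal the giant
component size, global efficiency and connection density of the remaining
induced subgraph are recorded.  Degrees are re-ranked after every removal
by default (``recompute=True``); ``recompute=False`` removes nodes in the
order of their initial degrees instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from connectogen.graph import GraphLike, as_adjacency
from connectogen.utils import as_rng


@dataclass
class LesionTrace:
    """Robustness curves recorded during a targeted attack.

    Index 0 is the intact graph; entry ``s`` describes the graph after
    ``s`` removals.  Giant component size and nodes_removed run from the
    intact network down to the empty one.  Density uses the remaining node
    count in its denominator and is NaN once fewer than 2 nodes remain.
    """

    nodes_removed: np.ndarray
    giant_component_size: np.ndarray
    global_efficiency: np.ndarray
    connection_density: np.ndarray
    removal_order: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nodes_removed": self.nodes_removed,
                "giant_component_size": self.giant_component_size,
                "global_efficiency": self.global_efficiency,
                "connection_density": self.connection_density,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _snapshot(U: np.ndarray, alive: np.ndarray) -> tuple[int, float, float]:
    idx = np.nonzero(alive)[0]
    m = idx.size
    if m == 0:
        return 0, 0.0, float("nan")
    sub = U[np.ix_(idx, idx)]
    if m == 1:
        return 1, 0.0, float("nan")
    ncomp, labels = connected_components(csr_matrix(sub), directed=False)
    giant = int(np.bincount(labels).max())
    d = shortest_path(csr_matrix(sub.astype(np.int8)), directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    eff = float(inv.sum() / (m * (m - 1)))
    dens = float(sub.sum() / (m * (m - 1)))  # symmetric matrix: edges*2 / pairs*2
    return giant, eff, dens


def targeted_attack(
    graph: GraphLike,
    recompute: bool = True,
    seed: int | np.random.Generator | None = None,
) -> LesionTrace:
    """Remove highest-degree nodes one at a time and record robustness curves.

    Parameters
    ----------
    graph
        Any graph; the attack runs on its undirected cast.
    recompute
        Re-rank degrees after every removal (default).  With False, the
        removal order is fixed by the intact graph's degrees.
    seed
        Seeds the uniform tie-break among equal-degree nodes.
    """
    U = as_adjacency(graph, directed=False).astype(np.int64)
    n = U.shape[0]
    if n < 2:
        raise ValueError("targeted attack needs at least 2 nodes")
    rng = as_rng(seed)
    alive = np.ones(n, dtype=bool)

    giants, effs, denss = [], [], []
    g0, e0, d0 = _snapshot(U, alive)
    giants.append(g0), effs.append(e0), denss.append(d0)

    if not recompute:
        deg0 = U.sum(axis=1)
        # random tie-break: sort by (degree, random) descending
        order = np.lexsort((rng.random(n), -deg0))
    removal = []
    for step in range(n):
        if recompute:
            deg = U.sum(axis=1).astype(float)
            deg[~alive] = -1.0
            top = deg.max()
            candidates = np.nonzero(deg == top)[0]
            victim = int(rng.choice(candidates))
        else:
            victim = int(order[step])
        alive[victim] = False
        U[victim, :] = 0
        U[:, victim] = 0
        removal.append(victim)
        g, e, d = _snapshot(U, alive)
        giants.append(g), effs.append(e), denss.append(d)

    return LesionTrace(
        nodes_removed=np.arange(n + 1),
        giant_component_size=np.asarray(giants),
        global_efficiency=np.asarray(effs),
        connection_density=np.asarray(denss),
        removal_order=np.asarray(removal),
        meta={"recompute": recompute, "n": n},
    )
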