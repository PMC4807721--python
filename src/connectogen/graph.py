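"""Core graph container shared by the growth models, metrics and lesioning.

A :class:`DirectedSpatialGraph` couples a simple directed edge set (dense
boolean adjacency, no self-loops) with optional node coordinates in
millimetres.  All generators emit one; all metrics consume one (or any
networkx graph / adjacency array, coerced through :func:`as_adjacency`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np

GraphLike = Union["DirectedSpatialGraph", nx.Graph, nx.DiGraph, np.ndarray]


@dataclass
class DirectedSpatialGraph:
    """A simple directed graph with optional spatial embedding.

    Parameters
    ----------
    adjacency
        ``(n, n)`` boolean matrix; ``adjacency[i, j]`` is True iff the
        directed edge ``i -> j`` exists.  The diagonal must be empty:
        self-connections are bookkeeping devices used only during growth and
        never appear in an emitted graph.
    coords
        Optional ``(n, 3)`` array of node positions in millimetres.
    meta
        Free-form provenance (growth parameters, seed, ...).
    """

    adjacency: np.ndarray
    coords: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if A.diagonal().any():
            raise ValueError("self-loops are not allowed in an emitted graph")
        self.adjacency = A
        if self.coords is not None:
            C = np.asarray(self.coords, dtype=float)
            if C.shape != (A.shape[0], 3):
                raise ValueError(
                    f"coords shape {C.shape} does not match {A.shape[0]} nodes"
                )
            if not np.all(np.isfinite(C)):
                raise ValueError("coordinates must be finite")
            self.coords = C

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def edges(self) -> np.ndarray:
        """``(K, 2)`` integer array of directed edges ``(source, target)``."""
        return np.argwhere(self.adjacency)

    def undirected_adjacency(self) -> np.ndarray:
        """Undirected cast: an edge wherever at least one direction exists."""
        return self.adjacency | self.adjacency.T

    def transpose(self) -> "DirectedSpatialGraph":
        return DirectedSpatialGraph(self.adjacency.T.copy(), self.coords, dict(self.meta))

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: np.ndarray | list[tuple[int, int]],
        coords: np.ndarray | None = None,
        meta: dict | None = None,
    ) -> "DirectedSpatialGraph":
        A = np.zeros((n, n), dtype=bool)
        edges = np.asarray(edges, dtype=int)
        if edges.size:
            A[edges[:, 0], edges[:, 1]] = True
        return cls(A, coords, meta or {})

    # -- interop ----------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        G = nx.from_numpy_array(self.adjacency, create_using=nx.DiGraph)
        if self.coords is not None:
            nx.set_node_attributes(
                G, {i: tuple(p) for i, p in enumerate(self.coords)}, "pos"
            )
        return G

    # -- text I/O ---------------------------------------------------------
    def write_edgelist(self, path: str | Path) -> None:
        """One ``i<TAB>j`` line per directed edge, 0-based node ids."""
        path = Path(path)
        with path.open("w") as fh:
            for i, j in self.edges:
                fh.write(f"{i}\t{j}\n")
        if self.meta:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def read_edgelist(
        cls, path: str | Path, n: int | None = None, coords: np.ndarray | None = None
    ) -> "DirectedSpatialGraph":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            i, j = line.split("\t")
            rows.append((int(i), int(j)))
        edges = np.asarray(rows, dtype=int)
        if n is None:
            n = int(edges.max()) + 1 if edges.size else 0
        return cls.from_edges(n, edges, coords)

    def write_adjacency_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.adjacency.astype(int), fmt="%d", delimiter=",")


def as_adjacency(graph: GraphLike, directed: bool = True) -> np.ndarray:
    """Coerce any supported graph object to a boolean adjacency matrix.

    With ``directed=False`` the undirected cast is returned (an edge wherever
    either direction exists).  Networkx graphs use their node insertion
    order; node labels are assumed hashable but arbitrary.
    """
    if isinstance(graph, DirectedSpatialGraph):
        A = graph.adjacency
    elif isinstance(graph, (nx.Graph, nx.DiGraph)):
        A = nx.to_numpy_array(graph, dtype=float) > 0
    else:
        A = np.asarray(graph) != 0
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        A = A.copy()
        np.fill_diagonal(A, False)
    if not directed:
        A = A | A.T
    return A


def get_coords(graph: GraphLike, coords: np.ndarray | None = None) -> np.ndarray:
    """Resolve node coordinates from an explicit argument or the graph itself."""
    if coords is not None:
        return np.asarray(coords, dtype=float)
    if isinstance(graph, DirectedSpatialGraph) and graph.coords is not None:
        return graph.coords
    raise ValueError("node coordinates are required but none were provided")
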