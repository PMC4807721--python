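"""Directed and undirected graph metrics for connectome-style networks.

Conventions shared by every function here:

* self-loops are never counted (the coercion strips any diagonal);
* "undirected cast" means an undirected edge wherever at least one of the
  two directed edges exists;
* clustering, characteristic path length and global efficiency are defined
  on the undirected cast; nodal efficiency uses directed shortest paths;
* unreachable pairs contribute 0 to efficiencies, and are excluded (with a
  warning) from the characteristic path length;
* the reciprocity coefficient counts each reciprocated unordered pair once
  and divides by the undirected edge count, which is equivalent to
  ``(K_directed - K_undirected) / K_undirected``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from connectogen.graph import GraphLike, as_adjacency, get_coords


# ---------------------------------------------------------------------------
# degree-level metrics
# ---------------------------------------------------------------------------

def degrees(graph: GraphLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node ``(k_in, k_out, k_undirected)``; self-loops excluded."""
    A = as_adjacency(graph, directed=True)
    k_in = A.sum(axis=0).astype(int)
    k_out = A.sum(axis=1).astype(int)
    k_und = (A | A.T).sum(axis=1).astype(int)
    return k_in, k_out, k_und


def proportion_in_degree(graph: GraphLike) -> np.ndarray:
    """``k_in / (k_in + k_out)`` per node; NaN where a node has no edges."""
    k_in, k_out, _ = degrees(graph)
    total = k_in + k_out
    with np.errstate(invalid="ignore"):
        out = np.where(total > 0, k_in / np.maximum(total, 1), np.nan)
    return out


def clustering_coefficients(graph: GraphLike) -> np.ndarray:
    """Watts–Strogatz clustering ``C_i = 2 t_i / (k_i (k_i - 1))``.

    Computed on the undirected cast; ``t_i`` counts triangles through node
    ``i``.  Nodes with undirected degree < 2 get NaN (undefined) and must be
    excluded from averages by the caller.
    """
    U = as_adjacency(graph, directed=False).astype(float)
    k = U.sum(axis=1)
    t = ((U @ U) * U).sum(axis=1) / 2.0  # diag(U^3)/2 via BLAS
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, 2.0 * t / np.maximum(denom, 1e-300), np.nan)
    return C


# ---------------------------------------------------------------------------
# shortest-path metrics
# ---------------------------------------------------------------------------

def _sp_matrix(A: np.ndarray, directed: bool) -> np.ndarray:
    return shortest_path(
        csr_matrix(A.astype(np.int8)), directed=directed, unweighted=True
    )


def characteristic_path_length(graph: GraphLike) -> float:
    """Mean shortest undirected path length over all ordered node pairs.

    If the undirected cast is disconnected the mean is taken over reachable
    pairs only and a warning is emitted.
    """
    U = as_adjacency(graph, directed=False)
    d = _sp_matrix(U, directed=False)
    n = U.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if finite.sum() < off.sum():
        warnings.warn(
            "graph is disconnected; characteristic path length computed "
            "over reachable pairs only",
            stacklevel=2,
        )
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def global_efficiency(graph: GraphLike) -> float:
    """Mean inverse shortest undirected path length; unreachable pairs → 0."""
    U = as_adjacency(graph, directed=False)
    n = U.shape[0]
    if n < 2:
        return 0.0
    d = _sp_matrix(U, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(graph: GraphLike) -> np.ndarray:
    """Per-node mean inverse *directed* shortest path length to all others.

    ``E_i = (1/(n-1)) Σ_j 1/d_ij`` with directed distances; unreachable
    targets contribute zero, so a node with no outgoing edges has ``E_i = 0``.
    """
    A = as_adjacency(graph, directed=True)
    n = A.shape[0]
    d = _sp_matrix(A, directed=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


# ---------------------------------------------------------------------------
# reciprocity / density
# ---------------------------------------------------------------------------

def reciprocity_coefficient(graph: GraphLike) -> float:
    """Fraction of connected unordered pairs linked in both directions.

    Equals ``(K_directed - K_undirected) / K_undirected`` where
    ``K_undirected`` is the undirected edge count of the cast.
    """
    A = as_adjacency(graph, directed=True)
    n_und = int((A | A.T).sum()) // 2
    if n_und == 0:
        raise ValueError("reciprocity undefined on a graph with no edges")
    n_recip = int((A & A.T).sum()) // 2
    return n_recip / n_und


def connection_density(graph: GraphLike, directed: bool = True) -> float:
    """Edge count over the number of possible (ordered or unordered) pairs."""
    A = as_adjacency(graph, directed=directed)
    n = A.shape[0]
    if n < 2:
        raise ValueError("density needs at least two nodes")
    possible = n * (n - 1) if directed else n * (n - 1) // 2
    n_edges = int(A.sum()) if directed else int(A.sum()) // 2
    return n_edges / possible


# ---------------------------------------------------------------------------
# spatial metrics
# ---------------------------------------------------------------------------

def mean_projection_length(
    graph: GraphLike, coords: np.ndarray | None = None
) -> np.ndarray:
    """Per-node mean Euclidean length (mm) of outgoing edges.

    In an anterograde-tracer connectome a node's measured edges are its
    outgoing projections, so "a node's mean edge length" is taken over the
    edges it sends.  On a symmetric (undirected-cast) adjacency this equals
    the mean incident edge length.  NaN for nodes with no outgoing edges.
    """
    A = as_adjacency(graph, directed=True).astype(float)
    C = get_coords(graph, coords)
    diff = C[:, None, :] - C[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    k = A.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(k > 0, (D * A).sum(axis=1) / np.maximum(k, 1), np.nan)
    return out


def edge_length_split(
    graph: GraphLike, coords: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Split directed edge lengths by whether the reverse edge exists.

    Returns ``(reciprocal_lengths, nonreciprocal_lengths, t, cohens_d)``
    where ``t`` is the pooled-variance independent two-sample t statistic
    for reciprocal vs nonreciprocal mean length and ``cohens_d`` uses the
    pooled standard deviation.  If either sample is empty the statistics
    are returned as NaN.
    """
    A = as_adjacency(graph, directed=True)
    C = get_coords(graph, coords)
    recip_mask = A & A.T
    src, tgt = np.nonzero(A)
    lengths = np.linalg.norm(C[src] - C[tgt], axis=1)
    is_recip = recip_mask[src, tgt]
    rec, nonrec = lengths[is_recip], lengths[~is_recip]
    if len(rec) < 2 or len(nonrec) < 2:
        return rec, nonrec, float("nan"), float("nan")
    t_stat, _ = stats.ttest_ind(rec, nonrec, equal_var=True)
    n1, n2 = len(rec), len(nonrec)
    pooled_sd = np.sqrt(
        ((n1 - 1) * rec.var(ddof=1) + (n2 - 1) * nonrec.var(ddof=1)) / (n1 + n2 - 2)
    )
    d = (rec.mean() - nonrec.mean()) / pooled_sd if pooled_sd > 0 else float("nan")
    return rec, nonrec, float(t_stat), float(d)


def clustering_edgelength_correlation(
    graph: GraphLike, coords: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman correlation between clustering and mean projection length.

    Uses nodes whose clustering is defined (undirected degree >= 2) and
    that have at least one outgoing edge.  Returns ``(rho, p_value)``.
    """
    C = clustering_coefficients(graph)
    mlen = mean_projection_length(graph, coords)
    ok = np.isfinite(C) & np.isfinite(mlen)
    if ok.sum() < 3:
        raise ValueError("too few nodes with defined clustering and edge length")
    rho, p = stats.spearmanr(C[ok], mlen[ok])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# distribution-level summaries
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """OLS fit of ``log10 C_i`` against ``log10 k_i``: ``C ∝ k^gamma``."""

    gamma: float
    r_squared: float
    n_points: int


def clustering_degree_powerlaw_fit(graph: GraphLike) -> PowerLawFit:
    """Fit ``C_i ∝ k_i^gamma`` by unweighted OLS in log10–log10 space.

    Nodes with undirected degree < 2 (clustering undefined) or zero
    clustering (log undefined) are excluded.
    """
    C = clustering_coefficients(graph)
    _, _, k = degrees(graph)
    ok = np.isfinite(C) & (C > 0) & (k >= 2)
    if ok.sum() < 3:
        raise ValueError("need at least 3 nodes with k >= 2 and C > 0")
    x, y = np.log10(k[ok]), np.log10(C[ok])
    res = stats.linregress(x, y)
    return PowerLawFit(
        gamma=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(ok.sum()),
    )


def degree_histogram(
    graph: GraphLike, directed_component: str = "undirected", bins: int | np.ndarray = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized degree density for ``in``, ``out`` or ``undirected`` degree."""
    k_in, k_out, k_und = degrees(graph)
    try:
        k = {"in": k_in, "out": k_out, "undirected": k_und}[directed_component]
    except KeyError:
        raise ValueError(
            f"directed_component must be in/out/undirected, got {directed_component!r}"
        ) from None
    return np.histogram(k, bins=bins, density=True)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-node vectors and graph-level scalars for one network."""

    k_in: np.ndarray
    k_out: np.ndarray
    k_undirected: np.ndarray
    clustering: np.ndarray
    nodal_efficiency: np.ndarray
    mean_edge_length: np.ndarray | None
    characteristic_path_length: float
    global_efficiency: float
    reciprocity: float
    density_directed: float
    density_undirected: float

    @property
    def mean_clustering(self) -> float:
        C = self.clustering
        return float(np.nanmean(C)) if np.isfinite(C).any() else float("nan")

    @property
    def mean_nodal_efficiency(self) -> float:
        return float(self.nodal_efficiency.mean())

    def scalars(self) -> dict:
        return {
            "mean_clustering": self.mean_clustering,
            "characteristic_path_length": self.characteristic_path_length,
            "global_efficiency": self.global_efficiency,
            "mean_nodal_efficiency": self.mean_nodal_efficiency,
            "reciprocity": self.reciprocity,
            "density_directed": self.density_directed,
            "density_undirected": self.density_undirected,
        }

    def to_csv(self, path: str | Path) -> None:
        cols = {
            "k_in": self.k_in,
            "k_out": self.k_out,
            "k_undirected": self.k_undirected,
            "clustering": self.clustering,
            "nodal_efficiency": self.nodal_efficiency,
        }
        if self.mean_edge_length is not None:
            cols["mean_edge_length_mm"] = self.mean_edge_length
        pd.DataFrame(cols).rename_axis("node_id").to_csv(path)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.scalars(), indent=1))


def compute_report(graph: GraphLike, coords: np.ndarray | None = None) -> MetricsReport:
    """Compute the full metric suite for one graph."""
    k_in, k_out, k_und = degrees(graph)
    try:
        mlen = mean_projection_length(graph, coords)
    except ValueError:
        mlen = None
    return MetricsReport(
        k_in=k_in,
        k_out=k_out,
        k_undirected=k_und,
        clustering=clustering_coefficients(graph),
        nodal_efficiency=nodal_efficiency(graph),
        mean_edge_length=mlen,
        characteristic_path_length=characteristic_path_length(graph),
        global_efficiency=global_efficiency(graph),
        reciprocity=reciprocity_coefficient(graph),
        density_directed=connection_density(graph, directed=True),
        density_undirected=connection_density(graph, directed=False),
    )
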