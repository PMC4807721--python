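"""Spatial embedding: node coordinates and Euclidean distance structure.

Model nodes are embedded in a cube whose side (7 mm by default elsewhere in
the package) is chosen so the inter-nodal distance distribution resembles
that of a real mesoscale connectome.  Coordinates can instead be loaded from
a CSV of region centroids (``node_id,x,y,z`` in millimetres).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from connectogen.utils import as_rng


def sample_cube_positions(
    n: int, side: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` node positions uniformly from a cube ``[0, side]^3``.

    Returns an ``(n, 3)`` float array in millimetres.  Coincident points are
    not excluded (a probability-zero event under the uniform draw).
    """
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got n={n}")
    if not side > 0:
        raise ValueError(f"cube side must be positive, got {side}")
    rng = as_rng(seed)
    return rng.uniform(0.0, side, size=(n, 3))


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Full symmetric Euclidean distance matrix (mm) with zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("coords must be an (n >= 2, dim) array")
    return squareform(pdist(coords))


def internodal_distance_density(
    coords: np.ndarray, bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of all n(n-1)/2 unordered pairwise distances.

    Returns ``(density, bin_edges)`` as from ``np.histogram(..., density=True)``;
    the density integrates to 1 over the bin range.
    """
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    d = pdist(coords)
    return np.histogram(d, bins=bins, density=True)


def load_coordinates(path: str | Path) -> np.ndarray:
    """Load node coordinates from a CSV with header ``node_id,x,y,z`` (mm).

    Node ids must be the integers ``0..n-1`` (in any row order); positions
    must be finite.  Returns an ``(n, 3)`` array indexed by node id.
    """
    df = pd.read_csv(path)
    expected = ["node_id", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"coordinate CSV must have columns {expected}, got {list(df.columns)}")
    n = len(df)
    ids = df["node_id"].to_numpy()
    if sorted(ids.tolist()) != list(range(n)):
        raise ValueError("node_id column must contain exactly 0..n-1")
    coords = np.full((n, 3), np.nan)
    coords[ids] = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return coords


def write_coordinates(coords: np.ndarray, path: str | Path) -> None:
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame(
        {
            "node_id": np.arange(coords.shape[0]),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    df.to_csv(path, index=False)
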