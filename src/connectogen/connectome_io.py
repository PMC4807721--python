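"""Tracer-projection tables and binary bilaterally mirrored connectomes.

A tracer table lists anterograde projections measured from one hemisphere's
source regions into both hemispheres: rows of ``(source_region,
target_region, strength, p_value)``.  Target labels carry an explicit
hemisphere prefix — ``ipsi:<region>`` for the injected hemisphere and
``contra:<region>`` for the opposite one.  Binarizing at a p-value
threshold and assuming bilateral symmetry yields a ``2m x 2m`` binary
directed adjacency with block structure ``[[ipsi, contra], [contra, ipsi]]``
(nodes ``0..m-1`` = right hemisphere, ``m..2m-1`` = left).

:func:`synthesize_tracer_fixture` builds a synthetic table with a requested
edge count and reciprocity, standing in for real atlas data in tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from connectogen.graph import DirectedSpatialGraph
from connectogen.utils import as_rng

IPSI, CONTRA = "ipsi:", "contra:"
_COLUMNS = ["source_region", "target_region", "strength", "p_value"]


def load_tracer_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a tracer CSV.

    Raises ``ValueError`` naming the offending CSV line for malformed rows,
    p-values outside [0, 1], negative strengths, bad hemisphere prefixes or
    duplicated (source, target) rows.  Self-projections (a region onto its
    own ipsilateral label) are dropped.
    """
    df = pd.read_csv(path, dtype={"source_region": str, "target_region": str})
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"tracer CSV must have columns {_COLUMNS}, got {list(df.columns)}")
    # +2: one for the header, one for 1-based line numbers
    lines = df.index.to_numpy() + 2
    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = ~np.isfinite(p) | (p < 0) | (p > 1)
    if bad.any():
        raise ValueError(f"p_value outside [0, 1] at line {lines[bad][0]}")
    s = pd.to_numeric(df["strength"], errors="coerce")
    bad = ~np.isfinite(s) | (s < 0)
    if bad.any():
        raise ValueError(f"strength not a nonnegative number at line {lines[bad][0]}")
    badt = ~df["target_region"].str.startswith((IPSI, CONTRA))
    if badt.any():
        raise ValueError(
            f"target_region must start with '{IPSI}' or '{CONTRA}' at line {lines[badt][0]}"
        )
    dup = df.duplicated(subset=["source_region", "target_region"])
    if dup.any():
        raise ValueError(f"duplicate (source, target) row at line {lines[dup][0]}")
    df = df.astype({"strength": float, "p_value": float})
    self_rows = df["target_region"] == IPSI + df["source_region"]
    return df.loc[~self_rows].reset_index(drop=True)


def write_tracer_table(table: pd.DataFrame, path: str | Path) -> None:
    table[_COLUMNS].to_csv(path, index=False)


def binarize_and_mirror(
    table: pd.DataFrame, p_threshold: float = 0.01
) -> tuple[DirectedSpatialGraph, list[str]]:
    """Threshold projections at ``p < p_threshold`` and mirror bilaterally.

    Significant ipsilateral projections fill block ``X`` (within-hemisphere)
    and contralateral ones block ``Y``; the full adjacency is
    ``[[X, Y], [Y, X]]`` over ``2m`` nodes.  Returns the graph and the node
    labels (right-hemisphere regions first, then ``L:``-prefixed mirrors).
    """
    target_bases = {
        t[len(IPSI):] if t.startswith(IPSI) else t[len(CONTRA):]
        for t in table["target_region"]
    }
    sources = sorted(set(table["source_region"]) | target_bases)
    m = len(sources)
    index = {r: i for i, r in enumerate(sources)}
    X = np.zeros((m, m), dtype=bool)
    Y = np.zeros((m, m), dtype=bool)
    sig = table[table["p_value"] < p_threshold]
    for _, row in sig.iterrows():
        i = index[row["source_region"]]
        t = row["target_region"]
        if t.startswith(IPSI):
            X[i, index[t[len(IPSI):]]] = True
        else:
            Y[i, index[t[len(CONTRA):]]] = True
    np.fill_diagonal(X, False)
    np.fill_diagonal(Y, False)  # keep the full 2m x 2m diagonal empty
    A = np.block([[X, Y], [Y, X]])
    labels = [f"R:{r}" for r in sources] + [f"L:{r}" for r in sources]
    return DirectedSpatialGraph(A, meta={"p_threshold": p_threshold, "m": m}), labels


def hemisphere_swap_permutation(m: int) -> np.ndarray:
    """Node permutation exchanging the two hemispheres of a mirrored graph."""
    return np.concatenate([np.arange(m, 2 * m), np.arange(m)])


def synthesize_tracer_fixture(
    m: int = 213,
    target_directed_edges: int = 8820,
    target_reciprocity: float = 0.13,
    seed: int | np.random.Generator | None = None,
    contra_fraction: float = 0.3,
) -> pd.DataFrame:
    """Build a synthetic tracer table with planted edge count and reciprocity.

    The mirrored, binarized graph (threshold 0.01) has approximately
    ``target_directed_edges`` directed edges and reciprocity close to
    ``target_reciprocity``.  Planted projections get p-values well below
    0.01; an equal number of decoy rows get p-values above 0.1.  Strengths
    are log-normal.  This is synthetic stand-in data, not derived from any
    real atlas.
    """
    cap = 2 * m * (2 * m - 1)
    if not (0 < target_directed_edges <= cap):
        raise ValueError(f"target_directed_edges outside (0, {cap}]")
    if not (0.0 <= target_reciprocity <= 1.0):
        raise ValueError("target_reciprocity must lie in [0, 1]")
    rng = as_rng(seed)
    # mirroring doubles everything, so plan at half scale: choose unordered
    # connected pairs P and reciprocated pairs R with K = N_e + R, r = R/N_e
    n_und_half = int(round(target_directed_edges / (1.0 + target_reciprocity) / 2))
    n_rec_half = int(round(n_und_half * target_reciprocity))
    n_contra = int(round(n_und_half * contra_fraction))
    n_ipsi = n_und_half - n_contra

    # sample unordered region pairs without replacement (i < j); each pair
    # mirrors to two unordered node pairs in the full graph
    iu, ju = np.triu_indices(m, k=1)

    def sample_pairs(count: int) -> np.ndarray:
        flat = rng.choice(iu.size, size=count, replace=False)
        return np.stack([iu[flat], ju[flat]], axis=1)

    ipsi_pairs = sample_pairs(n_ipsi)
    contra_pairs = sample_pairs(n_contra)
    recip_flags = np.zeros(n_und_half, dtype=bool)
    recip_flags[rng.choice(n_und_half, size=min(n_rec_half, n_und_half), replace=False)] = True

    rows: list[tuple[str, str, float, float]] = []
    names = [f"REG{i:03d}" for i in range(m)]

    def p_sig() -> float:
        return float(rng.uniform(1e-6, 5e-3))

    def strength() -> float:
        return float(rng.lognormal(mean=-2.0, sigma=1.0))

    for idx, (i, j) in enumerate(ipsi_pairs):
        recip = recip_flags[idx]
        if rng.random() < 0.5:
            i, j = j, i
        rows.append((names[i], IPSI + names[j], strength(), p_sig()))
        if recip:
            rows.append((names[j], IPSI + names[i], strength(), p_sig()))
    for k, (i, j) in enumerate(contra_pairs):
        recip = recip_flags[n_ipsi + k]
        if rng.random() < 0.5:
            i, j = j, i
        rows.append((names[i], CONTRA + names[j], strength(), p_sig()))
        if recip:
            rows.append((names[j], CONTRA + names[i], strength(), p_sig()))

    # decoy (non-significant) rows so thresholding is actually exercised
    planted = {(r[0], r[1]) for r in rows}
    n_decoys = len(rows)
    while n_decoys > 0:
        i, j = rng.integers(0, m, size=2)
        hemi = IPSI if rng.random() < 0.7 else CONTRA
        key = (names[i], hemi + names[j])
        if i == j and hemi == IPSI:
            continue
        if key in planted:
            continue
        planted.add(key)
        rows.append((key[0], key[1], strength(), float(rng.uniform(0.1, 1.0))))
        n_decoys -= 1

    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.sample(frac=1.0, random_state=int(as_rng(rng).integers(2**31))).reset_index(
        drop=True
    )
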