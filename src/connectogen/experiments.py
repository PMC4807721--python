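"""Seeded ensemble experiments reproducing the model-side summary analyses.

Each function grows a seeded ensemble of networks, computes the relevant
metric suite, and returns tidy pandas DataFrames: averaged undirected
metrics per model (``run_table1``), reciprocity as a function of the length
constant (``run_reciprocity_sweep``), nodal-efficiency summaries
(``run_efficiency_report``) and targeted-attack robustness curves
(``run_lesion_experiment``).  All are reproducible bit-for-bit from
``(parameters, seed)``.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from connectogen import metrics
from connectogen.graph import DirectedSpatialGraph
from connectogen.growth import GrowthParams, Variant, grow
from connectogen.lesioning import targeted_attack
from connectogen.reference import (
    ReferenceParams,
    degree_preserving_shuffle,
    directed_er_graph,
    scale_free_graph,
    small_world_graph,
)
DEFAULT_L = 0.725  # mm; the length constant matching a reciprocity of 0.13


def _grower(model: str, n: int, K: int, L: float) -> Callable[[int], object]:
    """Return a seed -> graph factory for a named model."""
    model = model.upper().replace("-", "_")
    growth_variants = {v.value for v in Variant}
    if model in growth_variants:
        def factory(seed: int):
            return grow(GrowthParams(n=n, K=K, L=L, variant=Variant(model), seed=seed))
        return factory
    if model == "SMALL_WORLD":
        return lambda seed: small_world_graph(ReferenceParams(n=n, seed=seed))
    if model == "SCALE_FREE":
        return lambda seed: scale_free_graph(ReferenceParams(n=n, seed=seed))
    if model == "ER_DIRECTED":
        return lambda seed: directed_er_graph(ReferenceParams(n=n, seed=seed))
    raise ValueError(f"unknown model {model!r}")


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd


def run_table1(
    repeats: int = 100,
    seed: int | None = None,
    n: int = 426,
    K: int = 8820,
    L: float = DEFAULT_L,
    connectome: DirectedSpatialGraph | None = None,
    models: Sequence[str] = ("SMALL_WORLD", "SCALE_FREE", "SGPA"),
) -> pd.DataFrame:
    """Averaged undirected metrics (clustering, path length, efficiency).

    If a connectome graph is supplied, its degree-preserving shuffle is
    included as the "random" row and the connectome's own metrics as a
    zero-variance row; otherwise those rows are omitted.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rows = []
    model_list = list(models)
    if connectome is not None:
        rep = metrics.compute_report(connectome)
        rows.append(
            {
                "model": "connectome",
                "clustering_mean": rep.mean_clustering,
                "clustering_sd": 0.0,
                "path_length_mean": rep.characteristic_path_length,
                "path_length_sd": 0.0,
                "global_efficiency_mean": rep.global_efficiency,
                "global_efficiency_sd": 0.0,
            }
        )
        model_list = ["RANDOM_SHUFFLE"] + model_list
    for model in model_list:
        cs, ls, es = [], [], []
        for s in _model_seeds(seed, model, repeats):
            if model == "RANDOM_SHUFFLE":
                g = degree_preserving_shuffle(connectome, directed=False, seed=s)
            else:
                g = _grower(model, n, K, L)(s)
            C = metrics.clustering_coefficients(g)
            cs.append(float(np.nanmean(C)))
            ls.append(metrics.characteristic_path_length(g))
            es.append(metrics.global_efficiency(g))
        (cm, csd), (lm, lsd), (em, esd) = _mean_sd(cs), _mean_sd(ls), _mean_sd(es)
        rows.append(
            {
                "model": model.lower(),
                "clustering_mean": cm,
                "clustering_sd": csd,
                "path_length_mean": lm,
                "path_length_sd": lsd,
                "global_efficiency_mean": em,
                "global_efficiency_sd": esd,
            }
        )
    return pd.DataFrame(rows)


def _model_seeds(seed: int | None, tag: str, repeats: int) -> list[int]:
    """Independent child seeds per (master seed, model tag)."""
    base = np.random.SeedSequence(seed).generate_state(1, dtype=np.uint64)[0]
    offset = sum(ord(c) for c in tag)  # stable, model-specific stream
    ss = np.random.SeedSequence([int(base) % (2**31), offset])
    return [int(x) % (2**31) for x in ss.generate_state(repeats, dtype=np.uint64)]


def run_reciprocity_sweep(
    L_grid: Iterable[float],
    repeats: int = 20,
    seed: int | None = None,
    n: int = 426,
    K: int = 8820,
    models: Sequence[str] = ("SGPA", "TAPA"),
    reference: float | None = 0.13,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean ± sd reciprocity per length constant and model.

    Returns the curve table and, per model, the length constant where the
    mean curve crosses ``reference`` (linear interpolation; NaN if the
    curve never crosses).
    """
    L_grid = sorted(float(L) for L in L_grid)
    if not L_grid:
        raise ValueError("L_grid must be nonempty")
    rows = []
    crossings: dict[str, float] = {}
    for model in models:
        means = []
        for L in L_grid:
            vals = [
                metrics.reciprocity_coefficient(_grower(model, n, K, L)(s))
                for s in _model_seeds(seed, f"{model}:{L}", repeats)
            ]
            mean, sd = _mean_sd(vals)
            means.append(mean)
            rows.append({"model": model.lower(), "L": L,
                         "reciprocity_mean": mean, "reciprocity_sd": sd})
        crossings[model.lower()] = (
            _crossing(L_grid, means, reference) if reference is not None else float("nan")
        )
    return pd.DataFrame(rows), crossings


def _crossing(L_grid: Sequence[float], means: Sequence[float], ref: float) -> float:
    """L where a (decreasing) mean curve crosses ``ref``, by interpolation."""
    for (L0, m0), (L1, m1) in zip(zip(L_grid, means), zip(L_grid[1:], means[1:])):
        if (m0 - ref) * (m1 - ref) <= 0 and m0 != m1:
            return L0 + (m0 - ref) / (m0 - m1) * (L1 - L0)
    return float("nan")


def run_efficiency_report(
    repeats: int = 100,
    seed: int | None = None,
    n: int = 426,
    K: int = 8820,
    L: float = DEFAULT_L,
    models: Sequence[str] = ("SGPA", "PA_DIRECTED", "TAPA", "ER_DIRECTED"),
    hist_bins: int = 50,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Mean ± sd of mean nodal efficiency per model, plus pooled histograms.

    Nodal efficiency is the directed inverse-shortest-path mean per node;
    each graph contributes its node average, then the ensemble average and
    standard deviation over repeats are reported.
    """
    rows = []
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for model in models:
        per_graph, pooled = [], []
        for s in _model_seeds(seed, model, repeats):
            eff = metrics.nodal_efficiency(_grower(model, n, K, L)(s))
            per_graph.append(float(eff.mean()))
            pooled.append(eff)
        mean, sd = _mean_sd(per_graph)
        rows.append({"model": model.lower(),
                     "mean_nodal_efficiency": mean, "sd": sd})
        hists[model.lower()] = np.histogram(
            np.concatenate(pooled), bins=hist_bins, range=(0.0, 1.0), density=True
        )
    return pd.DataFrame(rows), hists


def run_lesion_experiment(
    repeats: int = 100,
    seed: int | None = None,
    n: int = 426,
    K: int = 8820,
    L: float = DEFAULT_L,
    models: Sequence[str] = ("SGPA", "SMALL_WORLD", "SCALE_FREE"),
    recompute: bool = True,
) -> pd.DataFrame:
    """Mean ± sd targeted-attack traces per model.

    Returns a long-format frame with one row per (model, nodes_removed) and
    columns for giant-component size, global efficiency and density.
    """
    frames = []
    for model in models:
        traces = []
        for s in _model_seeds(seed, model, repeats):
            g = _grower(model, n, K, L)(s)
            traces.append(targeted_attack(g, recompute=recompute, seed=s).to_frame())
        stacked = pd.concat(traces, keys=range(len(traces)))
        mean = stacked.groupby("nodes_removed").mean()
        sd = stacked.groupby("nodes_removed").std(ddof=1)
        out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").reset_index()
        out.insert(0, "model", model.lower())
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def write_manifest(path: str | Path, **params) -> None:
    """Record run parameters, package version and wall time as JSON."""
    from connectogen import __version__

    payload = {"package_version": __version__, "unix_time": time.time(), **params}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
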