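"""Whole-brain and hemispheric network measures on FA-weighted connectomes.

Edge lengths for shortest paths are 1/w; clustering is the Onnela
max-normalized geometric-mean form; modularity is maximized exactly (full
partition enumeration) for tiny graphs and by seeded Louvain restarts
otherwise. Unreachable node pairs contribute 0 to efficiency, which keeps
it monotone under edge addition.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .errors import DataError

#: graphs up to this size get exact modularity by partition enumeration
EXACT_MODULARITY_MAX_NODES = 8


def _as_weight_matrix(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DataError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise DataError("weight matrix must be symmetric")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def density(w) -> float:
    """Fraction of node pairs connected by an edge."""
    w = _as_weight_matrix(w)
    n = w.shape[0]
    if n < 2:
        raise DataError("density needs >= 2 nodes")
    edges = int(np.count_nonzero(np.triu(w, 1)))
    return edges / (n * (n - 1) / 2)


def mean_strength(w) -> float:
    """Mean over nodes of the node strength sum_j w_ij."""
    w = _as_weight_matrix(w)
    return float(w.sum() / w.shape[0])


def global_efficiency(w) -> float:
    """Mean inverse weighted shortest-path length over ordered node pairs.

    Edge length = 1/w; unreachable pairs contribute 0.
    """
    w = _as_weight_matrix(w)
    if np.any(w < 0):
        raise DataError("negative weights not allowed")
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(csr_array(lengths), directed=False)
    np.fill_diagonal(d, np.inf)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def mean_clustering(w) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are first normalized by the maximum off-diagonal weight; per node
    C_i averages the geometric mean of triangle weights; nodes with degree
    < 2 contribute 0.
    """
    w = _as_weight_matrix(w)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    what = np.cbrt(w / wmax)
    tri = np.diag(what @ what @ what)  # 2x number of weighted triangles per node
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    return float(c.mean())


def _modularity_value(w: np.ndarray, labels: np.ndarray, two_m: float) -> float:
    s = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - s[idx].sum() ** 2 / two_m
    return q / two_m


def _set_partitions(n: int):
    """Yield all partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxlab: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)


def modularity(w, n_repetitions: int = 100, seed: int = 0) -> tuple[float, np.ndarray]:
    """Maximize Newman modularity Q at resolution 1; returns (Q, labels).

    Graphs with <= ``EXACT_MODULARITY_MAX_NODES`` nodes are solved exactly by
    enumerating all node partitions; larger graphs use the best of
    ``n_repetitions`` seeded Louvain runs. Deterministic given the seed.
    """
    w = _as_weight_matrix(w)
    if np.any(w < 0):
        raise DataError("negative weights not allowed")
    two_m = w.sum()
    if two_m == 0:
        raise DataError("modularity undefined for an empty graph (m = 0)")
    if n_repetitions < 1:
        raise DataError("n_repetitions must be >= 1")
    n = w.shape[0]
    if n <= EXACT_MODULARITY_MAX_NODES:
        best_q, best_labels = -np.inf, None
        for labels in _set_partitions(n):
            q = _modularity_value(w, labels, two_m)
            if q > best_q:
                best_q, best_labels = q, labels
        return float(best_q), best_labels

    g = nx.from_numpy_array(w)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_repetitions)
    best_q, best_labels = -np.inf, None
    for s in rep_seeds:
        communities = nx.community.louvain_communities(g, weight="weight", seed=int(s))
        q = nx.community.modularity(g, communities, weight="weight")
        if q > best_q:
            labels = np.empty(n, dtype=int)
            for c, nodes in enumerate(communities):
                labels[list(nodes)] = c
            best_q, best_labels = q, labels
    return float(best_q), best_labels


def intra_hemispheric_efficiency(w, node_table: pd.DataFrame) -> float:
    """Global efficiency of each hemisphere's subnetwork, averaged.

    Inter-hemispheric edges are removed by construction (the subnetworks are
    node-induced); midline nodes belong to neither subnetwork.
    """
    w = _as_weight_matrix(w)
    effs = []
    for h in ("L", "R"):
        idx = (node_table["hemisphere"] == h).to_numpy()
        if idx.sum() < 2:
            raise DataError(f"hemisphere {h} has < 2 nodes")
        effs.append(global_efficiency(w[np.ix_(idx, idx)]))
    return float(np.mean(effs))


def conservation_ratio(cr: float, e_intra: float) -> float:
    """Commissural ratio over intra-hemispheric efficiency."""
    if e_intra == 0:
        warnings.warn("intra-hemispheric efficiency is 0; conservation ratio undefined")
        return float("nan")
    return cr / e_intra


def metric_set(
    fa_matrix,
    node_table: pd.DataFrame | None = None,
    commissural_ratio: float | None = None,
    n_repetitions: int = 100,
    seed: int = 0,
) -> dict:
    """All scalar metrics for one subject's FA-weighted connectome."""
    out = {
        "density": density(fa_matrix),
        "mean_strength": mean_strength(fa_matrix),
        "efficiency": global_efficiency(fa_matrix),
        "clustering": mean_clustering(fa_matrix),
        "modularity": modularity(fa_matrix, n_repetitions=n_repetitions, seed=seed)[0],
    }
    if node_table is not None:
        out["intra_hemi_efficiency"] = intra_hemispheric_efficiency(fa_matrix, node_table)
        if commissural_ratio is not None:
            out["commissural_ratio"] = commissural_ratio
            out["conservation_ratio"] = conservation_ratio(
                commissural_ratio, out["intra_hemi_efficiency"]
            )
    return out
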