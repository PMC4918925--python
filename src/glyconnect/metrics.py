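"""Global weighted network measures for structural connectomes.

The connectome is an undirected, weighted graph whose edge weights are
fiber densities (streamline count / total streamline count).  Following
the Brain Connectivity Toolbox convention for density-weighted networks,
topological distance between connected nodes is the reciprocal weight
d = 1/w, so strong connections are short.

Measures
--------
- characteristic path length ``L`` (integration): mean finite shortest-path
  distance over ordered node pairs; disconnected pairs are excluded.
- global efficiency ``E`` (integration): mean of ``1/d`` over ordered pairs
  with ``1/inf = 0``; defined even on disconnected graphs.
- weighted clustering coefficient ``C`` (segregation): Onnela geometric-mean
  triangle intensity, weights normalized by the matrix maximum.
- modularity ``Q`` (segregation): Newman weighted modularity maximized by
  seeded Louvain restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


@dataclass
class NetworkMetrics:
    """Per-subject global network measures.

    Raw measures (C_raw, Q, L_raw, E) are computed from the weight matrix
    directly; gamma, lam and sigma are filled in by null-model
    normalization (see :mod:`glyconnect.nulls`) and are NaN until then.
    """

    C_raw: float
    Q: float
    L_raw: float
    E: float
    n_edges: int
    total_strength: float
    gamma: float = field(default=np.nan)
    lam: float = field(default=np.nan)
    sigma: float = field(default=np.nan)
    n_disconnected_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "C_raw": self.C_raw,
            "Q": self.Q,
            "L_raw": self.L_raw,
            "E": self.E,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "n_edges": self.n_edges,
            "total_strength": self.total_strength,
        }


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {w.shape}")
    if (w < 0).any():
        raise ValueError("weight matrix has negative entries")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    return w


def shortest_path_matrix(w: np.ndarray) -> np.ndarray:
    """Pairwise shortest-path distances over edge lengths d = 1/weight.

    Zero weights are absent edges. Unreachable pairs are ``inf``; the
    diagonal is 0. Dijkstra per source on the sparse length graph.
    """
    w = _check_weights(w)
    i, j = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[i, j], (i, j)), shape=w.shape)
    return shortest_path(lengths, method="D", directed=False)


def global_efficiency(w: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path distance over ordered node pairs.

    Disconnected pairs contribute 0, so E is defined on any graph.
    """
    w = _check_weights(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("efficiency requires >= 2 nodes")
    d = shortest_path_matrix(w) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def char_path_length(
    w: np.ndarray, dist: np.ndarray | None = None, return_disconnected: bool = False
):
    """Mean finite off-diagonal shortest-path distance.

    Infinite (disconnected) distances are excluded from the average;
    their count is available via ``return_disconnected``.
    """
    w = _check_weights(w)
    if w.shape[0] < 2:
        raise ValueError("path length requires >= 2 nodes")
    d = shortest_path_matrix(w) if dist is None else dist
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_disc = int(off.sum() - finite.sum())
    if not finite.any():
        raise ValueError("no finite path between any node pair")
    L = float(d[finite].mean())
    if return_disconnected:
        return L, n_disc
    return L


def clustering_coefficient(w: np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are normalized by the matrix maximum; each node's coefficient
    is the sum of geometric-mean triangle intensities divided by the
    number of possible neighbor pairs k(k-1).  Nodes with degree < 2
    contribute 0. Invariant to uniform weight scaling.
    """
    w = _check_weights(w)
    wmax = w.max()
    if wmax == 0:
        return 0.0
    cr = np.cbrt(w / wmax)
    cyc3 = np.diagonal(cr @ cr @ cr)  # 2 * triangle intensity per node
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, cyc3 / np.maximum(denom, 1), 0.0)
    return float(c.mean())


def modularity_value(w: np.ndarray, partition: np.ndarray) -> float:
    """Newman weighted modularity Q of a given partition.

    Q = (1/2m) * sum_ij [w_ij - s_i s_j / 2m] delta(c_i, c_j),
    with s the node strength and 2m the total weight.
    """
    w = _check_weights(w)
    partition = np.asarray(partition)
    s = w.sum(axis=1)
    two_m = s.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    same = partition[:, None] == partition[None, :]
    return float(((w - np.outer(s, s) / two_m) * same).sum() / two_m)


def modularity(
    w: np.ndarray, n_restarts: int = 100, rng: np.random.Generator | int | None = 0
) -> tuple[float, np.ndarray]:
    """Maximize weighted Newman modularity with seeded Louvain restarts.

    Returns the best Q over ``n_restarts`` runs and its partition as an
    integer community-label vector. Ties break on the first-found
    partition; seeding makes the result reproducible.
    """
    w = _check_weights(w)
    if w.max() == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    rng = np.random.default_rng(rng)
    g = nx.from_numpy_array(w)
    best_q, best_part = -np.inf, None
    for _ in range(max(1, n_restarts)):
        seed = int(rng.integers(0, 2**31 - 1))
        communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
        labels = np.empty(w.shape[0], dtype=int)
        for ci, nodes in enumerate(communities):
            labels[list(nodes)] = ci
        q = modularity_value(w, labels)
        if q > best_q + 1e-12:
            best_q, best_part = q, labels
    return best_q, best_part


def compute_metrics(
    w: np.ndarray, n_restarts: int = 100, rng: np.random.Generator | int | None = 0
) -> NetworkMetrics:
    """All raw global measures of one connectivity matrix (no nulls)."""
    w = _check_weights(w)
    d = shortest_path_matrix(w)
    L, n_disc = char_path_length(w, dist=d, return_disconnected=True)
    if n_disc:
        warnings.warn(f"{n_disc} disconnected node pairs excluded from path length")
    q, _ = modularity(w, n_restarts=n_restarts, rng=rng)
    return NetworkMetrics(
        C_raw=clustering_coefficient(w),
        Q=q,
        L_raw=L,
        E=global_efficiency(w, dist=d),
        n_edges=int((w > 0).sum() // 2),
        total_strength=float(w.sum() / 2.0),
        n_disconnected_pairs=n_disc,
    )
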