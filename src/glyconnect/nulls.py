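"""Degree-preserving null networks and normalized global measures.

Raw clustering and path length depend on degree and weight distributions,
so they are normalized by their means over an ensemble of Maslov–Sneppen
rewired surrogates: random double-edge swaps that preserve the degree
sequence exactly while randomizing global topology.  Weights travel with
the swapped edges, so the weight multiset is preserved too.

gamma  = C / <C_null>      (normalized clustering)
lambda = L / <L_null>      (normalized path length)
sigma  = gamma / lambda    (small-worldness; > 1 for small-world graphs)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import (
    NetworkMetrics,
    char_path_length,
    clustering_coefficient,
    compute_metrics,
)

try:  # hot loop jitted when numba is available; results identical either way
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap(a[0]) if a and callable(a[0]) else wrap


@dataclass
class NullEnsembleConfig:
    """Size and seeding of the randomized null ensemble."""

    n_null: int = 1000
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@njit(cache=False)
def _swap_loop(edges, adj, e1_idx, e2_idx, flips):  # pragma: no cover - jitted
    n_ok = 0
    for t in range(e1_idx.shape[0]):
        i1 = e1_idx[t]
        i2 = e2_idx[t]
        if i1 == i2:
            continue
        a = edges[i1, 0]
        b = edges[i1, 1]
        c = edges[i2, 0]
        d = edges[i2, 1]
        if flips[t]:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[i1, 1] = d
        edges[i2, 0] = c
        edges[i2, 1] = b
        n_ok += 1
    return n_ok


@njit(cache=False)
def _pairs_L_sum(indptr, indices, lengths, n):  # pragma: no cover - jitted
    """Sum and count of finite off-diagonal shortest-path distances.

    Binary-heap Dijkstra per source on a CSR graph; hot path for the null
    ensemble where thousands of path-length evaluations are needed.
    """
    cap = indices.size + 1
    hd = np.empty(cap)
    hi = np.empty(cap, np.int64)
    dist = np.empty(n)
    total = 0.0
    cnt = 0
    for src in range(n):
        for i in range(n):
            dist[i] = np.inf
        dist[src] = 0.0
        hd[0] = 0.0
        hi[0] = src
        hs = 1
        while hs > 0:
            d0 = hd[0]
            u = hi[0]
            hs -= 1
            hd[0] = hd[hs]
            hi[0] = hi[hs]
            k = 0
            while True:
                l = 2 * k + 1
                r = l + 1
                m = k
                if l < hs and hd[l] < hd[m]:
                    m = l
                if r < hs and hd[r] < hd[m]:
                    m = r
                if m == k:
                    break
                hd[k], hd[m] = hd[m], hd[k]
                hi[k], hi[m] = hi[m], hi[k]
                k = m
            if d0 > dist[u]:
                continue
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                nd = d0 + lengths[e]
                if nd < dist[v]:
                    dist[v] = nd
                    hd[hs] = nd
                    hi[hs] = v
                    k = hs
                    hs += 1
                    while k > 0:
                        p = (k - 1) // 2
                        if hd[k] < hd[p]:
                            hd[k], hd[p] = hd[p], hd[k]
                            hi[k], hi[p] = hi[p], hi[k]
                            k = p
                        else:
                            break
        for i in range(n):
            if i != src and dist[i] < np.inf:
                total += dist[i]
                cnt += 1
    return total, cnt


def fast_char_path_length(w: np.ndarray) -> float:
    """Mean finite shortest-path distance, via the jitted Dijkstra.

    Same definition as :func:`glyconnect.metrics.char_path_length`
    (tested for exact agreement); falls back to it without numba.
    """
    if not _HAVE_NUMBA:  # pragma: no cover
        return char_path_length(w)
    from scipy.sparse import csr_matrix

    i, j = np.nonzero(w)
    g = csr_matrix((1.0 / w[i, j], (i, j)), shape=w.shape)
    total, cnt = _pairs_L_sum(g.indptr.astype(np.int64), g.indices.astype(np.int64),
                              g.data, w.shape[0])
    if cnt == 0:
        raise ValueError("no finite path between any node pair")
    return total / cnt


def rewire(
    w: np.ndarray, swaps_per_edge: int = 10, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Maslov–Sneppen degree-preserving randomization of a weighted graph.

    Attempts ``swaps_per_edge * n_edges`` double-edge swaps; each swap
    exchanges endpoints of two randomly chosen edges, rejected if it would
    create a self-loop or a multi-edge.  Edge weights follow their edge
    through the swap, so degree sequence and weight multiset are both
    exactly preserved.

    Returns a new symmetric matrix. Graphs with fewer than 2 edges admit
    no swap and are returned unchanged with a warning.
    """
    w = np.asarray(w, dtype=float)
    rng = np.random.default_rng(rng)
    iu, ju = np.nonzero(np.triu(w, 1))
    n_edges = iu.size
    if n_edges < 2:
        warnings.warn("graph has < 2 edges; no rewiring possible")
        return w.copy()
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    weights = w[iu, ju].copy()
    adj = w > 0
    np.fill_diagonal(adj, False)
    adj = np.ascontiguousarray(adj)

    n_attempts = int(swaps_per_edge) * n_edges
    e1 = rng.integers(0, n_edges, size=n_attempts)
    e2 = rng.integers(0, n_edges, size=n_attempts)
    flips = rng.random(n_attempts) < 0.5
    _swap_loop(edges, adj, e1, e2, flips)

    out = np.zeros_like(w)
    out[edges[:, 0], edges[:, 1]] = weights
    out[edges[:, 1], edges[:, 0]] = weights
    return out


def null_distribution(
    w: np.ndarray,
    cfg: NullEnsembleConfig,
    rng: np.random.Generator | None = None,
    measures: tuple[str, ...] = ("C", "L"),
) -> tuple[np.ndarray, np.ndarray]:
    """Clustering and path length for each network of the null ensemble.

    ``measures`` restricts the computed quantities (the omitted one is
    returned as NaN), which matters when many ensembles are evaluated.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    c_null = np.full(cfg.n_null, np.nan)
    l_null = np.full(cfg.n_null, np.nan)
    for k in range(cfg.n_null):
        wn = rewire(w, cfg.swaps_per_edge, rng)
        if "C" in measures:
            c_null[k] = clustering_coefficient(wn)
        if "L" in measures:
            l_null[k] = fast_char_path_length(wn)
    return c_null, l_null


def normalize_metrics(
    w: np.ndarray,
    cfg: NullEnsembleConfig | None = None,
    metrics: NetworkMetrics | None = None,
) -> NetworkMetrics:
    """Fill gamma, lambda and sigma of a subject's metrics via null nulls.

    gamma = C_raw / <C_null>, lambda = L_raw / <L_null> over ``cfg.n_null``
    rewired surrogates; sigma = gamma / lambda exactly.  Raw metrics are
    computed if not supplied.
    """
    cfg = cfg or NullEnsembleConfig()
    m = compute_metrics(w) if metrics is None else metrics
    c_null, l_null = null_distribution(w, cfg)
    c_bar = c_null.mean()
    if c_bar == 0:
        raise ValueError("null-ensemble mean clustering is 0; gamma undefined")
    m.gamma = m.C_raw / c_bar
    m.lam = m.L_raw / l_null.mean()
    m.sigma = m.gamma / m.lam
    return m
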