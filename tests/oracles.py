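"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: Floyd–Warshall in
pure Python loops, clustering by explicit triangle enumeration, modularity
by exhaustive partition search, partial correlation from the generating
covariance. Slow, simple, and only run on tiny graphs.
"""

import itertools

import numpy as np


def floyd_warshall_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths over d = 1/w, triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_bruteforce(w: np.ndarray) -> float:
    d = floyd_warshall_distances(w)
    n = w.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


def path_length_bruteforce(w: np.ndarray) -> float:
    d = floyd_warshall_distances(w)
    n = w.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def onnela_clustering_bruteforce(w: np.ndarray) -> float:
    """Per-node geometric-mean triangle intensity by explicit enumeration."""
    n = w.shape[0]
    wh = w / w.max() if w.max() > 0 else w
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        acc = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            acc += (wh[i, a] * wh[i, b] * wh[a, b]) ** (1.0 / 3.0)
        cs.append(2.0 * acc / (k * (k - 1)))
    return float(np.mean(cs))


def _partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_bruteforce(w: np.ndarray) -> tuple[float, list]:
    """Best Newman modularity over all partitions (exhaustive)."""
    n = w.shape[0]
    s = w.sum(axis=1)
    two_m = s.sum()
    best_q, best_part = -np.inf, None
    for part in _partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            labels[block] = ci
        same = labels[:, None] == labels[None, :]
        q = ((w - np.outer(s, s) / two_m) * same).sum() / two_m
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), best_part


def bh_adjust_by_hand(p):
    """Benjamini–Hochberg step-up, written out longhand."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, p[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj
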