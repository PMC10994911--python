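"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (explicit loops, path enumeration)
and shares no code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bf_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by hand-rolled BFS (inf if unreachable)."""
    a = np.asarray(adj) > 0
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0.0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if a[u, v] and v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def bf_local_clustering(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj) > 0
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for u, v in itertools.combinations(nb, 2) if a[u, v])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def bf_global_metrics(adj: np.ndarray):
    """(Cp, Lp, Eglob, Eloc) with the same conventions the package documents."""
    a = np.asarray(adj) > 0
    n = a.shape[0]
    dist = bf_distances(a)
    lengths = [dist[i, j] for i in range(n) for j in range(n)
               if i != j and math.isfinite(dist[i, j])]
    lp = float(np.mean(lengths)) if lengths else float("nan")
    inv = [1.0 / dist[i, j] if math.isfinite(dist[i, j]) and dist[i, j] > 0 else 0.0
           for i in range(n) for j in range(n) if i != j]
    eglob = float(np.mean(inv))
    cp = float(bf_local_clustering(a).mean())

    def sub_eglob(nodes):
        m = len(nodes)
        if m < 2:
            return 0.0
        sub = a[np.ix_(nodes, nodes)]
        d = bf_distances(sub)
        terms = [1.0 / d[i, j] if math.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
                 for i in range(m) for j in range(m) if i != j]
        return float(np.mean(terms))

    eloc = float(np.mean([sub_eglob([j for j in range(n) if a[i, j]])
                          for i in range(n)]))
    return cp, lp, eglob, eloc


def _all_simple_paths(a: np.ndarray, s: int, t: int):
    n = a.shape[0]
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            yield path
            continue
        for v in range(n):
            if a[u, v] and v not in path:
                stack.append((v, path + [v]))


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness, endpoints excluded, each pair counted once."""
    a = np.asarray(adj) > 0
    n = a.shape[0]
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(_all_simple_paths(a, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            out[v] += through / len(sp)
    return out


def bf_phi(adj: np.ndarray, k: int) -> float:
    a = np.asarray(adj) > 0
    deg = a.sum(axis=1)
    nodes = [i for i in range(a.shape[0]) if deg[i] > k]
    if len(nodes) < 2:
        return float("nan")
    e = sum(1 for u, v in itertools.combinations(nodes, 2) if a[u, v])
    m = len(nodes)
    return e / (m * (m - 1) / 2)


def bf_phi_weighted(weights: np.ndarray, adj: np.ndarray, k: int) -> float:
    a = np.asarray(adj) > 0
    w = np.asarray(weights, float)
    deg = a.sum(axis=1)
    nodes = [i for i in range(a.shape[0]) if deg[i] > k]
    if len(nodes) < 2:
        return float("nan")
    rich = [(u, v) for u, v in itertools.combinations(nodes, 2) if a[u, v]]
    if not rich:
        return 0.0
    num = sum(w[u, v] for u, v in rich)
    all_w = sorted(
        (w[u, v] for u, v in itertools.combinations(range(a.shape[0]), 2) if a[u, v]),
        reverse=True,
    )
    return num / sum(all_w[: len(rich)])


def bf_icc_consistency(data: np.ndarray) -> float:
    """Two-way consistency ICC from an explicit ANOVA table (n subjects x k sessions)."""
    d = np.asarray(data, float)
    n, k = d.shape
    grand = d.mean()
    ss_rows = k * sum((d[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((d[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((d - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_b = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_b - ms_e) / (ms_b + (k - 1) * ms_e)


def bf_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def random_small_graph(rng: np.random.Generator, n_max: int = 7) -> np.ndarray:
    """A random connected-ish simple graph with 4..n_max nodes and >= 1 edge."""
    n = int(rng.integers(4, n_max + 1))
    while True:
        a = (rng.random((n, n)) < rng.uniform(0.25, 0.8)).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() > 0:
            return a
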