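"""Graph-theoretical metrics for binary and weighted susceptibility networks.

Conventions (stated because exact tests depend on them):

* clustering coefficient ``Cp`` is the mean of local clustering over *all*
  nodes, nodes of degree < 2 contributing 0;
* characteristic path length ``Lp`` averages shortest-path lengths over
  *connected* pairs only (disconnected pairs are dropped, not infinite);
* global efficiency averages ``1/d(i,j)`` over all pairs, disconnected
  pairs contributing 0, so it is defined on fragmented graphs;
* local efficiency of a node is the global efficiency of the subgraph
  induced on its neighbours (0 for degree < 2);
* betweenness centrality uses unnormalized pair counts with endpoints
  excluded (each unordered pair counted once);
* weighted paths run on lengths ``1/w``; weighted clustering is the
  Onnela geometric-mean-of-triangles form with weights scaled by the
  largest weight in the network.

Small-world normalization (``gamma = Cp/Cp_rand``, ``lambda = Lp/Lp_rand``,
``sigma = gamma/lambda``) averages over degree-preserving Maslov-Sneppen
rewired surrogates (10 x edge-count attempted swaps each), generated by
igraph's C rewiring engine under an explicit seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import ModelError, SurrogateError, UndefinedMetricError
from .network import ThresholdedNetworkSet

DEFAULT_N_RAND = 100
SWAPS_PER_EDGE = 10


# ---------------------------------------------------------------------------
# Binary metrics
# ---------------------------------------------------------------------------

def _check_binary(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise UndefinedMetricError("adjacency must be square")
    if a.shape[0] < 3:
        raise UndefinedMetricError("metrics require at least 3 nodes")
    a = (a > 0).astype(np.uint8)
    np.fill_diagonal(a, 0)
    if not np.array_equal(a, a.T):
        raise UndefinedMetricError("adjacency must be symmetric")
    if a.sum() == 0:
        raise UndefinedMetricError("metrics undefined on an empty graph")
    return a


def _distances_binary(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def local_clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(deg >= 2, 2.0 * triangles / (deg * (deg - 1.0)), 0.0)
    return c


def _pairwise_efficiency_terms(dist: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def _subgraph_eglob(adj: np.ndarray, nodes: np.ndarray) -> float:
    if nodes.size < 2:
        return 0.0
    sub = adj[np.ix_(nodes, nodes)]
    dist = _distances_binary(sub)
    inv = _pairwise_efficiency_terms(dist)
    m = nodes.size
    return float(inv.sum() / (m * (m - 1)))


@dataclass
class GlobalMetrics:
    """Global topology of one network at one sparsity."""

    cp: float
    lp: float
    eglob: float
    eloc: float
    sparsity: float | None = None


def global_metrics(adj: np.ndarray, sparsity: float | None = None) -> GlobalMetrics:
    """Cp, Lp, Eglob and Eloc of a binary network."""
    a = _check_binary(adj)
    n = a.shape[0]
    dist = _distances_binary(a)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lp = float(dist[finite].mean()) if finite.any() else float("nan")
    inv = _pairwise_efficiency_terms(dist)
    eglob = float(inv[off].sum() / (n * (n - 1)))
    eloc = float(
        np.mean([_subgraph_eglob(a, np.flatnonzero(a[i])) for i in range(n)])
    )
    cp = float(local_clustering(a).mean())
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, eloc=eloc, sparsity=sparsity)


@dataclass
class NodalMetrics:
    """Per-node centralities and efficiencies."""

    betweenness: np.ndarray
    degree: np.ndarray
    nodal_eglob: np.ndarray
    nodal_eloc: np.ndarray


def nodal_metrics(adj: np.ndarray) -> NodalMetrics:
    a = _check_binary(adj)
    n = a.shape[0]
    g = nx.from_numpy_array(a)
    btw = np.array([nx.betweenness_centrality(g, normalized=False)[i] for i in range(n)])
    dist = _distances_binary(a)
    inv = _pairwise_efficiency_terms(dist)
    np.fill_diagonal(inv, 0.0)
    nodal_eglob = inv.sum(axis=1) / (n - 1)
    nodal_eloc = np.array([_subgraph_eglob(a, np.flatnonzero(a[i])) for i in range(n)])
    return NodalMetrics(
        betweenness=btw,
        degree=a.sum(axis=1).astype(float),
        nodal_eglob=nodal_eglob,
        nodal_eloc=nodal_eloc,
    )


# ---------------------------------------------------------------------------
# Degree-preserving surrogates and small-world normalization
# ---------------------------------------------------------------------------

def rewire_preserving_degree(
    adj: np.ndarray, seed: int, swaps_per_edge: int = SWAPS_PER_EDGE
) -> np.ndarray:
    """One Maslov-Sneppen rewired surrogate with the same degree sequence.

    Performs ``swaps_per_edge * E`` attempted edge swaps that keep the
    graph simple.  Deterministic for a given seed.
    """
    a = _check_binary(adj)
    n = a.shape[0]
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    g = ig.Graph(n=n, edges=edges)
    ig.set_random_number_generator(random.Random(int(seed)))
    try:
        g.rewire(n=int(swaps_per_edge * len(edges)), mode="simple")
    except ig.InternalError as exc:  # pragma: no cover - pathological graphs
        raise SurrogateError(str(exc)) from exc
    out = np.zeros((n, n), dtype=np.uint8)
    for u, v in g.get_edgelist():
        out[u, v] = out[v, u] = 1
    return out


def _cp_lp(adj: np.ndarray) -> tuple[float, float]:
    dist = _distances_binary(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(dist) & off
    lp = float(dist[finite].mean()) if finite.any() else float("nan")
    return float(local_clustering(adj).mean()), lp


@dataclass
class SmallWorldMetrics:
    """Observed and surrogate-normalized small-world indices."""

    gamma: float
    lam: float
    sigma: float
    cp: float
    lp: float
    cp_rand: float
    lp_rand: float
    n_rand: int
    seed: int


def normalize_small_world(
    adj: np.ndarray, n_rand: int = DEFAULT_N_RAND, seed: int = 0
) -> SmallWorldMetrics:
    """gamma, lambda and sigma against degree-preserving rewired surrogates."""
    a = _check_binary(adj)
    cp, lp = _cp_lp(a)
    cps = np.empty(n_rand)
    lps = np.empty(n_rand)
    for i in range(n_rand):
        r = rewire_preserving_degree(a, seed=seed + i)
        cps[i], lps[i] = _cp_lp(r)
    cp_rand = float(cps.mean())
    lp_rand = float(np.nanmean(lps))
    gamma = cp / cp_rand if cp_rand > 0 else float("nan")
    lam = lp / lp_rand if lp_rand > 0 else float("nan")
    sigma = gamma / lam
    return SmallWorldMetrics(
        gamma=gamma, lam=lam, sigma=sigma, cp=cp, lp=lp,
        cp_rand=cp_rand, lp_rand=lp_rand, n_rand=n_rand, seed=seed,
    )


# ---------------------------------------------------------------------------
# Curves over sparsity and their AUC
# ---------------------------------------------------------------------------

def auc_trapezoid(x, y) -> float:
    """Trapezoidal area under a metric curve (NaN entries dropped pairwise)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise UndefinedMetricError("AUC needs at least 2 finite points")
    return float(np.trapezoid(y[ok], x[ok]))


@dataclass
class MetricCurve:
    """One metric as a function of sparsity, plus its AUC."""

    name: str
    sparsities: np.ndarray
    values: np.ndarray
    auc: float


BINARY_CURVE_METRICS = ("Cp", "Lp", "Eglob", "Eloc")
SMALLWORLD_CURVE_METRICS = ("gamma", "lambda", "sigma")


def metric_curves_and_auc(
    netset: ThresholdedNetworkSet,
    which=BINARY_CURVE_METRICS,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
) -> list[MetricCurve]:
    """Per-sparsity metric curves with trapezoidal AUC over the sparsity range."""
    sp = np.asarray(sorted(netset.binaries), float)
    if sp.size < 2:
        raise UndefinedMetricError("curves need at least 2 sparsities")
    need_sw = any(m in SMALLWORLD_CURVE_METRICS for m in which)
    rows: dict[str, list[float]] = {m: [] for m in which}
    for s in sp:
        adj = netset.binaries[round(float(s), 10)]
        gm = global_metrics(adj, sparsity=float(s))
        base = {"Cp": gm.cp, "Lp": gm.lp, "Eglob": gm.eglob, "Eloc": gm.eloc}
        if need_sw:
            sw = normalize_small_world(adj, n_rand=n_rand, seed=seed)
            base.update({"gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma})
        for m in which:
            rows[m].append(base[m])
    return [
        MetricCurve(
            name=m,
            sparsities=sp,
            values=np.asarray(rows[m], float),
            auc=auc_trapezoid(sp, rows[m]),
        )
        for m in which
    ]


# ---------------------------------------------------------------------------
# Weighted metrics
# ---------------------------------------------------------------------------

def weighted_global_metrics(weights: np.ndarray) -> GlobalMetrics:
    """Cp, Lp, Eglob, Eloc on a positively weighted network.

    Zero entries mean "no edge"; negative weights are a domain error.
    """
    w = np.asarray(weights, dtype=float).copy()
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise UndefinedMetricError("weight matrix must be square")
    np.fill_diagonal(w, 0.0)
    if (w < 0).any():
        raise ModelError("weighted metrics require nonnegative weights")
    if not np.allclose(w, w.T):
        raise UndefinedMetricError("weight matrix must be symmetric")
    n = w.shape[0]
    if n < 3 or w.sum() == 0:
        raise UndefinedMetricError("weighted metrics need >= 3 nodes and an edge")
    adj = (w > 0).astype(np.uint8)

    lengths = np.zeros_like(w)
    lengths[w > 0] = 1.0 / w[w > 0]
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lp = float(dist[finite].mean()) if finite.any() else float("nan")
    inv = _pairwise_efficiency_terms(dist)
    eglob = float(inv[off].sum() / (n * (n - 1)))

    w_hat = w / w.max()
    cbrt = np.cbrt(w_hat)
    deg = adj.sum(axis=1).astype(float)
    tri = np.diag(cbrt @ cbrt @ cbrt) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(deg >= 2, 2.0 * tri / (deg * (deg - 1.0)), 0.0)
    cp = float(c.mean())

    def sub_eglob(i: int) -> float:
        nodes = np.flatnonzero(adj[i])
        if nodes.size < 2:
            return 0.0
        sub = lengths[np.ix_(nodes, nodes)]
        d = shortest_path(csr_matrix(sub), method="D", directed=False)
        m = nodes.size
        return float(_pairwise_efficiency_terms(d).sum() / (m * (m - 1)))

    eloc = float(np.mean([sub_eglob(i) for i in range(n)]))
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, eloc=eloc)
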