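"""Rich-club organization: coefficient curves, normalization, connection classes.

For a degree threshold ``k`` the binary rich-club coefficient is the edge
density of the subgraph induced on nodes of degree > k:

    phi(k) = E_{>k} / [N_{>k} (N_{>k} - 1) / 2]

The weighted variant divides the weight captured inside that subgraph by
the sum of the ``E_{>k}`` strongest edge weights anywhere in the network.
Both are normalized against degree-preserving rewired surrogates (for the
weighted coefficient the observed weight multiset is reshuffled onto the
rewired topology).  phi_norm(k) > 1 over a range of k indicates rich-club
organization.

Hubs are the top ``round(0.12 * N)`` nodes by a reference degree (ties
broken by strength, then node index); edges are then partitioned into
rich-club (hub-hub), feeder (hub-peripheral) and local classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .metrics import _check_binary, rewire_preserving_degree

DEFAULT_HUB_FRACTION = 0.12
DEFAULT_N_RAND = 1000


def phi(adj: np.ndarray, k: int) -> float:
    """Binary rich-club coefficient; NaN when < 2 nodes have degree > k."""
    a = _check_binary(adj)
    deg = a.sum(axis=1)
    nodes = np.flatnonzero(deg > k)
    m = nodes.size
    if m < 2:
        return float("nan")
    e_sub = a[np.ix_(nodes, nodes)].sum() / 2.0
    return float(e_sub / (m * (m - 1) / 2.0))


def phi_weighted(weights: np.ndarray, adj: np.ndarray, k: int) -> float:
    """Weighted rich-club coefficient.

    Ratio of the weight on edges among nodes of degree > k to the summed
    ``E_{>k}`` largest edge weights of the whole network.  NaN when fewer
    than 2 nodes qualify; 0 when they share no edge.
    """
    a = _check_binary(adj)
    w = np.asarray(weights, dtype=float)
    deg = a.sum(axis=1)
    nodes = np.flatnonzero(deg > k)
    if nodes.size < 2:
        return float("nan")
    sub = a[np.ix_(nodes, nodes)]
    e_sub = int(sub.sum()) // 2
    if e_sub == 0:
        return 0.0
    iu, ju = np.nonzero(np.triu(sub, 1))
    w_sub = w[np.ix_(nodes, nodes)][iu, ju].sum()
    gi, gj = np.nonzero(np.triu(a, 1))
    all_w = np.sort(w[gi, gj])[::-1]
    return float(w_sub / all_w[:e_sub].sum())


@dataclass
class RichClubCurve:
    """phi(k) and its surrogate-normalized forms over a degree grid."""

    k: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray
    phi_w: np.ndarray | None = None
    phi_w_norm: np.ndarray | None = None
    n_rand: int = 0
    seed: int = 0


def normalized_richclub(
    adj: np.ndarray,
    weights: np.ndarray | None = None,
    k_grid: np.ndarray | None = None,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
) -> RichClubCurve:
    """Rich-club curve normalized by the mean over rewired surrogates.

    Undefined entries (fewer than 2 qualifying nodes, either observed or
    in every surrogate) are reported as NaN, never fabricated.
    """
    a = _check_binary(adj)
    rng = np.random.default_rng(seed)
    max_deg = int(a.sum(axis=1).max())
    if k_grid is None:
        k_grid = np.arange(1, max(max_deg, 2))
    k_grid = np.asarray(k_grid, dtype=int)
    phi_obs = np.array([phi(a, int(k)) for k in k_grid])
    phi_w_obs = None
    if weights is not None:
        phi_w_obs = np.array([phi_weighted(weights, a, int(k)) for k in k_grid])
        gi, gj = np.nonzero(np.triu(a, 1))
        weight_pool = np.asarray(weights, float)[gi, gj]

    phi_rand = np.empty((n_rand, k_grid.size))
    phi_w_rand = np.empty((n_rand, k_grid.size)) if weights is not None else None
    for i in range(n_rand):
        r = rewire_preserving_degree(a, seed=seed + 1 + i)
        phi_rand[i] = [phi(r, int(k)) for k in k_grid]
        if weights is not None:
            wr = np.zeros_like(np.asarray(weights, float))
            ri, rj = np.nonzero(np.triu(r, 1))
            shuffled = rng.permutation(weight_pool)
            wr[ri, rj] = shuffled
            wr += wr.T
            phi_w_rand[i] = [phi_weighted(wr, r, int(k)) for k in k_grid]

    def _nanmean_cols(arr: np.ndarray) -> np.ndarray:
        """Column-wise nanmean; all-NaN columns (k undefined in every
        surrogate) stay NaN without numpy's empty-slice warning."""
        counts = (~np.isnan(arr)).sum(axis=0)
        sums = np.nansum(arr, axis=0)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rand = _nanmean_cols(phi_rand)
        phi_norm = phi_obs / mean_rand
        phi_w_norm = None
        if weights is not None:
            mean_w_rand = _nanmean_cols(phi_w_rand)
            phi_w_norm = phi_w_obs / mean_w_rand
    return RichClubCurve(
        k=k_grid, phi=phi_obs, phi_norm=phi_norm,
        phi_w=phi_w_obs, phi_w_norm=phi_w_norm, n_rand=n_rand, seed=seed,
    )


# ---------------------------------------------------------------------------
# Hub identification and connection classes
# ---------------------------------------------------------------------------

def hub_nodes(
    reference_degrees: np.ndarray,
    hub_fraction: float = DEFAULT_HUB_FRACTION,
    strengths: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the top ``round(hub_fraction * N)`` nodes by reference degree.

    Degree ties are broken by strength (descending), then node index.
    """
    deg = np.asarray(reference_degrees, dtype=float)
    n = deg.size
    n_hub = int(np.floor(hub_fraction * n + 0.5))
    if n_hub == 0:
        raise ParameterError(f"hub fraction {hub_fraction} selects zero of {n} nodes")
    st = np.zeros(n) if strengths is None else np.asarray(strengths, float)
    order = np.lexsort((np.arange(n), -st, -deg))
    return np.sort(order[:n_hub])


CONNECTION_CLASSES = ("rich-club", "feeder", "local")


@dataclass
class ConnectionClassStats:
    """Edge partition into rich-club / feeder / local, with per-class totals."""

    hubs: np.ndarray
    degree: dict[str, int]
    strength: dict[str, float]

    @property
    def total_degree(self) -> int:
        return sum(self.degree.values())


def classify_connections(
    adj: np.ndarray,
    weights: np.ndarray | None = None,
    hub_fraction: float = DEFAULT_HUB_FRACTION,
    reference_degrees: np.ndarray | None = None,
) -> ConnectionClassStats:
    """Partition a subject's edges by the hub status of their endpoints.

    ``reference_degrees`` holds the degrees that define hubs (typically a
    reference-group mean degree, held fixed across subjects); when omitted
    the subject's own degrees are used (per-subject mode).  Strength is
    the summed weight per class (edge count when no weights are given).
    """
    a = _check_binary(adj)
    ref = a.sum(axis=1).astype(float) if reference_degrees is None else reference_degrees
    st = None
    if weights is not None:
        st = np.asarray(weights, float).sum(axis=1)
    hubs = hub_nodes(ref, hub_fraction=hub_fraction, strengths=st)
    is_hub = np.zeros(a.shape[0], dtype=bool)
    is_hub[hubs] = True
    iu, ju = np.nonzero(np.triu(a, 1))
    n_hub_ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    w = np.ones(iu.size) if weights is None else np.asarray(weights, float)[iu, ju]
    degree = {}
    strength = {}
    for cls, ends in zip(CONNECTION_CLASSES, (2, 1, 0)):
        sel = n_hub_ends == ends
        degree[cls] = int(sel.sum())
        strength[cls] = float(w[sel].sum())
    return ConnectionClassStats(hubs=hubs, degree=degree, strength=strength)
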