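"""Sparsity thresholding of weighted similarity matrices into binary networks.

A sparsity ``S`` keeps the ``round(S * N(N-1)/2)`` strongest off-diagonal
edges (round half up).  Ties are broken by lexicographic (i, j) order so
results are reproducible; since thresholding only consults weight ranks,
it is invariant to any strictly monotone transform of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, ParameterError
from .klse import SusceptibilityMatrix


def default_sparsities(start: float = 0.05, stop: float = 0.40, step: float = 0.01) -> np.ndarray:
    """The standard sparsity grid: 0.05 to 0.40 in steps of 0.01 (36 values)."""
    count = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, count), 10)


def _weights_of(matrix) -> np.ndarray:
    w = matrix.values if isinstance(matrix, SusceptibilityMatrix) else np.asarray(matrix, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ParameterError("weight matrix must be square")
    return w


def threshold_by_sparsity(matrix, sparsity: float) -> np.ndarray:
    """Binary adjacency keeping the top ``round(S * N(N-1)/2)`` edges.

    Returns a symmetric uint8 matrix with a zero diagonal.  Raises
    :class:`EmptyNetworkError` when the requested sparsity keeps no edge.
    """
    w = _weights_of(matrix)
    if not 0.0 < sparsity < 1.0:
        raise ParameterError(f"sparsity must be in (0, 1); got {sparsity}")
    n = w.shape[0]
    m = n * (n - 1) // 2
    k = int(np.floor(sparsity * m + 0.5))  # round half up
    if k == 0:
        raise EmptyNetworkError(f"sparsity {sparsity} keeps zero of {m} edges")
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    order = np.lexsort((ju, iu, -vals))  # weight desc, then (i, j) ascending
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return adj


@dataclass
class ThresholdedNetworkSet:
    """The weighted network plus one binary network per sparsity."""

    weighted: np.ndarray
    sparsities: np.ndarray
    binaries: dict[float, np.ndarray]
    region_ids: list[int] | None = None
    subject_id: str = "subject"
    meta: dict = field(default_factory=dict)

    def binary(self, sparsity: float) -> np.ndarray:
        return self.binaries[round(float(sparsity), 10)]

    def edge_counts(self) -> dict[float, int]:
        return {s: int(a.sum()) // 2 for s, a in self.binaries.items()}


def build_network_set(matrix, sparsities=None) -> ThresholdedNetworkSet:
    """Threshold a weighted matrix across the sparsity grid.

    The weighted matrix is kept untouched (weighted analyses use the raw
    similarities unless a sparsity mask is explicitly requested via
    :func:`masked_weights`).
    """
    w = _weights_of(matrix)
    sp = default_sparsities() if sparsities is None else np.asarray(sparsities, float)
    binaries = {round(float(s), 10): threshold_by_sparsity(w, float(s)) for s in sp}
    region_ids = None
    subject_id = "subject"
    if isinstance(matrix, SusceptibilityMatrix):
        region_ids = list(matrix.region_ids)
        subject_id = matrix.subject_id
    return ThresholdedNetworkSet(
        weighted=w,
        sparsities=sp,
        binaries=binaries,
        region_ids=region_ids,
        subject_id=subject_id,
    )


def masked_weights(matrix, sparsity: float) -> np.ndarray:
    """Weights retained at a sparsity threshold, zero elsewhere."""
    w = _weights_of(matrix)
    adj = threshold_by_sparsity(w, sparsity)
    out = np.where(adj > 0, w, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def write_edge_list(netset: ThresholdedNetworkSet, path) -> None:
    """All retained edges as TSV rows (region_i, region_j, weight, sparsity)."""
    ids = netset.region_ids or list(range(1, netset.weighted.shape[0] + 1))
    rows = []
    for s in sorted(netset.binaries):
        adj = netset.binaries[s]
        iu, ju = np.nonzero(np.triu(adj, 1))
        for a, b in zip(iu, ju):
            rows.append((ids[a], ids[b], netset.weighted[a, b], s))
    pd.DataFrame(
        rows, columns=["region_i", "region_j", "weight", "sparsity"]
    ).to_csv(path, sep="\t", index=False)
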