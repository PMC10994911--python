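"""Test-retest reliability of susceptibility networks.

Group level: Pearson correlation between the upper triangles of the two
session-mean similarity matrices (the diagonal is fixed at 1 and would
inflate r, so it is excluded).  Individual level: per-connection
intraclass correlation of the two-way mixed, single-measures, consistency
form

    ICC = (MS_B - MS_E) / (MS_B + (k - 1) MS_E)

where ``MS_B`` is the between-subjects mean square, ``MS_E`` the error
mean square of the subject x session two-way table, and ``k`` the number
of sessions (2 for a standard test-retest design; general k supported).
Being a consistency ICC it is invariant both to subject-constant offsets
and to a global session offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AlignmentError, ModelError
from .klse import SusceptibilityMatrix


def _stack_sessions(session1, session2) -> tuple[np.ndarray, list[int]]:
    """Upper-triangle feature matrix of shape (n_subjects, 2, n_edges)."""
    if len(session1) != len(session2) or len(session1) < 2:
        raise AlignmentError("sessions must pair the same subjects (>= 2)")
    region_ids = None
    rows = []
    for m1, m2 in zip(session1, session2):
        for m in (m1, m2):
            if not isinstance(m, SusceptibilityMatrix):
                raise AlignmentError("expected SusceptibilityMatrix inputs")
        if m1.region_ids != m2.region_ids:
            raise AlignmentError("region sets differ between sessions")
        if region_ids is None:
            region_ids = list(m1.region_ids)
        elif m1.region_ids != region_ids:
            raise AlignmentError("region sets differ across subjects")
        iu = np.triu_indices(len(region_ids), 1)
        rows.append(np.stack([m1.values[iu], m2.values[iu]]))
    return np.stack(rows), region_ids


def group_spatial_correlation(session1, session2) -> float:
    """Pearson r between the session-mean matrices' upper triangles."""
    data, _ = _stack_sessions(session1, session2)
    mean1 = data[:, 0, :].mean(axis=0)
    mean2 = data[:, 1, :].mean(axis=0)
    r, _ = sps.pearsonr(mean1, mean2)
    return float(r)


@dataclass
class ICCResult:
    """Per-connection consistency ICC plus its summary."""

    icc: np.ndarray
    icc_mean: float
    icc_sd: float
    ms_b: np.ndarray
    ms_e: np.ndarray
    k_sessions: int
    icc_matrix: np.ndarray | None = None
    region_ids: list[int] | None = None


def icc_consistency_from_array(data: np.ndarray) -> ICCResult:
    """Consistency ICC per feature from a (subjects, sessions, features) array."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    n, k, _ = data.shape
    if n < 3:
        raise ModelError("ICC needs at least 3 subjects for error degrees of freedom")
    if k < 2:
        raise ModelError("ICC needs at least 2 sessions")
    grand = data.mean(axis=(0, 1))
    row_means = data.mean(axis=1)      # (n, F)
    col_means = data.mean(axis=0)      # (k, F)
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_b = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_b + (k - 1) * ms_e
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (ms_b - ms_e) / denom, np.nan)
    ok = np.isfinite(icc)
    return ICCResult(
        icc=icc,
        icc_mean=float(icc[ok].mean()) if ok.any() else float("nan"),
        icc_sd=float(icc[ok].std(ddof=1)) if ok.sum() > 1 else float("nan"),
        ms_b=ms_b,
        ms_e=ms_e,
        k_sessions=k,
    )


def icc_consistency(session1, session2) -> ICCResult:
    """Per-connection ICC between two sessions of similarity matrices.

    Also fills ``icc_matrix``: a symmetric N x N matrix of per-connection
    ICC values with NaN on the (constant) diagonal.
    """
    data, region_ids = _stack_sessions(session1, session2)
    res = icc_consistency_from_array(data)
    n_reg = len(region_ids)
    mat = np.full((n_reg, n_reg), np.nan)
    iu = np.triu_indices(n_reg, 1)
    mat[iu] = res.icc
    mat[(iu[1], iu[0])] = res.icc
    res.icc_matrix = mat
    res.region_ids = region_ids
    return res
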