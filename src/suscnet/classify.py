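"""Sparse (l1) logistic regression on vectorized connectivity features.

The classifier minimizes the convex, nonsmooth objective

    (1/n) sum_i log(1 + exp(-y_i (W^T x_i + b))) + lambda * ||W||_1

with labels y in {-1, +1}; the intercept b is unpenalized.  The solver is
FISTA (accelerated proximal gradient with adaptive restart); the soft
threshold yields exact zeros, so "selected features" means literally
W_j != 0 up to a 1e-8 tolerance.  Evaluation follows a leave-one-out
cross-validation: each subject is scored by a model trained on all
others, decision threshold 0 on W^T x + b, ROC from the pooled continuous
scores, and per-feature selection frequency across folds.

The positive class (+1) is the patient group; sensitivity is defined on
patients, specificity on the reference group.  Features are KLSE values,
which already share the (0, 1] scale, so no standardization is applied by
default (a flag exists and is recorded in the report when used).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import AlignmentError, ModelError
from .klse import SusceptibilityMatrix

DEFAULT_LAMBDA = 0.01
NONZERO_TOL = 1e-8


@dataclass
class FeatureSet:
    """Subjects x edges design built from upper-triangle vectorization."""

    X: np.ndarray
    y: np.ndarray
    edge_index: list[tuple[int, int]]
    region_ids: list[int]
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def vectorize_edges(matrices, y=None) -> FeatureSet:
    """Stack each subject's upper triangle into a feature row.

    Columns follow fixed lexicographic (i, j) order; ``edge_index`` maps
    each column back to its region-id pair.  ``y`` (labels in {-1, +1})
    may be attached now or later.
    """
    region_ids = None
    rows = []
    subject_ids = []
    for m in matrices:
        if not isinstance(m, SusceptibilityMatrix):
            raise AlignmentError("expected SusceptibilityMatrix inputs")
        if region_ids is None:
            region_ids = list(m.region_ids)
        elif m.region_ids != region_ids:
            raise AlignmentError(f"subject {m.subject_id!r} has a different region set")
        iu = np.triu_indices(len(region_ids), 1)
        rows.append(m.values[iu])
        subject_ids.append(m.subject_id)
    iu = np.triu_indices(len(region_ids), 1)
    edge_index = [(region_ids[a], region_ids[b]) for a, b in zip(*iu)]
    y_arr = np.array([]) if y is None else _check_labels(np.asarray(y))
    return FeatureSet(
        X=np.vstack(rows), y=y_arr, edge_index=edge_index,
        region_ids=region_ids, subject_ids=subject_ids,
    )


def unvectorize(vec: np.ndarray, n_regions: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of the upper-triangle vectorization."""
    out = np.full((n_regions, n_regions), diagonal, dtype=float)
    iu = np.triu_indices(n_regions, 1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ModelError("labels must be -1 or +1")
    return y


# ---------------------------------------------------------------------------
# FISTA solver
# ---------------------------------------------------------------------------

def slr_objective(X, y, w, b, lambda_reg: float) -> float:
    """Mean logistic loss plus l1 penalty on the weights (not the intercept)."""
    margin = y * (X @ w + b)
    return float(np.mean(np.logaddexp(0.0, -margin)) + lambda_reg * np.abs(w).sum())


@dataclass
class SLRModel:
    """A fitted sparse logistic regression."""

    W: np.ndarray
    b: float
    lambda_reg: float
    objective: float
    n_iter: int
    converged: bool
    tol: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X) >= 0, 1.0, -1.0)

    @property
    def n_selected(self) -> int:
        return int((np.abs(self.W) > NONZERO_TOL).sum())


def fit_slr(
    X,
    y,
    lambda_reg: float = DEFAULT_LAMBDA,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> SLRModel:
    """Fit the l1 logistic objective with FISTA.

    The gradient of the mean logistic loss is (1/(4n)) ||[X, 1]||_2^2
    Lipschitz, which fixes the step size; momentum restarts whenever the
    objective increases.  Convergence is declared when the relative
    objective change stays below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, d = X.shape
    if n < 4:
        raise ModelError("need at least 4 subjects to fit")
    if np.unique(y).size < 2:
        raise ModelError("labels contain a single class")
    x1 = np.column_stack([X, np.ones(n)])
    lip = float(np.linalg.norm(x1, 2) ** 2) / (4.0 * n)
    step = 1.0 / lip

    theta = np.zeros(d + 1)
    z = theta.copy()
    t_k = 1.0
    f_prev = slr_objective(X, y, theta[:d], theta[d], lambda_reg)
    n_small = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        margin = y * (x1 @ z)
        sigma = 1.0 / (1.0 + np.exp(margin))  # = logistic(-margin)
        grad = -(x1.T @ (y * sigma)) / n
        cand = z - step * grad
        new = np.empty_like(cand)
        thr = step * lambda_reg
        new[:d] = np.sign(cand[:d]) * np.maximum(np.abs(cand[:d]) - thr, 0.0)
        new[d] = cand[d]
        f_new = slr_objective(X, y, new[:d], new[d], lambda_reg)
        if f_new > f_prev:  # adaptive restart
            t_k = 1.0
            z = theta.copy()
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        z = new + ((t_k - 1.0) / t_next) * (new - theta)
        theta = new
        t_k = t_next
        if abs(f_prev - f_new) <= tol * max(1.0, abs(f_new)):
            n_small += 1
            if n_small >= 3:
                converged = True
                f_prev = f_new
                break
        else:
            n_small = 0
        f_prev = f_new
    return SLRModel(
        W=theta[:d], b=float(theta[d]), lambda_reg=lambda_reg,
        objective=slr_objective(X, y, theta[:d], theta[d], lambda_reg),
        n_iter=it, converged=converged, tol=tol,
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Pooled LOOCV performance and per-feature selection statistics."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    scores: np.ndarray
    predictions: np.ndarray
    y: np.ndarray
    selection_frequency: np.ndarray
    mean_weight: np.ndarray
    lambda_reg: float
    n_folds: int
    skipped_folds: list[int] = field(default_factory=list)
    standardized: bool = False


def loocv_classify(
    features,
    y=None,
    lambda_reg: float = DEFAULT_LAMBDA,
    tol: float = 1e-9,
    standardize: bool = False,
) -> ClassificationReport:
    """Leave-one-out evaluation of the sparse logistic classifier.

    ``features`` is a :class:`FeatureSet` (labels taken from it unless
    ``y`` is given) or a plain (n, d) array with ``y`` supplied.  A fold
    whose training split collapses to a single class is skipped and
    reported; this only happens when one class has a single member.
    """
    if isinstance(features, FeatureSet):
        X = features.X
        y = features.y if y is None else _check_labels(np.asarray(y))
    else:
        X = np.asarray(features, dtype=float)
        y = _check_labels(np.asarray(y))
    n = X.shape[0]
    if n < 6:
        raise ModelError("LOOCV needs at least 6 subjects")
    scores = np.full(n, np.nan)
    selected = np.zeros(X.shape[1])
    weight_sum = np.zeros(X.shape[1])
    skipped = []
    n_fit = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            skipped.append(i)
            continue
        x_tr = X[mask]
        mu = x_tr.mean(axis=0) if standardize else 0.0
        sd = np.where(x_tr.std(axis=0) > 0, x_tr.std(axis=0), 1.0) if standardize else 1.0
        model = fit_slr((x_tr - mu) / sd, y[mask], lambda_reg=lambda_reg, tol=tol)
        scores[i] = model.decision_scores(((X[i] - mu) / sd)[None, :])[0]
        selected += np.abs(model.W) > NONZERO_TOL
        weight_sum += model.W
        n_fit += 1
    if n_fit == 0:
        raise ModelError("no valid LOOCV fold")
    valid = ~np.isnan(scores)
    preds = np.where(scores[valid] >= 0, 1.0, -1.0)
    truth = y[valid]
    tp = int(((preds == 1) & (truth == 1)).sum())
    tn = int(((preds == -1) & (truth == -1)).sum())
    fp = int(((preds == 1) & (truth == -1)).sum())
    fn = int(((preds == -1) & (truth == 1)).sum())
    accuracy = (tp + tn) / valid.sum()
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    auc = float(roc_auc_score(truth == 1, scores[valid]))
    return ClassificationReport(
        accuracy=float(accuracy), sensitivity=float(sensitivity),
        specificity=float(specificity), auc=auc,
        scores=scores, predictions=np.where(scores >= 0, 1.0, -1.0), y=y,
        selection_frequency=selected / n_fit, mean_weight=weight_sum / n_fit,
        lambda_reg=lambda_reg, n_folds=n_fit, skipped_folds=skipped,
        standardized=standardize,
    )


def selected_features(
    model_or_report,
    feature_set: FeatureSet,
    partition: dict[int, str] | None = None,
    rank_by: str = "weight",
) -> pd.DataFrame:
    """Nonzero features mapped back to region pairs (and network pairs).

    Ranked by |weight| (``rank_by="weight"``) or by LOOCV selection
    frequency (``rank_by="frequency"``, reports only).
    """
    if isinstance(model_or_report, SLRModel):
        weight = model_or_report.W
        frequency = (np.abs(weight) > NONZERO_TOL).astype(float)
    else:
        weight = model_or_report.mean_weight
        frequency = model_or_report.selection_frequency
    sel = np.flatnonzero((np.abs(weight) > NONZERO_TOL) | (frequency > 0))
    df = pd.DataFrame(
        {
            "feature": sel,
            "region_i": [feature_set.edge_index[j][0] for j in sel],
            "region_j": [feature_set.edge_index[j][1] for j in sel],
            "weight": weight[sel],
            "frequency": frequency[sel],
        }
    )
    if partition is not None:
        df["network_pair"] = [
            "-".join(sorted((partition[a], partition[b])))
            for a, b in zip(df["region_i"], df["region_j"])
        ]
    key = "frequency" if rank_by == "frequency" else "weight"
    df = df.reindex(
        df[key].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    return df
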