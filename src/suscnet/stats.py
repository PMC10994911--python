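"""Covariate-adjusted group comparison, permutation tests, edge labeling, mediation.

Group differences in network metrics are tested with a linear model
``value ~ group + age + gender + education`` (t for two groups, F for
three or more).  Edgewise inference uses a Freedman-Lane permutation
scheme: nuisance covariates are regressed out, the residuals are permuted,
the full-model statistic is recomputed, and

    p = (1 + #{perm >= observed}) / (1 + n_perm)

so the smallest attainable p is ``1/(n_perm + 1)``.  Mediation follows the
classic three-regression decomposition (a, b, c, c') with a bias-corrected
(BC, no acceleration) percentile bootstrap interval for the indirect
effect a*b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CatalogError, CollinearityError, ModelError, ParameterError
from .roi_io import CohortDesign

DEFAULT_COVARIATES = ("age", "gender", "education")
DEFAULT_EDGE_ALPHA = 0.001
DEFAULT_NODE_ALPHA = 0.05


def _design_frame(design) -> pd.DataFrame:
    return design.table if isinstance(design, CohortDesign) else pd.DataFrame(design)


def _covariate_matrix(df: pd.DataFrame, covariates) -> np.ndarray:
    """Intercept + covariates; categorical covariates are dummy-coded."""
    cols = [np.ones(len(df))]
    for c in covariates:
        v = df[c]
        if v.isna().any():
            raise ModelError(f"covariate {c!r} has missing values")
        if v.dtype == object or str(v.dtype) == "category":
            codes, _ = pd.factorize(v, sort=True)
            dummies = pd.get_dummies(codes, drop_first=True).to_numpy(float)
            for j in range(dummies.shape[1]):
                cols.append(dummies[:, j])
        else:
            cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def _group_dummies(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    groups = sorted(df["group"].astype(str).unique())
    if len(groups) < 2:
        raise ModelError("need at least 2 groups")
    g = df["group"].astype(str)
    cols = [(g == lev).to_numpy(float) for lev in groups[1:]]  # reference = first
    return np.column_stack(cols), groups


def _partial_f(y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray,
               q: int, dfe: int) -> tuple[np.ndarray, np.ndarray]:
    """Partial F for the terms in x_full beyond x_reduced; vectorized over columns of y."""
    beta_f, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(x_reduced, y, rcond=None)
    rss_f = ((y - x_full @ beta_f) ** 2).sum(axis=0)
    rss_r = ((y - x_reduced @ beta_r) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / q) / (rss_f / dfe)
    f = np.where(rss_f <= 0, np.where(rss_r - rss_f <= 0, 0.0, np.inf), f)
    f = np.where(np.isnan(f), 0.0, np.maximum(f, 0.0))
    return f, beta_f


def adjusted_group_test(values, design, covariates=DEFAULT_COVARIATES):
    """Covariate-adjusted group test on one scalar per subject.

    Returns ``(t, p)`` for two groups (sign follows the second group minus
    the reference, groups sorted alphabetically) and ``(F, p)`` for three
    or more.
    """
    df = _design_frame(design)
    y = np.asarray(values, dtype=float).reshape(len(df), 1)
    z = _covariate_matrix(df, covariates)
    g, groups = _group_dummies(df)
    counts = df["group"].value_counts()
    if (counts < 3).any():
        raise ModelError("every group needs at least 3 subjects")
    x = np.column_stack([g, z])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    q = g.shape[1]
    dfe = len(df) - x.shape[1]
    f, beta = _partial_f(y, x, z, q, dfe)
    f = float(f[0])
    if len(groups) == 2:
        t = float(np.sign(beta[0, 0]) * np.sqrt(f))
        p = 2.0 * sps.t.sf(abs(t), dfe)
        return t, float(p)
    return f, float(sps.f.sf(f, q, dfe))


@dataclass
class EdgeComparisonResult:
    """Per-feature permutation statistics for a group comparison."""

    statistic: np.ndarray
    p_perm: np.ndarray
    significant: np.ndarray
    direction: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    groups: list[str]
    network_pair: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": np.arange(self.statistic.size),
                "statistic": self.statistic,
                "p_perm": self.p_perm,
                "significant": self.significant,
                "direction": self.direction,
            }
        )
        if self.network_pair is not None:
            df["network_pair"] = self.network_pair
        return df


def permutation_test(
    values_matrix,
    design,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = DEFAULT_EDGE_ALPHA,
    covariates=DEFAULT_COVARIATES,
) -> EdgeComparisonResult:
    """Freedman-Lane permutation test of group effects, one feature per column.

    The statistic is the partial F for the group terms after covariate
    adjustment (equivalently |t| for two groups); ``direction`` carries the
    sign of the non-reference group coefficient in the two-group case.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be at least 100")
    df = _design_frame(design)
    y = np.asarray(values_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != len(df):
        raise ModelError("values_matrix rows must match the design table")
    if 1.0 / (n_perm + 1) > alpha:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} cannot resolve alpha={alpha}; "
            f"minimum attainable p is {1.0 / (n_perm + 1):.2g}",
            UserWarning,
            stacklevel=2,
        )
    z = _covariate_matrix(df, covariates)
    g, groups = _group_dummies(df)
    x = np.column_stack([g, z])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    q = g.shape[1]
    n = len(df)
    dfe = n - x.shape[1]

    f_obs, beta_obs = _partial_f(y, x, z, q, dfe)
    direction = np.sign(beta_obs[0]) if len(groups) == 2 else np.zeros(y.shape[1])

    # Freedman-Lane: permute residuals from the nuisance-only model.
    beta_z, *_ = np.linalg.lstsq(z, y, rcond=None)
    fitted_z = z @ beta_z
    resid_z = y - fitted_z
    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted_z + resid_z[perm]
        f_star, _ = _partial_f(y_star, x, z, q, dfe)
        exceed += f_star >= f_obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    stat = direction * np.sqrt(f_obs) if len(groups) == 2 else f_obs
    return EdgeComparisonResult(
        statistic=stat,
        p_perm=p,
        significant=p < alpha,
        direction=direction,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        groups=groups,
    )


def label_edges_by_network(edges, partition: dict[int, str]):
    """Label edges by the functional networks of their endpoint regions.

    Returns ``(labels, counts)`` where labels are alphabetically ordered
    pair strings such as ``"DMN-VN"`` and counts is a Series over the
    unordered network pairs present.
    """
    labels = []
    for i, j in edges:
        try:
            a, b = partition[int(i)], partition[int(j)]
        except KeyError as exc:
            raise CatalogError(f"region {exc.args[0]} has no network assignment") from exc
        labels.append("-".join(sorted((a, b))))
    counts = pd.Series(labels, dtype="object").value_counts().sort_index()
    return labels, counts


@dataclass
class MediationResult:
    """Path coefficients and BC bootstrap interval for an indirect effect."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    conf_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
            "indirect": self.indirect, "ci": [self.ci_low, self.ci_high],
            "n_boot": self.n_boot, "seed": self.seed, "conf_level": self.conf_level,
        }


def _batched_coef(x: np.ndarray, y: np.ndarray, idx: np.ndarray, col: int) -> np.ndarray:
    """OLS coefficient ``col`` across bootstrap resamples given row indices."""
    xb = x[idx]                      # (B, n, p)
    yb = y[idx][..., None]           # (B, n, 1)
    gram = np.einsum("bni,bnj->bij", xb, xb)
    rhs = np.einsum("bni,bnj->bij", xb, yb)
    beta = np.linalg.solve(gram, rhs)
    return beta[:, col, 0]


def mediation(
    x, m, y, covariates=None, n_boot: int = 5000, seed: int = 0,
    conf_level: float = 0.95,
) -> MediationResult:
    """Mediation of the x -> y relationship through m, with covariates.

    Fits the three OLS regressions (m ~ x + C for path a; y ~ x + m + C for
    b and the direct effect c'; y ~ x + C for the total effect c) and
    bootstraps the indirect effect a*b with a bias-corrected percentile
    interval.  With identical covariate sets, a*b + c' = c exactly.
    """
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    if n < 20:
        raise ModelError("mediation requires at least 20 subjects")
    if min(x.std(), m.std(), y.std()) <= 0:
        raise ModelError("degenerate variance in x, m or y")
    c_mat = None
    if covariates is not None:
        c_mat = np.asarray(covariates, float)
        if c_mat.ndim == 1:
            c_mat = c_mat[:, None]
        if np.isnan(c_mat).any():
            raise ModelError("covariates contain missing values")

    def design(*cols):
        parts = [np.ones(n)] + list(cols)
        if c_mat is not None:
            parts.append(c_mat)
        return np.column_stack(parts)

    xa = design(x)        # m ~ 1 + x (+C)
    xb = design(x, m)     # y ~ 1 + x + m (+C)
    beta_a, *_ = np.linalg.lstsq(xa, m, rcond=None)
    beta_b, *_ = np.linalg.lstsq(xb, y, rcond=None)
    beta_c, *_ = np.linalg.lstsq(xa, y, rcond=None)
    a = float(beta_a[1])
    c_prime = float(beta_b[1])
    b = float(beta_b[2])
    c_total = float(beta_c[1])
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_a = _batched_coef(xa, m, idx, 1)
    boot_b = _batched_coef(xb, y, idx, 2)
    boot = boot_a * boot_b

    alpha = 1.0 - conf_level
    prop = np.mean(boot < indirect)
    prop = min(max(prop, 1.0 / (n_boot + 1)), 1.0 - 1.0 / (n_boot + 1))
    z0 = sps.norm.ppf(prop)
    lo_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(alpha / 2))
    hi_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(1 - alpha / 2))
    ci_low, ci_high = np.quantile(boot, [lo_q, hi_q])
    return MediationResult(
        a=a, b=b, c=c_total, c_prime=c_prime, indirect=indirect,
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_boot=n_boot, seed=seed, conf_level=conf_level,
    )
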