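"""Permutational multivariate statistics for the motion analysis.

Four tools: the Escoufier RV coefficient (matrix covariation between two
variable blocks) with a row-permutation test; a permutational multivariate
regression (adonis-style pseudo-F on Euclidean distances, equivalent to
redundancy analysis for Euclidean response tables); a dispersion
(morpho-space occupation) comparison; and outlier detection by ordered
squared robust Mahalanobis distances with a minimum-covariance-determinant
(MCD) location/scatter estimate.

All permutation procedures are seeded and report
``p = (exceedances + 1) / (n_permutations + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from sklearn.covariance import MinCovDet


@dataclass
class RVResult:
    """RV coefficient between two blocks, optionally with a permutation p-value."""

    rv: float
    p_value: float | None
    p: int  # columns in block 1
    q: int  # columns in block 2
    n_permutations: int | None = None


@dataclass
class PermTestResult:
    """Pseudo-F permutation test result for a multivariate linear model."""

    statistic: float
    adjusted_r_squared: float
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class OutlierResult:
    """Ordered squared robust Mahalanobis distances and outlier flags."""

    squared_distances: np.ndarray  # in input row order
    order: np.ndarray  # argsort of distances, ascending
    flags: np.ndarray  # bool, input row order
    threshold: float
    quantile: float


def _center(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return x - x.mean(axis=0)


def _rv_statistic(x1c: np.ndarray, x2c: np.ndarray) -> float:
    n = x1c.shape[0]
    a1 = x1c.T @ x1c / (n - 1)
    a2 = x2c.T @ x2c / (n - 1)
    a12 = x1c.T @ x2c / (n - 1)
    num = np.sum(a12 * a12)  # trace(A12 A21)
    den = np.sqrt(np.sum(a1 * a1) * np.sum(a2 * a2))
    if den <= 0:
        raise ValueError("zero variance in one block")
    return float(num / den)


def rv_coefficient(x1: np.ndarray, x2: np.ndarray) -> RVResult:
    """Escoufier RV coefficient between two blocks of variables.

    ``RV = trace(A12 A21) / sqrt(trace(A1 A1) trace(A2 A2))`` where the
    ``A`` blocks are the covariance blocks of the combined vector
    ``x = (x1, x2)``.  Lies in [0, 1]; the matrix analog of a squared
    correlation.  Invariant under separate orthogonal rotation and common
    rescaling of either block.
    """
    x1c, x2c = _center(x1), _center(x2)
    if x1c.shape[0] != x2c.shape[0]:
        raise ValueError("blocks must have equal row counts")
    if x1c.shape[0] < 3:
        raise ValueError("need at least three rows")
    return RVResult(rv=_rv_statistic(x1c, x2c), p_value=None,
                    p=x1c.shape[1], q=x2c.shape[1])


def rv_permutation_test(x1: np.ndarray, x2: np.ndarray, n_perm: int = 999,
                        seed: int = 0) -> RVResult:
    """Permutation test of block association: rows of ``x2`` are shuffled.

    ``p = (#{RV_perm >= RV_obs} + 1) / (n_perm + 1)``; reproducible for a
    fixed seed.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-values are coarse")
    x1c, x2c = _center(x1), _center(x2)
    obs = _rv_statistic(x1c, x2c)
    rng = np.random.default_rng(seed)
    exceed = 0
    n = x1c.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _rv_statistic(x1c, x2c[perm]) >= obs - 1e-12:
            exceed += 1
    return RVResult(rv=obs, p_value=(exceed + 1) / (n_perm + 1),
                    p=x1c.shape[1], q=x2c.shape[1], n_permutations=n_perm)


def permanova_regression(y: np.ndarray, x: np.ndarray, n_perm: int = 999,
                         seed: int = 0) -> PermTestResult:
    """Permutational multivariate regression of a response table on predictors.

    Euclidean-distance pseudo-F for the model ``y ~ x`` (adonis-style;
    identical to the redundancy-analysis F for Euclidean responses):
    ``F = (SS_model / r) / (SS_residual / (n - r - 1))`` with sums of
    squares from the hat-matrix projection of the column-centered
    response.  The p-value permutes response rows; ``adjusted R^2 =
    1 - (1 - R^2)(n - 1)/(n - r - 1)``.  Collinear predictor columns are
    dropped with a warning.
    """
    yc = _center(y)
    xm = np.atleast_2d(np.asarray(x, dtype=float))
    if xm.ndim == 2 and xm.shape[0] == 1 and yc.shape[0] != 1:
        xm = xm.T
    n = yc.shape[0]
    if xm.shape[0] != n:
        raise ValueError("response and predictors must have equal row counts")

    design = np.column_stack([np.ones(n), xm])
    q, r_mat, piv = _qr_drop_collinear(design)
    rank = q.shape[1]
    r = rank - 1  # predictor degrees of freedom (intercept removed)
    if r < 1:
        raise ValueError("no usable (non-constant) predictor columns")
    if r + 1 >= n:
        raise ValueError("model is saturated: need n > r + 1")
    if rank < design.shape[1]:
        warnings.warn(f"dropped {design.shape[1] - rank} collinear predictor column(s)")

    hat = q @ q.T
    gram = yc @ yc.T
    ss_total = float(np.trace(gram))
    if ss_total <= 0:
        raise ValueError("response table has zero variance")
    ss_model = float(np.sum(hat * gram))
    ss_resid = ss_total - ss_model
    df_resid = n - r - 1
    f_obs = (ss_model / r) / (ss_resid / df_resid)
    r2 = ss_model / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssm = float(np.sum(hat * gram[np.ix_(perm, perm)]))
        f_perm = (ssm / r) / ((ss_total - ssm) / df_resid)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    return PermTestResult(statistic=f_obs, adjusted_r_squared=adj_r2, r_squared=r2,
                          p_value=(exceed + 1) / (n_perm + 1), n_permutations=n_perm)


def _qr_drop_collinear(design: np.ndarray):
    """Thin QR keeping a maximal independent column subset (pivoted)."""
    q, r_mat, piv = None, None, None
    from scipy.linalg import qr

    q_full, r_full, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r_full))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    q, r_mat = np.linalg.qr(design[:, keep])
    return q, r_mat, keep


def dispersion_comparison(distances_a: np.ndarray, distances_b: np.ndarray,
                          n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """Permutation test of equal mean dispersion between two embeddings.

    Inputs are per-observation distances to the respective consensus (the
    betadisper idea).  The statistic is the one-way pseudo-F for the group
    factor; group membership is permuted across the pooled distances.
    """
    a = np.asarray(distances_a, dtype=float).ravel()
    b = np.asarray(distances_b, dtype=float).ravel()
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(len(a), dtype=int), np.ones(len(b), dtype=int)])
    n = len(pooled)

    def pseudo_f(vals: np.ndarray, lab: np.ndarray) -> tuple[float, float]:
        grand = vals.mean()
        ss_total = np.sum((vals - grand) ** 2)
        ss_within = sum(np.sum((vals[lab == g] - vals[lab == g].mean()) ** 2)
                        for g in (0, 1))
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return (np.inf if ss_between > 0 else 0.0), ss_total
        return float((ss_between / 1) / (ss_within / (n - 2))), ss_total

    f_obs, ss_total = pseudo_f(pooled, labels)
    r2 = 0.0
    if ss_total > 0 and np.isfinite(f_obs):
        r2 = f_obs / (f_obs + n - 2)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(pooled, labels[rng.permutation(n)])
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    return PermTestResult(statistic=f_obs, adjusted_r_squared=adj_r2, r_squared=r2,
                          p_value=(exceed + 1) / (n_perm + 1), n_permutations=n_perm)


def robust_mahalanobis_outliers(scores: np.ndarray, quantile: float = 0.975,
                                support_fraction: float = 0.75,
                                seed: int = 0) -> OutlierResult:
    """Outlier test on ordered squared robust Mahalanobis distances.

    Location and scatter come from the minimum-covariance-determinant
    estimator (seeded, deterministic); observations whose squared distance
    exceeds the chi-square quantile (default 0.975 at ``d`` degrees of
    freedom) are flagged.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    n, d = x.shape
    if n < 10:
        raise ValueError("need at least 10 observations for a stable MCD estimate")
    mcd = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(x)
    if np.linalg.matrix_rank(mcd.covariance_) < d:
        raise np.linalg.LinAlgError("singular robust covariance")
    d2 = mcd.mahalanobis(x)  # squared distances
    threshold = float(sp_stats.chi2.ppf(quantile, df=d))
    return OutlierResult(
        squared_distances=d2,
        order=np.argsort(d2),
        flags=d2 > threshold,
        threshold=threshold,
        quantile=quantile,
    )
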