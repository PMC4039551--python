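"""REML fitting of the two-level random-intercept linear model.

The model is ``y = X beta + u_cluster + e`` with ``u ~ N(0, sigma_b2)`` and
``e ~ N(0, sigma_w2)``. Restricted maximum likelihood is computed by
profiling: for a given variance ratio ``r = sigma_b2 / sigma_w2`` the GLS
estimates and the residual scale have closed forms built from per-cluster
sufficient statistics, leaving a one-dimensional criterion minimised over
``r >= 0`` (boundary allowed). Inference on the fixed effects uses the
Wald z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["RandomInterceptModel", "FitResult", "fit_random_intercept", "significant"]

_LOG_RATIO_LO, _LOG_RATIO_HI = -16.0, 8.0


def _cluster_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Sort by cluster and accumulate the per-cluster sufficient statistics."""
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, starts, sizes = np.unique(gs, return_index=True, return_counts=True)
    A = np.add.reduceat(Xs, starts, axis=0)  # per-cluster column sums of X
    S = np.add.reduceat(ys, starts)  # per-cluster sums of y
    G = Xs.T @ Xs
    Xty = Xs.T @ ys
    yty = float(ys @ ys)
    return A, S, sizes.astype(float), G, Xty, yty


def _profiled_reml(ratio, A, S, sizes, G, Xty, yty, n, p):
    """Return (-2 profiled REML up to a constant, beta, XtWiX, rss) at this ratio."""
    shrink = ratio / (1.0 + sizes * ratio)  # lambda/(1+n_j lambda) per cluster
    XtWiX = G - (A * shrink[:, None]).T @ A
    XtWiy = Xty - A.T @ (shrink * S)
    yWiy = yty - float(shrink @ S**2)
    beta = np.linalg.solve(XtWiX, XtWiy)
    rss = max(yWiy - float(beta @ XtWiy), 1e-300)
    sign, logdet_x = np.linalg.slogdet(XtWiX)
    crit = (n - p) * np.log(rss) + float(np.sum(np.log1p(sizes * ratio))) + logdet_x
    return crit, beta, XtWiX, rss


class RandomInterceptModel(BaseEstimator, RegressorMixin):
    """Linear mixed model with a single random intercept per cluster, fit by REML.

    Parameters
    ----------
    fit_intercept : bool, default=True
        Prepend a column of ones to ``X``.
    tol : float, default=1e-8
        Convergence tolerance on the profiled REML criterion.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Fixed-effect estimates for the columns of ``X``.
    intercept_ : float
        Intercept estimate (0.0 when ``fit_intercept=False``).
    se_ : ndarray
        Wald standard errors aligned with ``[intercept] + coef``.
    p_values_ : ndarray
        Two-sided Wald z p-values, same alignment.
    sigma_b2_, sigma_w2_ : float
        Between- and within-cluster variance components (``sigma_b2_`` may
        land on the boundary 0).
    icc_ : float
        ``sigma_b2_ / (sigma_b2_ + sigma_w2_)``.
    n_clusters_, n_obs_ : int
        Analysis-set dimensions.
    converged_ : bool
        Whether the one-dimensional optimiser reported success.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8):
        self.fit_intercept = fit_intercept
        self.tol = tol

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (cluster labels) are required")
        X, y = check_X_y(X, y, ensure_min_samples=2)
        groups = np.asarray(groups)
        if groups.shape[0] != y.shape[0]:
            raise ValueError("groups must align with y")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(y)), X])
        n, p = X.shape
        if n <= p:
            raise ValueError("more parameters than observations")
        stats = _cluster_stats(X, y, groups)
        A, S, sizes, G, Xty, yty = stats

        def objective(t: float) -> float:
            return _profiled_reml(np.exp(t), *stats, n, p)[0]

        res = minimize_scalar(
            objective,
            bounds=(_LOG_RATIO_LO, _LOG_RATIO_HI),
            method="bounded",
            options={"xatol": self.tol},
        )
        ratio = float(np.exp(res.x))
        crit, beta, XtWiX, rss = _profiled_reml(ratio, *stats, n, p)
        crit0, beta0, XtWiX0, rss0 = _profiled_reml(0.0, *stats, n, p)
        if crit0 <= crit:  # boundary: no between-cluster variance
            ratio, beta, XtWiX, rss = 0.0, beta0, XtWiX0, rss0
        sigma_w2 = rss / (n - p)
        sigma_b2 = ratio * sigma_w2
        cov = np.linalg.inv(XtWiX) * sigma_w2
        se = np.sqrt(np.diag(cov))
        z = beta / se
        self.p_values_ = 2.0 * norm.sf(np.abs(z))
        self.se_ = se
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(beta[0]), beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
        self.sigma_b2_ = float(sigma_b2)
        self.sigma_w2_ = float(sigma_w2)
        self.icc_ = float(sigma_b2 / (sigma_b2 + sigma_w2))
        self.n_obs_ = n
        self.n_clusters_ = sizes.size
        self.converged_ = bool(res.success)
        self.n_features_in_ = p - int(self.fit_intercept)
        return self

    def predict(self, X):
        """Population-level (fixed-effects) prediction."""
        check_is_fitted(self)
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


@dataclass(frozen=True)
class FitResult:
    """Estimates from one random-intercept fit of a trial analysis set."""

    beta0: float
    beta1: float
    se_beta1: float
    p_value: float
    sigma_b2_hat: float
    sigma_w2_hat: float
    icc_hat: float
    n_clusters: int
    n_subjects: int
    converged: bool

    def to_row(self) -> dict:
        return dict(self.__dict__)


def fit_random_intercept(data) -> FitResult:
    """Fit the random-intercept model to a trial's analysis set.

    Records with ``analysis_arm`` marked excluded are removed; the fixed
    part is ``beta0 + beta1 * arm`` and clusters are the analysis labels.
    Requires at least two clusters with members in each arm.
    """
    mask = data.included
    arm = data.analysis_arm[mask]
    y = data.outcome[mask]
    groups = data.analysis_cluster[mask]
    for a in (0, 1):
        labels = np.unique(groups[arm == a])
        if labels.size < 2:
            raise ValueError(f"need at least two analysis clusters in arm {a}")
    model = RandomInterceptModel().fit(arm.reshape(-1, 1).astype(float), y, groups=groups)
    return FitResult(
        beta0=model.intercept_,
        beta1=float(model.coef_[0]),
        se_beta1=float(model.se_[1]),
        p_value=float(model.p_values_[1]),
        sigma_b2_hat=model.sigma_b2_,
        sigma_w2_hat=model.sigma_w2_,
        icc_hat=model.icc_,
        n_clusters=model.n_clusters_,
        n_subjects=model.n_obs_,
        converged=model.converged_,
    )


def significant(fit: FitResult, alpha: float = 0.05) -> bool:
    """Strict-inequality Wald test decision: ``p < alpha``."""
    if not fit.converged:
        raise ValueError("cannot assess significance of a non-converged fit")
    return fit.p_value < alpha
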