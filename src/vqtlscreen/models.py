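"""Regression and test engines used by every analysis stage.

Implements ordinary least squares with classical or HC1 sandwich standard
errors, logistic regression by iteratively reweighted least squares,
Levene's median test (Brown-Forsythe) for variance heterogeneity, an exact
log-space binomial upper tail, and the Bonferroni threshold helper.

The two regression engines are scikit-learn style estimators
(:class:`LinearModel`, :class:`LogisticModel`) with fitted attributes
(``coef_``, ``se_``, ``ci95_``, ``pvalues_``, ``minus2loglik_`` ...); the
module-level :func:`fit_linear` / :func:`fit_logistic` are thin wrappers
returning the fitted estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "LinearModel",
    "LogisticModel",
    "LeveneResult",
    "CollinearityError",
    "SeparationError",
    "fit_linear",
    "fit_logistic",
    "levene_median_test",
    "hard_call",
    "binomial_tail",
    "bonferroni_alpha",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile


class CollinearityError(ValueError):
    """Design matrix is rank deficient; offending columns are named."""


class SeparationError(RuntimeError):
    """Logistic fit diverged (perfect or quasi-perfect separation)."""


def _design(X, terms, fit_intercept):
    """Normalize design input to (matrix, term names)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = list(terms) if terms is not None else [
            f"x{j}" for j in range(M.shape[1])
        ]
    if fit_intercept:
        M = np.column_stack([np.ones(M.shape[0]), M])
        names = ["const"] + names
    return M, names


def _complete_cases(M, y):
    ok = np.isfinite(y) & np.all(np.isfinite(M), axis=1)
    return M[ok], y[ok], int((~ok).sum())


def _check_rank(M, names):
    # QR with pivoting: near-zero trailing diagonals of R identify the
    # columns that are linear combinations of earlier ones.
    from scipy.linalg import qr

    _, r, piv = qr(M, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(M.shape) * np.finfo(float).eps if d.size else 0.0
    bad = [names[piv[i]] for i in range(len(d)) if d[i] <= tol]
    if bad:
        raise CollinearityError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


class LinearModel(BaseEstimator):
    """OLS with classical or heteroskedasticity-consistent (HC1) errors.

    Parameters
    ----------
    robust : bool
        Use the HC1 sandwich (XtX)^-1 Xt diag(e^2) X (XtX)^-1 * n/(n-k)
        instead of the classical sigma^2 (XtX)^-1 covariance.
    fit_intercept : bool
        Prepend a constant column (term name ``const``).

    Fitted attributes: ``terms_``, ``coef_``, ``se_``, ``ci95_`` (k x 2),
    ``pvalues_`` (two-sided, normal reference), ``minus2loglik_`` (Gaussian),
    ``n_used_``, ``n_dropped_``, ``residuals_``, ``cov_``, ``family_``.
    """

    def __init__(self, robust: bool = False, fit_intercept: bool = True):
        self.robust = robust
        self.fit_intercept = fit_intercept

    def fit(self, X, y, terms=None):
        y = np.asarray(y, dtype=float).ravel()
        M, names = _design(X, terms, self.fit_intercept)
        if M.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        M, y, dropped = _complete_cases(M, y)
        n, k = M.shape
        if n == 0:
            raise ValueError("no complete cases to fit")
        if n <= k + 1:
            raise ValueError(f"too few complete cases (n={n}) for {k} terms")
        _check_rank(M, names)

        xtx = M.T @ M
        xtx_inv = np.linalg.inv(xtx)
        coef = xtx_inv @ (M.T @ y)
        resid = y - M @ coef
        rss = float(resid @ resid)
        if self.robust:
            meat = (M * resid[:, None] ** 2).T @ M
            cov = xtx_inv @ meat @ xtx_inv * (n / (n - k))
        else:
            cov = xtx_inv * (rss / (n - k))
        se = np.sqrt(np.diag(cov))

        self.terms_ = names
        self.coef_ = coef
        self.se_ = se
        self.cov_ = cov
        self.ci95_ = np.column_stack([coef - Z95 * se, coef + Z95 * se])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, coef / se, np.inf * np.sign(coef))
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(z))
        sigma2_mle = rss / n
        self.minus2loglik_ = (
            n * (np.log(2.0 * np.pi * sigma2_mle) + 1.0) if sigma2_mle > 0
            else -np.inf
        )
        self.n_used_ = n
        self.n_dropped_ = dropped
        self.residuals_ = resid
        self.family_ = "linear_robust" if self.robust else "linear"
        return self

    def predict(self, X):
        M, _ = _design(X, None, self.fit_intercept)
        return M @ self.coef_

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "ci_lo": self.ci95_[:, 0],
                "ci_hi": self.ci95_[:, 1],
                "p": self.pvalues_,
            },
            index=self.terms_,
        )


class LogisticModel(BaseEstimator):
    """Logistic regression fit by IRLS with Wald inference.

    Converges when the maximum absolute score component drops below
    ``tol`` (default 1e-8) or after ``max_iter`` Newton steps. Raises
    :class:`SeparationError` when coefficients diverge (perfect
    separation) and ``ValueError`` for a single-class outcome. Fitted
    attributes mirror :class:`LinearModel`; ``minus2loglik_`` is the
    binomial deviance and odds ratios are ``exp(coef_)``.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 50):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, terms=None):
        y = np.asarray(y, dtype=float).ravel()
        M, names = _design(X, terms, self.fit_intercept)
        if M.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        M, y, dropped = _complete_cases(M, y)
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("outcome must be coded 0/1")
        if uniq.size < 2:
            raise ValueError("outcome has a single class; cannot fit")
        _check_rank(M, names)
        n, k = M.shape

        # fit on internally standardized columns (better conditioned when
        # covariates live on very different scales, e.g. age^2 vs PCs);
        # coefficients are mapped back to the original scale at the end
        scale = M.std(axis=0)
        scale[scale == 0.0] = 1.0
        Ms = M / scale

        def _deviance(b):
            eta = np.clip(Ms @ b, -500, 500)
            # -2 loglik via logaddexp for numerical stability
            return 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))

        beta = np.zeros(k)
        dev = _deviance(beta)
        converged = False
        for _ in range(self.max_iter):
            p = expit(Ms @ beta)
            score = Ms.T @ (y - p)         # score on the standardized scale
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = np.maximum(p * (1.0 - p), 1e-12)
            info = (Ms * w[:, None]).T @ Ms
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SeparationError("singular Fisher information") from exc
            # step-halving: accept the Newton step only if it does not
            # increase the deviance (plateau tolerance scales with the
            # deviance's own float rounding, ~eps * n)
            plateau = 64.0 * np.finfo(float).eps * max(dev, 1.0)
            improved = False
            for _half in range(25):
                cand = beta + step
                dev_new = _deviance(cand)
                if dev_new <= dev + plateau:
                    improved = True
                    break
                step = step / 2.0
            if not improved:
                converged = True  # at the optimum to double precision
                break
            beta, dev = cand, dev_new
            if np.max(np.abs(beta)) > 50.0:
                raise SeparationError(
                    "coefficients diverging (|standardized coef| > 50); "
                    "likely perfect separation"
                )
        else:
            p = expit(Ms @ beta)
            score = Ms.T @ (y - p)
            converged = bool(np.max(np.abs(score)) < self.tol)
        p_hat = expit(Ms @ beta)
        if np.all((p_hat < 1e-10) | (p_hat > 1 - 1e-10)):
            raise SeparationError("fitted probabilities all saturated; "
                                  "perfect separation")
        if not converged:
            warnings.warn("IRLS did not reach score tolerance", RuntimeWarning)
        beta = beta / scale                 # back to the original scale

        p = expit(M @ beta)
        w = p * (1.0 - p)
        info = (M * w[:, None]).T @ M
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        self.terms_ = names
        self.coef_ = beta
        self.se_ = se
        self.cov_ = cov
        self.ci95_ = np.column_stack([beta - Z95 * se, beta + Z95 * se])
        z = beta / se
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(z))
        eps = 1e-300
        self.minus2loglik_ = -2.0 * float(
            y @ np.log(p + eps) + (1.0 - y) @ np.log(1.0 - p + eps)
        )
        self.n_used_ = n
        self.n_dropped_ = dropped
        self.residuals_ = y - p
        self.family_ = "logistic"
        return self

    def predict_proba(self, X):
        M, _ = _design(X, None, self.fit_intercept)
        p = expit(M @ self.coef_)
        return np.column_stack([1.0 - p, p])

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef_)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "or": np.exp(self.coef_),
                "or_lo": np.exp(self.ci95_[:, 0]),
                "or_hi": np.exp(self.ci95_[:, 1]),
                "p": self.pvalues_,
            },
            index=self.terms_,
        )


def fit_linear(X, y, robust: bool = False, fit_intercept: bool = True,
               terms=None) -> LinearModel:
    """OLS fit of y on X; returns the fitted :class:`LinearModel`."""
    return LinearModel(robust=robust, fit_intercept=fit_intercept).fit(
        X, y, terms=terms
    )


def fit_logistic(X, y, fit_intercept: bool = True, terms=None) -> LogisticModel:
    """IRLS logistic fit of a 0/1 outcome; returns :class:`LogisticModel`."""
    return LogisticModel(fit_intercept=fit_intercept).fit(X, y, terms=terms)


@dataclass
class LeveneResult:
    """Brown-Forsythe variance-heterogeneity test result."""

    w: float
    df1: int
    df2: int
    p: float
    group_sizes: list[int] = field(default_factory=list)
    group_medians: list[float] = field(default_factory=list)
    n_dropped_groups: int = 0


def hard_call(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest of {0, 1, 2} (genotype groups)."""
    return np.clip(np.rint(np.asarray(dosage, dtype=float)), 0, 2)


def levene_median_test(values: np.ndarray, groups: np.ndarray,
                       min_group_size: int = 10) -> LeveneResult:
    """Levene's median (Brown-Forsythe) test across genotype groups.

    Computes z_ij = |x_ij - median_i| within each group and the one-way
    ANOVA F statistic W = [(N-k)/(k-1)] * sum_i n_i (zbar_i - zbar)^2 /
    sum_ij (z_ij - zbar_i)^2, with the p-value from the upper tail of
    F(k-1, N-k). Groups smaller than ``min_group_size`` are dropped; fewer
    than two usable groups is an error. If all z are identical (zero
    denominator) the test is degenerate and p = 1 with a warning.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = np.isfinite(x)
    x, g = x[ok], g[ok]
    labels, counts = np.unique(g, return_counts=True)
    keep = counts >= min_group_size
    dropped = int((~keep).sum())
    labels = labels[keep]
    if labels.size < 2:
        raise ValueError(
            f"need >= 2 groups of size >= {min_group_size}; "
            f"got {labels.size} usable group(s)"
        )
    zs, sizes, medians = [], [], []
    for lab in labels:
        xi = x[g == lab]
        med = float(np.median(xi))
        zs.append(np.abs(xi - med))
        sizes.append(xi.size)
        medians.append(med)
    ncount = int(sum(sizes))
    kgroups = len(zs)
    zbar_i = np.array([z.mean() for z in zs])
    zbar = float(np.concatenate(zs).mean()) if kgroups else 0.0
    num = float(np.sum(np.array(sizes) * (zbar_i - zbar) ** 2))
    den = float(sum(((z - zb) ** 2).sum() for z, zb in zip(zs, zbar_i)))
    df1, df2 = kgroups - 1, ncount - kgroups
    if den <= 0.0:
        warnings.warn("all absolute deviations identical; Levene p set to 1",
                      RuntimeWarning)
        return LeveneResult(0.0, df1, df2, 1.0, sizes, medians, dropped)
    w = (df2 / df1) * num / den
    p = float(stats.f.sf(w, df1, df2))
    return LeveneResult(float(w), df1, df2, p, sizes, medians, dropped)


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper binomial tail P(X >= k), X ~ Binomial(n, p0), in log space.

    Accurate far into the tail (e.g. P(X >= 19 | n=25, p0=0.05) ~ 2.5e-20),
    where naive summation of pmf terms would lose precision.
    """
    k, n = int(k), int(n)
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * np.log(p0) + (n - i) * np.log1p(-p0)
    )
    return float(min(np.exp(logsumexp(logpmf)), 1.0))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
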