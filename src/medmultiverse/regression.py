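"""Ordinary least squares with coefficient covariance.

This is the shared fitting engine behind every path model in the package:
the total-effect model, the mediator model, the outcome model (optionally
with a determinant-by-mediator interaction), and their age-moderated
variants.  Classical homoskedastic standard errors and t-distribution
reference are used throughout, matching the ordinary multiple linear
regression the rest of the package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import statsmodels.api as sm
from scipy import stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending term names."""

    def __init__(self, terms: Sequence[str]):
        self.terms = list(terms)
        super().__init__(
            "design matrix is rank deficient; linearly dependent terms: "
            + ", ".join(self.terms)
        )


class InsufficientDataError(ValueError):
    """Fewer observations than needed to estimate the model."""


class MissingDataError(ValueError):
    """Missing values reached the fitting engine (must be filtered upstream)."""


@dataclass(frozen=True)
class LinearFit:
    """A fitted linear model: coefficients, their covariance, and fit metadata.

    Attributes
    ----------
    term_names : tuple of str
        Ordered labels for the design columns (including the intercept).
    coefficients : ndarray
        Point estimates, one per term, in outcome units per term unit.
    covariance : ndarray
        Classical (homoskedastic) covariance matrix of the coefficients.
    residual_variance : float
        Unbiased residual variance estimate (RSS / dof_residual).
    n_obs, dof_residual : int
        Sample size and residual degrees of freedom (n_obs - n_terms).
    """

    term_names: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    residual_variance: float
    n_obs: int
    dof_residual: int

    def __post_init__(self) -> None:
        k = len(self.term_names)
        if self.coefficients.shape != (k,) or self.covariance.shape != (k, k):
            raise ValueError("coefficient/covariance dimensions do not match terms")

    def index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(
                f"unknown term {term!r}; available: {list(self.term_names)}"
            ) from None

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.index(term)])

    def se(self, term: str) -> float:
        i = self.index(term)
        return float(np.sqrt(self.covariance[i, i]))


def _dependent_terms(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns that a pivoted QR marks as linearly dependent."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[j] for j in sorted(piv[rank:])]


def fit_ols(
    rows: np.ndarray,
    response: np.ndarray,
    term_names: Sequence[str],
) -> LinearFit:
    """Fit an OLS regression of ``response`` on the columns of ``rows``.

    ``rows`` must already contain the intercept column; missing values are
    rejected (complete-case filtering happens upstream, per universe).

    Raises
    ------
    CollinearityError
        if the design is rank deficient (names the dependent terms).
    InsufficientDataError
        if there are not strictly more observations than terms.
    MissingDataError
        if any value in the design or response is NaN.
    """
    X = np.asarray(rows, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("rows must be 2-D and response 1-D with matching length")
    if len(term_names) != X.shape[1]:
        raise ValueError("term_names length must match the number of columns")
    if np.isnan(X).any() or np.isnan(y).any():
        raise MissingDataError(
            "missing values in design or response; filter complete cases first"
        )
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(
            f"{n} observations cannot identify {k} terms (need n > k)"
        )
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError(_dependent_terms(X, list(term_names)))

    res = sm.OLS(y, X).fit()
    return LinearFit(
        term_names=tuple(term_names),
        coefficients=np.asarray(res.params, dtype=float),
        covariance=np.asarray(res.cov_params(), dtype=float),
        residual_variance=float(res.mse_resid),
        n_obs=n,
        dof_residual=int(res.df_resid),
    )


@dataclass(frozen=True)
class CoefficientSummary:
    estimate: float
    standard_error: float
    p_value: float
    significant: bool
    dof: int = field(repr=False, default=0)


def coefficient_summary(
    fit: LinearFit, term: str, alpha: float = 0.05
) -> CoefficientSummary:
    """Two-sided t test of a single coefficient against zero.

    ``significant`` is the strict comparison p < alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    est = fit.coef(term)
    se = fit.se(term)
    if se == 0.0:
        # Degenerate (noise-free) fit: any nonzero estimate is certain.
        p = 0.0 if est != 0.0 else 1.0
    else:
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), fit.dof_residual)
    return CoefficientSummary(
        estimate=est,
        standard_error=se,
        p_value=float(p),
        significant=bool(p < alpha),
        dof=fit.dof_residual,
    )


def linear_combination(
    fit: LinearFit, weights: dict[str, float]
) -> tuple[float, float]:
    """Estimate and SE of a linear combination of coefficients.

    Used for simple slopes, e.g. a(z) = a + z * a_xz.
    """
    w = np.zeros(len(fit.term_names))
    for term, weight in weights.items():
        w[fit.index(term)] = weight
    est = float(w @ fit.coefficients)
    var = float(w @ fit.covariance @ w)
    return est, float(np.sqrt(max(var, 0.0)))


def combination_pvalue(fit: LinearFit, weights: dict[str, float]) -> float:
    """Two-sided t test of a linear combination against zero."""
    est, se = linear_combination(fit, weights)
    if se == 0.0:
        return 0.0 if est != 0.0 else 1.0
    return float(2.0 * stats.t.sf(abs(est / se), fit.dof_residual))
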