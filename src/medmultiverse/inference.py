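"""Monte Carlo confidence intervals for mediation effects.

The indirect effect is a product of regression coefficients, so its sampling
distribution is skewed and a normal-theory interval is poorly calibrated.
The Monte Carlo interval instead samples coefficient vectors from a
multivariate normal centred at the estimates with the estimated coefficient
covariance, applies the effect function to each draw, and takes percentile
endpoints.  Mediator-model and outcome-model coefficient blocks are sampled
independently (they come from separate regressions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg

MIN_DRAWS = 1000


@dataclass(frozen=True)
class EffectCI:
    """A point estimate with a Monte Carlo percentile interval.

    ``significant`` is True iff the interval excludes zero.
    """

    estimate: float
    lower: float
    upper: float
    level: float
    n_draws: int
    seed: int
    significant: bool


def _check_psd(covariance: np.ndarray) -> None:
    cov = np.asarray(covariance, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    tol = 1e-10 * max(1.0, float(eig.max(initial=0.0)))
    if eig.min(initial=0.0) < -tol:
        raise ValueError("covariance is not positive semi-definite")


def monte_carlo_ci(
    path_estimates: np.ndarray,
    covariance: np.ndarray,
    effect_fn: Callable[[np.ndarray], np.ndarray],
    level: float = 0.95,
    n_draws: int = 20000,
    seed: int = 0,
) -> EffectCI:
    """Percentile Monte Carlo interval for a function of regression coefficients.

    Parameters
    ----------
    path_estimates, covariance
        Coefficient estimates and their (block) covariance.  Independence of
        the mediator- and outcome-model blocks is expressed by passing a
        block-diagonal covariance (see :func:`joint_blocks`).
    effect_fn
        Vectorized map from an (n_draws, k) array of coefficient draws to an
        (n_draws,) array of effects.  The point estimate is effect_fn applied
        to the estimates themselves.
    """
    est_vec = np.atleast_1d(np.asarray(path_estimates, float))
    _check_psd(covariance)
    if np.asarray(covariance).shape[0] != est_vec.size:
        raise ValueError("covariance dimension does not match estimates")
    if n_draws < MIN_DRAWS:
        raise ValueError(f"n_draws must be at least {MIN_DRAWS}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        est_vec, np.asarray(covariance, float), size=n_draws, method="svd"
    )
    effects = np.asarray(effect_fn(draws), float)
    if effects.shape != (n_draws,):
        raise ValueError("effect_fn must return one effect per draw")
    if not np.all(np.isfinite(effects)):
        raise RuntimeError("effect_fn produced non-finite values on MC draws")
    point = float(np.asarray(effect_fn(est_vec[None, :]), float)[0])
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(effects, [tail, 1.0 - tail])
    return EffectCI(
        estimate=point,
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_draws=n_draws,
        seed=seed,
        significant=bool(not (lower <= 0.0 <= upper)),
    )


def mediation_verdict_ci(indirect_ci: EffectCI) -> bool:
    """Mediation verdict by interval: True iff the indirect-effect interval
    excludes zero."""
    return indirect_ci.significant


def joint_blocks(
    estimates_a: np.ndarray,
    cov_a: np.ndarray,
    estimates_b: np.ndarray,
    cov_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack two independent coefficient blocks into one estimate vector and
    block-diagonal covariance (mediator model first, outcome model second)."""
    est = np.concatenate([np.atleast_1d(estimates_a), np.atleast_1d(estimates_b)])
    cov = scipy.linalg.block_diag(np.atleast_2d(cov_a), np.atleast_2d(cov_b))
    return est, cov
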