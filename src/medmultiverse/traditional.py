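"""Traditional single-mediator analysis from three linear regressions.

The mediation model is estimated with the classic three-equation system:

    Y = i1 + c*X            + controls + e1      (total effect)
    M = i2 + a*X            + controls + e2      (mediator model)
    Y = i3 + c'*X + b*M     + controls + e3      (outcome model)

optionally extended with a determinant-by-mediator interaction X*M in the
outcome model and with binary-moderator interactions (X*Z in every equation
where X appears, plus M*Z in the outcome model) for simple-slopes analysis.

All path quantities (a, b, c, c', interaction) are represented as linear
combinations of fitted coefficients so that moderated and unmoderated
universes share one code path: at moderator level z the determinant-mediator
slope is a(z) = a + z * a_xz, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regression import (
    InsufficientDataError,
    LinearFit,
    combination_pvalue,
    fit_ols,
    linear_combination,
)

INTERCEPT = "const"


def _product_name(left: str, right: str) -> str:
    return f"{left}:{right}"


def build_design(
    frame: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Assemble a design matrix from column names and ':'-product terms."""
    cols = []
    for term in terms:
        if term == INTERCEPT:
            cols.append(np.ones(len(frame)))
        elif ":" in term:
            left, right = term.split(":", 1)
            cols.append(frame[left].to_numpy(float) * frame[right].to_numpy(float))
        else:
            cols.append(frame[term].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(frame), 0)), list(terms)


def _is_binary(values: pd.Series) -> bool:
    uniq = set(np.unique(values.to_numpy(float)))
    return uniq <= {0.0, 1.0}


@dataclass(frozen=True)
class PathCoefficients:
    """Fitted path coefficients of a (possibly moderated) mediation model.

    Each path is stored as a weight map over the terms of its source fit, so
    moderated simple slopes and plain coefficients are read out uniformly via
    the linear-combination variance.  ``w_mu0`` gives the mediator-model
    prediction at the determinant reference value (intercept plus covariates
    held at the covariate profile), which the natural-effect formulas need.
    """

    fit_total: LinearFit
    fit_mediator: LinearFit
    fit_outcome: LinearFit
    w_c: Mapping[str, float]
    w_a: Mapping[str, float]
    w_b: Mapping[str, float]
    w_c_prime: Mapping[str, float]
    w_interaction: Mapping[str, float] | None
    w_mu0: Mapping[str, float]
    determinant: str
    mediator: str
    outcome: str
    n_complete: int
    covariates_mediator: tuple[str, ...] = ()
    covariates_outcome: tuple[str, ...] = ()
    moderator: str | None = None
    target_level: float | None = None
    covariate_profile: Mapping[str, float] = field(default_factory=dict)

    # -- point estimates and standard errors -------------------------------
    @property
    def c(self) -> tuple[float, float]:
        return linear_combination(self.fit_total, dict(self.w_c))

    @property
    def a(self) -> tuple[float, float]:
        return linear_combination(self.fit_mediator, dict(self.w_a))

    @property
    def b(self) -> tuple[float, float]:
        return linear_combination(self.fit_outcome, dict(self.w_b))

    @property
    def c_prime(self) -> tuple[float, float]:
        return linear_combination(self.fit_outcome, dict(self.w_c_prime))

    @property
    def interaction(self) -> tuple[float, float]:
        if self.w_interaction is None:
            return 0.0, 0.0
        return linear_combination(self.fit_outcome, dict(self.w_interaction))

    @property
    def mu0(self) -> float:
        est, _ = linear_combination(self.fit_mediator, dict(self.w_mu0))
        return est

    @property
    def has_interaction(self) -> bool:
        return self.w_interaction is not None

    def p_value(self, path: str) -> float:
        """Two-sided p-value of a path coefficient ('c', 'a', 'b', 'c_prime')."""
        fits = {
            "c": (self.fit_total, self.w_c),
            "a": (self.fit_mediator, self.w_a),
            "b": (self.fit_outcome, self.w_b),
            "c_prime": (self.fit_outcome, self.w_c_prime),
        }
        fit, w = fits[path]
        return combination_pvalue(fit, dict(w))


def covariate_profile(
    frame: pd.DataFrame, covariates: Iterable[str]
) -> dict[str, float]:
    """Default evaluation profile: sample mean for continuous covariates,
    reference level (0) for binary/dummy-coded ones."""
    profile: dict[str, float] = {}
    for cov in covariates:
        profile[cov] = 0.0 if _is_binary(frame[cov]) else float(frame[cov].mean())
    return profile


def estimate_paths(
    data: pd.DataFrame,
    determinant: str,
    mediator: str,
    outcome: str,
    covariates_mediator: Sequence[str] = (),
    covariates_outcome: Sequence[str] = (),
    include_interaction: bool = False,
    moderator: str | None = None,
    target_level: float | None = None,
) -> PathCoefficients:
    """Fit the three-equation mediation system on complete cases.

    With ``moderator`` set (a 0/1 column) the equations are augmented with
    X*Z interactions (and M*Z in the outcome model) and the returned path
    weight maps evaluate the simple slopes at ``target_level``.
    """
    x, m, y = determinant, mediator, outcome
    used = [x, m, y, *covariates_mediator, *covariates_outcome]
    if moderator is not None:
        if target_level not in (0, 1, 0.0, 1.0):
            raise ValueError("target_level must be 0 or 1 for a binary moderator")
        used.append(moderator)
    used = list(dict.fromkeys(used))
    complete = data.dropna(subset=used)
    n_terms_max = 4 + len(set(covariates_mediator) | set(covariates_outcome)) + 4
    if len(complete) < n_terms_max + 1:
        raise InsufficientDataError(
            f"only {len(complete)} complete cases for {len(used)} variables"
        )
    if moderator is not None:
        levels = set(np.unique(complete[moderator].to_numpy(float)))
        if not levels <= {0.0, 1.0}:
            raise ValueError(f"moderator {moderator!r} must be coded 0/1")
        if len(levels) < 2:
            raise ValueError(f"moderator {moderator!r} has a single level")

    z = moderator
    zl = float(target_level) if moderator is not None else 0.0
    xz = _product_name(x, z) if z else None
    mz = _product_name(m, z) if z else None
    xm = _product_name(x, m)

    terms1 = [INTERCEPT, x] + ([z, xz] if z else []) + list(covariates_outcome)
    terms2 = [INTERCEPT, x] + ([z, xz] if z else []) + list(covariates_mediator)
    terms3 = (
        [INTERCEPT, x, m]
        + ([xm] if include_interaction else [])
        + ([z, xz, mz] if z else [])
        + list(covariates_outcome)
    )

    X1, n1 = build_design(complete, terms1)
    X2, n2 = build_design(complete, terms2)
    X3, n3 = build_design(complete, terms3)
    yv = complete[y].to_numpy(float)
    mv = complete[m].to_numpy(float)

    fit_total = fit_ols(X1, yv, n1)
    fit_mediator = fit_ols(X2, mv, n2)
    fit_outcome = fit_ols(X3, yv, n3)

    w_x = {x: 1.0, **({xz: zl} if z else {})}
    w_b = {m: 1.0, **({mz: zl} if z else {})}
    profile = covariate_profile(complete, covariates_mediator)
    w_mu0 = {INTERCEPT: 1.0, **profile}
    if z:
        w_mu0[z] = zl

    return PathCoefficients(
        fit_total=fit_total,
        fit_mediator=fit_mediator,
        fit_outcome=fit_outcome,
        w_c=dict(w_x),
        w_a=dict(w_x),
        w_b=w_b,
        w_c_prime=dict(w_x),
        w_interaction={xm: 1.0} if include_interaction else None,
        w_mu0=w_mu0,
        determinant=x,
        mediator=m,
        outcome=y,
        n_complete=len(complete),
        covariates_mediator=tuple(covariates_mediator),
        covariates_outcome=tuple(covariates_outcome),
        moderator=moderator,
        target_level=zl if z else None,
        covariate_profile=profile,
    )


@dataclass(frozen=True)
class ProportionMediated:
    """Indirect effect as a percentage of the total effect.

    ``defined`` is False when |c| falls below tolerance (the ratio is then
    meaningless and downstream verdict criteria must treat it as failed).
    ``inconsistent`` marks opposite-signed direct and indirect effects, in
    which case the proportion can legitimately exceed 100%.
    """

    value: float | None
    defined: bool
    inconsistent: bool


def proportion_mediated(
    paths: PathCoefficients,
    indirect: float | None = None,
    tolerance: float = 1e-10,
) -> ProportionMediated:
    """Proportion mediated, 100 * indirect / c.

    ``indirect`` defaults to the product of coefficients a*b; universes that
    quantify the indirect effect as a natural indirect effect pass that
    estimate instead.
    """
    c_est, _ = paths.c
    if indirect is None:
        indirect = paths.a[0] * paths.b[0]
    direct = c_est - indirect
    inconsistent = bool(indirect * direct < 0.0)
    if abs(c_est) <= tolerance:
        return ProportionMediated(value=None, defined=False, inconsistent=inconsistent)
    return ProportionMediated(
        value=100.0 * indirect / c_est, defined=True, inconsistent=inconsistent
    )


def causal_steps_verdict(
    paths: PathCoefficients,
    alpha: float = 0.05,
    direct_estimate: float | None = None,
) -> bool:
    """Four-condition causal-steps criterion.

    True iff the total effect c, the determinant-mediator path a, and the
    mediator-outcome path b are all statistically significant, and the
    direct effect is attenuated relative to the total effect (|c'| < |c|).
    ``direct_estimate`` defaults to c'; universes quantifying the direct
    effect as a natural direct effect pass that estimate.
    """
    c_est, _ = paths.c
    if direct_estimate is None:
        direct_estimate = paths.c_prime[0]
    return bool(
        paths.p_value("c") < alpha
        and paths.p_value("a") < alpha
        and paths.p_value("b") < alpha
        and abs(direct_estimate) < abs(c_est)
    )


@dataclass(frozen=True)
class TraditionalResult:
    """Summary of the traditional mediation criteria for one universe."""

    indirect_product: float
    indirect_difference: float
    proportion: ProportionMediated
    causal_steps: bool
    criteria_verdict: bool


def traditional_result(
    paths: PathCoefficients,
    alpha: float = 0.05,
    proportion_threshold: float = 20.0,
    indirect: float | None = None,
    direct: float | None = None,
) -> TraditionalResult:
    """Assemble the original-study style verdict: causal steps AND proportion
    mediated at or above the threshold (default 20%)."""
    ab = paths.a[0] * paths.b[0]
    c_est, _ = paths.c
    diff = c_est - paths.c_prime[0]
    prop = proportion_mediated(paths, indirect=indirect)
    steps = causal_steps_verdict(paths, alpha=alpha, direct_estimate=direct)
    meets_prop = prop.defined and prop.value is not None and prop.value >= proportion_threshold
    return TraditionalResult(
        indirect_product=ab,
        indirect_difference=diff,
        proportion=prop,
        causal_steps=steps,
        criteria_verdict=bool(steps and meets_prop),
    )
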