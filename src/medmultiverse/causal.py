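"""Natural direct and indirect effects for the linear mediation model.

With a linear mediator model E[M|X=x] = mu0 + a*x (covariates absorbed into
mu0 at a fixed profile) and a linear outcome model with determinant-by-
mediator interaction,

    E[Y|X=x, M=m] = i3 + c'*x + b*m + h*x*m  (+ covariates),

the potential-outcome definitions of the natural effects reduce to closed
forms for a contrast x0 -> x1:

    PNDE = (c' + h*(mu0 + a*x0)) * (x1 - x0)
    TNDE = (c' + h*(mu0 + a*x1)) * (x1 - x0)
    PNIE = (b + h*x0) * a * (x1 - x0)
    TNIE = (b + h*x1) * a * (x1 - x0)

The total effect decomposes both ways: total = PNDE + TNIE = TNDE + PNIE.
When h = 0 all four collapse to the familiar c' and a*b*(x1 - x0).

Effects are computed from fitted coefficients (a regression-based
estimator); a resampling potential-outcome oracle exists in the test suite
only, as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .regression import LinearFit
from .traditional import INTERCEPT, PathCoefficients


@dataclass(frozen=True)
class NaturalEffects:
    """Pure/total natural direct and indirect effects for a contrast x0 -> x1.

    All effects are on the outcome's native scale, evaluated with covariates
    held at ``covariate_profile``.
    """

    x0: float
    x1: float
    pnde: float
    tnde: float
    pnie: float
    tnie: float
    total: float
    covariate_profile: Mapping[str, float] = field(default_factory=dict)


def natural_effects_from_coefficients(
    a: float,
    mu0: float,
    c_prime: float,
    b: float,
    h: float,
    x0: float,
    x1: float,
    covariate_profile: Mapping[str, float] | None = None,
) -> NaturalEffects:
    """Closed-form natural effects from scalar path coefficients."""
    dx = x1 - x0
    pnde = (c_prime + h * (mu0 + a * x0)) * dx
    tnde = (c_prime + h * (mu0 + a * x1)) * dx
    pnie = (b + h * x0) * a * dx
    tnie = (b + h * x1) * a * dx
    return NaturalEffects(
        x0=float(x0),
        x1=float(x1),
        pnde=pnde,
        tnde=tnde,
        pnie=pnie,
        tnie=tnie,
        total=pnde + tnie,
        covariate_profile=dict(covariate_profile or {}),
    )


def natural_effects(
    mediator_fit: LinearFit,
    outcome_fit: LinearFit,
    determinant: str,
    mediator: str,
    x0: float,
    x1: float,
    covariate_profile: Mapping[str, float] | None = None,
) -> NaturalEffects:
    """Natural effects from a mediator fit and an outcome fit with an X*M term.

    The outcome fit must contain the interaction term named
    ``"<determinant>:<mediator>"`` (its coefficient may be zero).  The
    covariate profile must cover every covariate appearing in either fit;
    a mismatch is a contract error.
    """
    profile = dict(covariate_profile or {})
    xm = f"{determinant}:{mediator}"
    if xm not in outcome_fit.term_names:
        raise ValueError(
            f"outcome fit lacks the determinant-mediator interaction term {xm!r}"
        )
    if determinant not in mediator_fit.term_names:
        raise ValueError("mediator fit lacks the determinant term")
    special = {INTERCEPT, determinant, mediator, xm}
    needed = (set(mediator_fit.term_names) | set(outcome_fit.term_names)) - special
    needed = {t for t in needed if ":" not in t}
    missing = needed - profile.keys()
    if missing:
        raise ValueError(f"covariate profile missing values for: {sorted(missing)}")

    mu0 = mediator_fit.coef(INTERCEPT) + sum(
        mediator_fit.coef(t) * profile[t]
        for t in mediator_fit.term_names
        if t in profile
    )
    return natural_effects_from_coefficients(
        a=mediator_fit.coef(determinant),
        mu0=mu0,
        c_prime=outcome_fit.coef(determinant),
        b=outcome_fit.coef(mediator),
        h=outcome_fit.coef(xm),
        x0=x0,
        x1=x1,
        covariate_profile=profile,
    )


def natural_effects_from_paths(
    paths: PathCoefficients, x0: float, x1: float
) -> NaturalEffects:
    """Natural effects from a fitted (possibly moderated) path system.

    Simple-slope weight maps make this valid at a moderator stratum: a, b,
    c' and mu0 are the stratum-specific linear combinations.
    """
    return natural_effects_from_coefficients(
        a=paths.a[0],
        mu0=paths.mu0,
        c_prime=paths.c_prime[0],
        b=paths.b[0],
        h=paths.interaction[0],
        x0=x0,
        x1=x1,
        covariate_profile=paths.covariate_profile,
    )


def effect_decomposition_check(
    effects: NaturalEffects, tolerance: float = 1e-8
) -> bool:
    """True iff both decompositions PNDE + TNIE and TNDE + PNIE recover the
    total effect to tolerance (scaled by the magnitude of the total)."""
    scale = max(1.0, abs(effects.total))
    return bool(
        abs(effects.pnde + effects.tnie - effects.total) <= tolerance * scale
        and abs(effects.tnde + effects.pnie - effects.total) <= tolerance * scale
    )
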