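"""Seeded generator of aging-cohort-like mediation datasets.

Emulates the structure of a cross-sectional wave of an older-adult cohort in
which percent weight change since age 25 (determinant, %) acts on hip bone
mineral density (outcome, mg/cm^2) partly through total-body fat mass
(mediator, kg), with a panel of candidate confounders (anthropometry,
lifestyle, chronic disease, medication) plus an optional hormonal block
(ln-SHBG, ln-PTH, 25(OH)D, IGF-1, albumin) generated downstream of fat mass,
so its causal status as confounder versus consequence is deliberately
ambiguous.  Age moderates the determinant-mediator and mediator-outcome
paths via a 75-year old-old threshold.

The generator draws confounders first, then the determinant as a linear
function of its confounders plus noise (raw lowest/current body weights are
emitted consistently with the percent change so reliable-change coding is
possible), then the mediator and outcome from the declared structural
coefficients, and finally applies completely-at-random missingness.  The
same seed always reproduces the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .causal import NaturalEffects, natural_effects_from_coefficients


@dataclass(frozen=True)
class ConfounderSpec:
    """One candidate confounder: its marginal distribution and its linear
    effects on the determinant (X), mediator (M) and outcome (Y).

    kind 'continuous' uses a normal(mean, sd); 'binary' a Bernoulli(prob);
    'ordinal' a categorical over levels 0..k-1 with the given probabilities.
    Effects apply to the mean-centred value, so they do not shift the
    marginal locations of X, M, Y.
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    prob: float = 0.5
    levels: tuple[float, ...] = ()
    effect_x: float = 0.0
    effect_m: float = 0.0
    effect_y: float = 0.0

    def expectation(self) -> float:
        if self.kind == "continuous":
            return self.mean
        if self.kind == "binary":
            return self.prob
        if self.kind == "ordinal":
            return float(np.dot(np.arange(len(self.levels)), self.levels))
        raise ValueError(f"unknown confounder kind {self.kind!r}")


HORMONAL_NAMES = ("ln_shbg", "ln_pth", "vitd_25oh", "igf1", "albumin")

# (name, intercept, effect of centred fat mass, residual sd, effect on BMD)
_HORMONAL_STRUCTURE = (
    ("ln_shbg", 4.0, -0.030, 0.35, -40.0),
    ("ln_pth", 1.3, 0.020, 0.30, -15.0),
    ("vitd_25oh", 55.0, -0.60, 18.0, 0.40),
    ("igf1", 14.0, 0.15, 4.5, 1.0),
    ("albumin", 43.0, -0.05, 2.5, 0.8),
)


def _default_confounders() -> tuple[ConfounderSpec, ...]:
    # Scales: X in %, M in kg, Y in mg/cm^2.  Height and age are the strong
    # common causes; several panel members are near-null so the >=10%
    # change-in-estimate screen has something to reject.
    return (
        ConfounderSpec("height", "continuous", mean=162.0, sd=6.5,
                       effect_x=0.15, effect_m=0.35, effect_y=4.0),
        ConfounderSpec("age", "continuous", mean=75.0, sd=6.0,
                       effect_x=-0.25, effect_m=-0.22, effect_y=-5.5),
        ConfounderSpec("smoking", "ordinal", levels=(0.45, 0.35, 0.20),
                       effect_x=-2.0, effect_m=-1.6, effect_y=-18.0),
        ConfounderSpec("alcohol", "continuous", mean=3.0, sd=4.0,
                       effect_x=0.1, effect_m=0.05, effect_y=0.5),
        ConfounderSpec("walking", "continuous", mean=45.0, sd=30.0,
                       effect_x=0.02, effect_m=-0.03, effect_y=0.25),
        ConfounderSpec("sports", "binary", prob=0.30,
                       effect_x=0.0, effect_m=-0.3, effect_y=3.0),
        ConfounderSpec("copd", "binary", prob=0.08,
                       effect_x=-1.0, effect_m=-0.8, effect_y=-10.0),
        ConfounderSpec("stroke", "binary", prob=0.08,
                       effect_x=0.5, effect_m=0.4, effect_y=-6.0),
        ConfounderSpec("rheumatoid_arthritis", "binary", prob=0.08,
                       effect_x=0.0, effect_m=0.2, effect_y=-8.0),
        ConfounderSpec("diabetes", "binary", prob=0.08,
                       effect_x=1.5, effect_m=1.2, effect_y=2.0),
        ConfounderSpec("corticosteroid_use", "binary", prob=0.07,
                       effect_x=0.5, effect_m=0.5, effect_y=-25.0),
        ConfounderSpec("estrogen_use", "binary", prob=0.10,
                       effect_x=-1.0, effect_m=-1.5, effect_y=30.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Structural parameters of the synthetic cohort.

    true_a (kg per %), true_b (mg/cm^2 per kg), true_c_prime (mg/cm^2 per %)
    and true_interaction (mg/cm^2 per %*kg) are the mediation coefficients;
    moderator_shift_a / moderator_shift_b are added to a and b for the
    old-old stratum (age >= age_cutoff).  missing_rate is applied
    column-wise, completely at random, and must stay in the low range
    typical of the emulated cohort wave (at most 7%).
    """

    n: int = 264
    true_a: float = 0.25
    true_b: float = 13.0
    true_c_prime: float = -0.5
    true_interaction: float = 0.0
    moderator_shift_a: float = -0.08
    moderator_shift_b: float = -3.0
    confounders: tuple[ConfounderSpec, ...] = field(
        default_factory=_default_confounders
    )
    hormonal_block: bool = True
    residual_sd_m: float = 5.0
    residual_sd_y: float = 80.0
    x_mean: float = 10.0
    x_residual_sd: float = 13.5
    m_mean: float = 25.0
    y_mean: float = 800.0
    age_cutoff: float = 75.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 30:
            raise ValueError("n must be at least 30")
        if not 0.0 <= self.missing_rate <= 0.07:
            raise ValueError("missing_rate must lie in [0, 0.07]")
        names = [c.name for c in self.confounders]
        if len(names) != len(set(names)):
            raise ValueError("duplicate confounder names")


def lasa_like(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default preset: n = 264 women with effect sizes that give the
    indirect effect roughly 80% power in the original specification, so a
    full multiverse run shows a mix of significant and non-significant
    universes (stratified and small-contrast universes lose power)."""
    return replace(GeneratorConfig(seed=seed), **overrides)


def _draw_confounder(rng: np.random.Generator, spec: ConfounderSpec, n: int):
    if spec.kind == "continuous":
        return rng.normal(spec.mean, spec.sd, size=n)
    if spec.kind == "binary":
        return (rng.random(n) < spec.prob).astype(float)
    if spec.kind == "ordinal":
        return rng.choice(len(spec.levels), size=n, p=spec.levels).astype(float)
    raise ValueError(f"unknown confounder kind {spec.kind!r}")


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort dataset.

    Columns: lowest_weight, current_weight, pct_weight_change (X), fat_mass
    (M), bmd (Y), every declared confounder, and the hormonal block when
    enabled.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    frame: dict[str, np.ndarray] = {}
    centred: dict[str, np.ndarray] = {}
    for spec in config.confounders:
        values = _draw_confounder(rng, spec, n)
        frame[spec.name] = values
        centred[spec.name] = values - spec.expectation()

    def structural(attr: str) -> np.ndarray:
        total = np.zeros(n)
        for spec in config.confounders:
            total += getattr(spec, attr) * centred[spec.name]
        return total

    x = config.x_mean + structural("effect_x") + rng.normal(
        0.0, config.x_residual_sd, n
    )
    # Raw weights consistent with the percent change (current relative to the
    # self-reported lowest weight since age 25).
    lowest = np.clip(rng.normal(62.0, 7.5, n), 40.0, None)
    current = lowest * (1.0 + x / 100.0)

    old = (frame["age"] >= config.age_cutoff).astype(float) if "age" in frame else (
        np.zeros(n)
    )
    a_i = config.true_a + config.moderator_shift_a * old
    m_intercept = config.m_mean - config.true_a * config.x_mean
    m = (
        m_intercept
        + a_i * x
        + structural("effect_m")
        + rng.normal(0.0, config.residual_sd_m, n)
    )

    # Hormonal block: generated downstream of fat mass AND carrying part of
    # its effect onto the outcome (fat mass -> hormone -> BMD).  Adjusting
    # the outcome model for these intermediates therefore attenuates the b
    # path, which is the causal ambiguity the reduced confounder set avoids.
    hormonal_y = np.zeros(n)
    hormone_effect_via_block = 0.0
    if config.hormonal_block:
        m_c = m - m.mean()
        for name, intercept, delta, noise_sd, gamma in _HORMONAL_STRUCTURE:
            w = intercept + delta * m_c + rng.normal(0.0, noise_sd, n)
            frame[name] = w
            hormonal_y += gamma * (w - intercept)
            hormone_effect_via_block += gamma * delta

    # true_b is the TOTAL mediator-outcome effect; the part routed through
    # the hormonal block is subtracted from the direct coefficient.
    b_i = (
        config.true_b - hormone_effect_via_block
        + config.moderator_shift_b * old
    )
    y_intercept = (
        config.y_mean
        - config.true_c_prime * config.x_mean
        - config.true_b * config.m_mean
        - config.true_interaction * config.x_mean * config.m_mean
    )
    y = (
        y_intercept
        + config.true_c_prime * x
        + b_i * m
        + hormonal_y
        + config.true_interaction * x * m
        + structural("effect_y")
        + rng.normal(0.0, config.residual_sd_y, n)
    )

    frame["lowest_weight"] = lowest
    frame["current_weight"] = current
    frame["pct_weight_change"] = x
    frame["fat_mass"] = m
    frame["bmd"] = y

    df = pd.DataFrame(frame)
    if config.missing_rate > 0:
        protected = {"pct_weight_change"}  # keep the determinant observed
        for col in df.columns:
            if col in protected:
                continue
            mask = rng.random(n) < config.missing_rate
            df.loc[mask, col] = np.nan
    return df


def confounder_names(config: GeneratorConfig, include_hormonal: bool = True):
    """Candidate-confounder column names implied by a generator config."""
    names = [c.name for c in config.confounders]
    if include_hormonal and config.hormonal_block:
        names += list(HORMONAL_NAMES)
    return names


def true_natural_effects(
    config: GeneratorConfig, x0: float, x1: float
) -> NaturalEffects:
    """Ground-truth natural effects implied by the generator's coefficients.

    Evaluated with confounders at their generator means and the old-old
    indicator at its implied prevalence (so the moderator enters linearly at
    its expectation); with zero moderator shifts this is exactly the
    population value, and with shifts it is the conditional-at-means value
    the package's estimators target.
    """
    old_prev = 0.0
    for spec in config.confounders:
        if spec.name == "age" and spec.kind == "continuous":
            from scipy.stats import norm

            old_prev = float(norm.sf(config.age_cutoff, spec.mean, spec.sd))
    a_eff = config.true_a + config.moderator_shift_a * old_prev
    b_eff = config.true_b + config.moderator_shift_b * old_prev
    # Mediator-model intercept as generated (covariate effects are centred).
    mu0 = config.m_mean - config.true_a * config.x_mean
    return natural_effects_from_coefficients(
        a=a_eff,
        mu0=mu0,
        c_prime=config.true_c_prime,
        b=b_eff,
        h=config.true_interaction,
        x0=x0,
        x1=x1,
        covariate_profile={
            spec.name: spec.expectation() for spec in config.confounders
        },
    )
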