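"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import medmultiverse as mv


def simple_mediation_data(
    n: int,
    a: float = 0.5,
    b: float = 0.4,
    c_prime: float = 0.2,
    h: float = 0.0,
    mu_m: float = 0.0,
    sd_m: float = 1.0,
    sd_y: float = 1.0,
    x_mean: float = 0.0,
    x_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal three-variable mediation generator for unit tests (the full
    cohort emulator lives in the synthetic module)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(x_mean, x_sd, n)
    m = mu_m + a * x + rng.normal(0.0, sd_m, n)
    y = c_prime * x + b * m + h * x * m + rng.normal(0.0, sd_y, n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


def potential_outcome_oracle(
    a: float,
    mu0: float,
    c_prime: float,
    b: float,
    h: float,
    resid_sd_m: float,
    x0: float,
    x1: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
):
    """Brute-force natural effects by simulating potential mediator values.

    Draws M(x) = mu0 + a*x + eps with eps from the mediator residual
    distribution, evaluates the outcome mean surface at cross-world
    combinations, and averages.  Returns dicts of estimates and Monte Carlo
    standard errors.  Independent of the closed forms under test.
    """
    rng = np.random.default_rng(seed)
    eps0 = rng.normal(0.0, resid_sd_m, n_draws)
    eps1 = rng.normal(0.0, resid_sd_m, n_draws)
    m_at_x0 = mu0 + a * x0 + eps0
    m_at_x1 = mu0 + a * x1 + eps1

    def y_mean(x, m):
        return c_prime * x + b * m + h * x * m

    per_draw = {
        "pnde": y_mean(x1, m_at_x0) - y_mean(x0, m_at_x0),
        "tnde": y_mean(x1, m_at_x1) - y_mean(x0, m_at_x1),
        "pnie": y_mean(x0, m_at_x1) - y_mean(x0, m_at_x0),
        "tnie": y_mean(x1, m_at_x1) - y_mean(x1, m_at_x0),
    }
    estimates = {k: float(v.mean()) for k, v in per_draw.items()}
    errors = {k: float(v.std(ddof=1) / np.sqrt(n_draws)) for k, v in per_draw.items()}
    return estimates, errors


@pytest.fixture(scope="session")
def cohort_data() -> pd.DataFrame:
    """One synthetic cohort at the default (worked-example) scale."""
    return mv.generate(mv.lasa_like(seed=7))


@pytest.fixture(scope="session")
def full_run(cohort_data):
    """A complete 108-universe multiverse run, shared across tests."""
    points = mv.worked_example_decision_points()
    universes = mv.enumerate_universes(points)
    config = mv.default_config(seed=7, mc_draws=2000)
    return mv.run_multiverse(cohort_data, universes, config, points)
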