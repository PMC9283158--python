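"""Variable-centric analysis decisions.

Covers the determinant recodings (percent weight change and the
Edwards-Nunnally reliable-change categorization), the >=10%
change-in-estimate confounder-selection rule, and binary-moderator
simple-slopes path estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traditional import PathCoefficients, estimate_paths

logger = logging.getLogger(__name__)

DECREASED = "decreased"
STABLE = "stable"
INCREASED = "increased"


def percent_weight_change(lowest_since_25, current):
    """Percentage change between the lowest body weight since age 25 and the
    currently measured weight: 100 * (current - lowest) / lowest.

    Accepts scalars or arrays; both weights must be strictly positive.
    """
    lowest = np.asarray(lowest_since_25, float)
    cur = np.asarray(current, float)
    with np.errstate(invalid="ignore"):
        if np.any(lowest[~np.isnan(lowest)] <= 0) or np.any(cur[~np.isnan(cur)] <= 0):
            raise ValueError("weights must be strictly positive")
    result = 100.0 * (cur - lowest) / lowest
    return float(result) if result.ndim == 0 else result


def edwards_nunnally_classify(
    pre,
    post,
    reliability: float,
    pre_mean: float,
    pre_sd: float,
):
    """Classify individual change as decreased / stable / increased.

    The Edwards-Nunnally index regresses the pretest toward the group mean by
    the scale reliability and surrounds it with a band of two standard errors
    of measurement:

        adjusted = reliability * (pre - pre_mean) + pre_mean
        band     = adjusted +/- 2 * pre_sd * sqrt(1 - reliability)

    A posttest above the band is a reliable increase, below a reliable
    decrease; values on or inside the band (boundary inclusive) are stable.
    As reliability -> 1 the band collapses to the pretest itself.
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError("reliability must be in (0, 1]")
    if pre_sd <= 0:
        raise ValueError("pre_sd must be positive")
    pre_arr = np.asarray(pre, float)
    post_arr = np.asarray(post, float)
    adjusted = reliability * (pre_arr - pre_mean) + pre_mean
    half_width = 2.0 * pre_sd * np.sqrt(1.0 - reliability)
    labels = np.where(
        post_arr > adjusted + half_width,
        INCREASED,
        np.where(post_arr < adjusted - half_width, DECREASED, STABLE),
    )
    labels = np.where(np.isnan(pre_arr) | np.isnan(post_arr), None, labels)
    return labels.item() if labels.ndim == 0 else labels


@dataclass(frozen=True)
class ConfounderSelection:
    """Outcome of the change-in-estimate screen.

    ``change_table`` maps each candidate to its maximum absolute percent
    change across the a, b and c' paths; ``selected`` holds the candidates
    at or above the threshold (inclusive).
    """

    candidates: tuple[str, ...]
    selected: tuple[str, ...]
    change_table: Mapping[str, float]
    threshold: float
    details: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


def change_in_estimate_select(
    data: pd.DataFrame,
    determinant: str,
    mediator: str,
    outcome: str,
    candidates: Sequence[str],
    threshold: float = 10.0,
    base_covariates: Sequence[str] = (),
    moderator: str | None = None,
    target_level: float | None = None,
    tolerance: float = 1e-10,
) -> ConfounderSelection:
    """Select confounders whose single-candidate adjustment shifts any of the
    a, b, c' path estimates by at least ``threshold`` percent.

    Each candidate is evaluated one-at-a-time against the base (unadjusted)
    model: the mediator and outcome equations are refitted with the candidate
    added, and the percent change (adjusted - unadjusted) / unadjusted * 100
    is computed for each path.  Both fits for a candidate use the complete
    cases of the candidate's own variable set, so the comparison is not
    confounded by differential missingness.  Paths with a near-zero
    unadjusted estimate are skipped with a warning (the ratio is undefined).
    """
    overlap = set(candidates) & {determinant, mediator, outcome}
    if overlap:
        raise ValueError(f"candidates must be disjoint from X/M/Y: {sorted(overlap)}")
    change_table: dict[str, float] = {}
    details: dict[str, dict[str, float]] = {}
    notes: list[str] = []
    selected: list[str] = []
    for cand in candidates:
        subset_cols = [determinant, mediator, outcome, cand, *base_covariates]
        if moderator is not None:
            subset_cols.append(moderator)
        subset = data.dropna(subset=list(dict.fromkeys(subset_cols)))
        base = estimate_paths(
            subset,
            determinant,
            mediator,
            outcome,
            covariates_mediator=list(base_covariates),
            covariates_outcome=list(base_covariates),
            moderator=moderator,
            target_level=target_level,
        )
        adj = estimate_paths(
            subset,
            determinant,
            mediator,
            outcome,
            covariates_mediator=[*base_covariates, cand],
            covariates_outcome=[*base_covariates, cand],
            moderator=moderator,
            target_level=target_level,
        )
        per_path: dict[str, float] = {}
        for path in ("a", "b", "c_prime"):
            unadjusted = getattr(base, path)[0]
            adjusted = getattr(adj, path)[0]
            if abs(unadjusted) < tolerance:
                msg = f"{cand}: unadjusted {path} near zero; %change undefined"
                notes.append(msg)
                logger.warning(msg)
                continue
            per_path[path] = 100.0 * (adjusted - unadjusted) / unadjusted
        details[cand] = per_path
        max_change = max((abs(v) for v in per_path.values()), default=0.0)
        change_table[cand] = max_change
        if max_change >= threshold:
            selected.append(cand)
    return ConfounderSelection(
        candidates=tuple(candidates),
        selected=tuple(selected),
        change_table=change_table,
        threshold=threshold,
        details=details,
        warnings=tuple(notes),
    )


def simple_slopes(
    data: pd.DataFrame,
    determinant: str,
    mediator: str,
    outcome: str,
    moderator: str,
    target_level: float,
    covariates_mediator: Sequence[str] = (),
    covariates_outcome: Sequence[str] = (),
    include_interaction: bool = False,
) -> PathCoefficients:
    """Stratum-specific path coefficients from pooled moderated models.

    Determinant-by-moderator terms are added to every equation where the
    determinant appears, and a mediator-by-moderator term to the outcome
    equation; the returned paths are the simple slopes at ``target_level``
    (e.g. a(z) = a + z * a_xz) with standard errors from the
    linear-combination variance.  At the reference level (z = 0) the simple
    slopes equal the main-effect coefficients of the augmented fits exactly.
    """
    return estimate_paths(
        data,
        determinant,
        mediator,
        outcome,
        covariates_mediator=covariates_mediator,
        covariates_outcome=covariates_outcome,
        include_interaction=include_interaction,
        moderator=moderator,
        target_level=target_level,
    )
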