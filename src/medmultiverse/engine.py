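"""Multiverse enumeration and execution.

Declares decision points, enumerates every combination of analysis decisions
(the universes), collapses redundant universes whose resolved model
specifications coincide, runs the full mediation analysis in each universe,
and tabulates the results in one long table.

The built-in worked-example grid has five decision points — determinant
coding (3), confounder set (2), confounder consideration (2), age moderation
(3) and determinant-mediator interaction handling (3) — for
3 x 2 x 2 x 3 x 3 = 108 indirect/direct specifications.  The total effect
does not involve the mediator, so the interaction axis is irrelevant to it
and the grid collapses to 36 distinct total-effect specifications.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import transforms
from .causal import natural_effects_from_paths
from .inference import joint_blocks, mediation_verdict_ci, monte_carlo_ci
from .traditional import estimate_paths, traditional_result
from .transforms import change_in_estimate_select, edwards_nunnally_classify

logger = logging.getLogger(__name__)

# Option ids of the built-in worked-example grid.  The first option of every
# decision point is the original-study decision.
DET_CONTINUOUS = "continuous"
DET_INCREASED = "increased_vs_stable"
DET_DECREASED = "decreased_vs_stable"
CONF_FULL = "full"
CONF_NO_HORMONAL = "no_hormonal"
SEL_APRIORI = "a_priori"
SEL_CIE = "change_in_estimate"
MOD_ALL = "all_ages"
MOD_YOUNG = "young_old"
MOD_OLD = "old_old"
INT_NONE = "none"
INT_PURE = "pure_natural"
INT_TOTAL = "total_natural"

OLD_AGE_COLUMN = "_old_age"
CONTRAST_COLUMN = "_determinant_contrast"
CLASS_COLUMN = "_weight_class"


@dataclass(frozen=True)
class DecisionOption:
    option_id: str
    label: str = ""
    rationale: str = ""


@dataclass(frozen=True)
class DecisionPoint:
    """A named analysis decision with its ordered alternatives.

    ``affects_total_effect`` marks whether the decision changes the
    total-effect model; decisions that only touch the mediator machinery
    (interaction handling) leave the total effect untouched and drive the
    deduplication of total-effect specifications.
    """

    name: str
    options: tuple[DecisionOption, ...]
    affects_total_effect: bool = True

    def __post_init__(self) -> None:
        if not self.options:
            raise ValueError(f"decision point {self.name!r} has no options")
        ids = [o.option_id for o in self.options]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate option ids in decision point {self.name!r}")


@dataclass
class UniverseSpec:
    """One fully specified analysis: exactly one choice per decision point."""

    universe_id: int
    choices: dict[str, str]
    is_original: bool = False


def worked_example_decision_points() -> list[DecisionPoint]:
    """The worked-example grid: 3 x 2 x 2 x 3 x 3 = 108 universes."""

    def opts(*ids: str) -> tuple[DecisionOption, ...]:
        return tuple(DecisionOption(i, i.replace("_", " ")) for i in ids)

    return [
        DecisionPoint("determinant", opts(DET_CONTINUOUS, DET_INCREASED, DET_DECREASED)),
        DecisionPoint("confounder_set", opts(CONF_FULL, CONF_NO_HORMONAL)),
        DecisionPoint("confounder_selection", opts(SEL_APRIORI, SEL_CIE)),
        DecisionPoint("age_moderation", opts(MOD_ALL, MOD_YOUNG, MOD_OLD)),
        DecisionPoint(
            "interaction",
            opts(INT_NONE, INT_PURE, INT_TOTAL),
            affects_total_effect=False,
        ),
    ]


def count_universes(points: Sequence[DecisionPoint]) -> int:
    return math.prod(len(p.options) for p in points)


def count_total_effect_specs(points: Sequence[DecisionPoint]) -> int:
    """Number of distinct total-effect specifications: the grid product over
    the decision points that reach the total-effect model."""
    return math.prod(
        len(p.options) for p in points if p.affects_total_effect
    )


def enumerate_universes(points: Sequence[DecisionPoint]) -> list[UniverseSpec]:
    """Full Cartesian product in lexicographic order (declared point order,
    then option order), universe ids consecutive from 1.  The universe made
    of every first option is the original specification."""
    if not points:
        raise ValueError("at least one decision point is required")
    names = [p.name for p in points]
    if len(names) != len(set(names)):
        raise ValueError("duplicate decision point names")
    universes = []
    for i, combo in enumerate(
        itertools.product(*[[o.option_id for o in p.options] for p in points]),
        start=1,
    ):
        universes.append(
            UniverseSpec(
                universe_id=i,
                choices=dict(zip(names, combo)),
                is_original=(i == 1),
            )
        )
    return universes


@dataclass
class AnalysisConfig:
    """Column roles and analysis parameters shared across the multiverse.

    Thresholds are the worked example's: significance level 0.05,
    proportion-mediated criterion 20%, change-in-estimate criterion 10%,
    weight-scale reliability (Cronbach's alpha) 0.822, old-old age cutoff 75.
    The determinant contrast for natural effects is x0 = 0 (no weight
    change) to x1 = 1 (one percentage-point increase) for the continuous
    coding, and reference-vs-index (0 to 1) for the categorical codings.
    """

    determinant: str = "pct_weight_change"
    mediator: str = "fat_mass"
    outcome: str = "bmd"
    lowest_weight: str = "lowest_weight"
    current_weight: str = "current_weight"
    age: str = "age"
    confounders_full: tuple[str, ...] = ()
    confounders_hormonal: tuple[str, ...] = ()
    alpha: float = 0.05
    proportion_threshold: float = 20.0
    cie_threshold: float = 10.0
    reliability: float = 0.822
    age_cutoff: float = 75.0
    x0: float = 0.0
    x1: float = 1.0
    mc_draws: int = 20000
    seed: int = 0
    en_pre_mean: float | None = None
    en_pre_sd: float | None = None


def default_config(**overrides) -> AnalysisConfig:
    """Config matching the synthetic generator's column roster."""
    from .synthetic import HORMONAL_NAMES, GeneratorConfig

    non_hormonal = tuple(c.name for c in GeneratorConfig().confounders)
    cfg = AnalysisConfig(
        confounders_full=non_hormonal + tuple(HORMONAL_NAMES),
        confounders_hormonal=tuple(HORMONAL_NAMES),
    )
    return replace(cfg, **overrides)


@dataclass
class ResolvedUniverse:
    """A universe with every decision resolved against the data: concrete
    determinant column, covariate set, moderation level and estimands."""

    universe: UniverseSpec
    x_column: str
    included_classes: tuple[str, ...] | None
    covariates: tuple[str, ...]
    candidates: tuple[str, ...]
    moderator_level: float | None
    include_interaction: bool
    estimand_indirect: str
    estimand_direct: str
    x0: float
    x1: float
    warnings: tuple[str, ...] = ()

    @property
    def signature(self) -> tuple:
        """Resolved model specification; universes with equal signatures are
        redundant (same data situation, same estimand)."""
        return (
            self.x_column,
            self.included_classes,
            frozenset(self.covariates),
            self.moderator_level,
            self.include_interaction,
            self.estimand_indirect,
        )

    @property
    def total_signature(self) -> tuple:
        """Total-effect model specification (mediator machinery excluded)."""
        return (
            self.x_column,
            self.included_classes,
            frozenset(self.covariates),
            self.moderator_level,
        )


_ESTIMANDS = {
    INT_NONE: ("ab", "c_prime", False),
    INT_PURE: ("PNIE", "PNDE", True),
    INT_TOTAL: ("TNIE", "TNDE", True),
}

_CLASS_SUBSETS = {
    DET_INCREASED: (transforms.INCREASED, transforms.STABLE),
    DET_DECREASED: (transforms.DECREASED, transforms.STABLE),
}

_MOD_LEVELS = {MOD_ALL: None, MOD_YOUNG: 0.0, MOD_OLD: 1.0}


def prepare_frame(data: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Attach derived columns: the old-age indicator and the reliable-change
    weight class (Edwards-Nunnally, reliability from config, pre mean/sd from
    the observed weight pairs unless supplied)."""
    frame = data.copy()
    age = frame[config.age]
    frame[OLD_AGE_COLUMN] = np.where(
        age.isna(), np.nan, (age >= config.age_cutoff).astype(float)
    )
    pre = frame[config.lowest_weight]
    post = frame[config.current_weight]
    pre_mean = (
        config.en_pre_mean if config.en_pre_mean is not None else float(pre.mean())
    )
    pre_sd = config.en_pre_sd if config.en_pre_sd is not None else float(pre.std())
    labels = edwards_nunnally_classify(
        pre.to_numpy(float), post.to_numpy(float), config.reliability, pre_mean, pre_sd
    )
    frame[CLASS_COLUMN] = labels
    return frame


def _determinant_subset(
    frame: pd.DataFrame, det_option: str, config: AnalysisConfig
) -> tuple[pd.DataFrame, str, tuple[str, ...] | None, float, float]:
    if det_option == DET_CONTINUOUS:
        return frame, config.determinant, None, config.x0, config.x1
    index_class, reference = _CLASS_SUBSETS[det_option]
    subset = frame[frame[CLASS_COLUMN].isin([index_class, reference])].copy()
    subset[CONTRAST_COLUMN] = (subset[CLASS_COLUMN] == index_class).astype(float)
    return subset, CONTRAST_COLUMN, (index_class, reference), 0.0, 1.0


def resolve_universes(
    frame: pd.DataFrame,
    universes: Sequence[UniverseSpec],
    config: AnalysisConfig,
) -> list[ResolvedUniverse]:
    """Resolve each universe's decisions into a concrete model specification.

    Change-in-estimate selection is executed once per (determinant coding,
    candidate set, moderation) combination and cached — it does not depend
    on the interaction-handling decision.  In stratified universes the
    percent changes are evaluated on the stratum simple slopes.
    """
    selection_cache: dict[tuple, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    resolved = []
    for uni in universes:
        ch = uni.choices
        det = ch["determinant"]
        subset, x_col, classes, x0, x1 = _determinant_subset(frame, det, config)
        candidates = tuple(config.confounders_full)
        if ch["confounder_set"] == CONF_NO_HORMONAL:
            candidates = tuple(
                c for c in candidates if c not in set(config.confounders_hormonal)
            )
        mod_level = _MOD_LEVELS[ch["age_moderation"]]
        warns: list[str] = []
        if ch["confounder_selection"] == SEL_APRIORI:
            covariates = candidates
        else:
            key = (det, candidates, ch["age_moderation"])
            if key not in selection_cache:
                try:
                    sel = change_in_estimate_select(
                        subset,
                        x_col,
                        config.mediator,
                        config.outcome,
                        candidates,
                        threshold=config.cie_threshold,
                        moderator=OLD_AGE_COLUMN if mod_level is not None else None,
                        target_level=mod_level,
                    )
                    selection_cache[key] = (sel.selected, sel.warnings)
                except Exception as exc:  # recorded, not fatal
                    logger.warning("confounder selection failed for %s: %s", key, exc)
                    selection_cache[key] = (candidates, (f"selection failed: {exc}",))
            covariates, sel_warns = selection_cache[key]
            warns.extend(sel_warns)
        est_ind, est_dir, interaction = _ESTIMANDS[ch["interaction"]]
        resolved.append(
            ResolvedUniverse(
                universe=uni,
                x_column=x_col,
                included_classes=classes,
                covariates=tuple(covariates),
                candidates=candidates,
                moderator_level=mod_level,
                include_interaction=interaction,
                estimand_indirect=est_ind,
                estimand_direct=est_dir,
                x0=x0,
                x1=x1,
                warnings=tuple(warns),
            )
        )
    return resolved


def detect_redundancy(resolved: Sequence[ResolvedUniverse]) -> dict[int, int]:
    """Map every universe id to the canonical (first-seen) universe id with
    an identical resolved model specification."""
    canon: dict[tuple, int] = {}
    mapping: dict[int, int] = {}
    for ru in resolved:
        sig = ru.signature
        uid = ru.universe.universe_id
        mapping[uid] = canon.setdefault(sig, uid)
    return mapping


def _derived_seed(base: int, *tags: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base) & 0x7FFFFFFF, spawn_key=tuple(tags))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class _UniverseEstimates:
    indirect: object = None  # EffectCI
    direct: object = None
    total: object = None
    paths: object = None
    effects: object = None  # NaturalEffects, when interaction is modelled
    verdicts: object = None  # TraditionalResult
    ci_verdict: bool | None = None
    ab_identity_applicable: bool = False
    ab_identity_gap: float = float("nan")
    n_complete: int = 0
    error: str | None = None


def analyze_universe(
    frame: pd.DataFrame,
    ru: ResolvedUniverse,
    config: AnalysisConfig,
    canonical_id: int,
) -> _UniverseEstimates:
    """Fit one universe: paths, point estimates, Monte Carlo intervals, and
    both mediation verdicts."""
    try:
        subset, x_col, _, x0, x1 = _determinant_subset(
            frame, ru.universe.choices["determinant"], config
        )
        moderator = OLD_AGE_COLUMN if ru.moderator_level is not None else None
        paths = estimate_paths(
            subset,
            x_col,
            config.mediator,
            config.outcome,
            covariates_mediator=list(ru.covariates),
            covariates_outcome=list(ru.covariates),
            include_interaction=ru.include_interaction,
            moderator=moderator,
            target_level=ru.moderator_level,
        )
        dx = x1 - x0

        fm, fo, ft = paths.fit_mediator, paths.fit_outcome, paths.fit_total
        k_m = len(fm.term_names)

        def weight_vec(fit, mapping) -> np.ndarray:
            w = np.zeros(len(fit.term_names))
            for term, val in mapping.items():
                w[fit.index(term)] = val
            return w

        wa = weight_vec(fm, paths.w_a)
        wmu0 = weight_vec(fm, paths.w_mu0)
        wb = weight_vec(fo, paths.w_b)
        wcp = weight_vec(fo, paths.w_c_prime)
        wh = (
            weight_vec(fo, paths.w_interaction)
            if paths.w_interaction is not None
            else np.zeros(len(fo.term_names))
        )

        def components(draws):
            dm, do = draws[:, :k_m], draws[:, k_m:]
            return dm @ wa, dm @ wmu0, do @ wb, do @ wcp, do @ wh

        def indirect_fn(draws):
            a_d, _, b_d, _, h_d = components(draws)
            x_ref = {"ab": x0, "PNIE": x0, "TNIE": x1}[ru.estimand_indirect]
            return (b_d + h_d * x_ref) * a_d * dx

        def direct_fn(draws):
            a_d, mu0_d, _, cp_d, h_d = components(draws)
            x_ref = {"c_prime": None, "PNDE": x0, "TNDE": x1}[ru.estimand_direct]
            if x_ref is None:
                return cp_d * dx
            return (cp_d + h_d * (mu0_d + a_d * x_ref)) * dx

        est, cov = joint_blocks(fm.coefficients, fm.covariance, fo.coefficients, fo.covariance)
        seed_joint = _derived_seed(config.seed, canonical_id, 0)
        indirect_ci = monte_carlo_ci(
            est, cov, indirect_fn, level=1 - config.alpha,
            n_draws=config.mc_draws, seed=seed_joint,
        )
        direct_ci = monte_carlo_ci(
            est, cov, direct_fn, level=1 - config.alpha,
            n_draws=config.mc_draws, seed=seed_joint,
        )

        wc = weight_vec(ft, paths.w_c)
        total_ci = monte_carlo_ci(
            ft.coefficients,
            ft.covariance,
            lambda draws: (draws @ wc) * dx,
            level=1 - config.alpha,
            n_draws=config.mc_draws,
            seed=_derived_seed(config.seed, canonical_id, 1),
        )

        effects = None
        if ru.include_interaction:
            effects = natural_effects_from_paths(paths, x0, x1)

        verdicts = traditional_result(
            paths,
            alpha=config.alpha,
            proportion_threshold=config.proportion_threshold,
            indirect=indirect_ci.estimate,
            direct=direct_ci.estimate,
        )
        applicable = (not ru.include_interaction) and (moderator is None)
        gap = float("nan")
        if applicable:
            ab = paths.a[0] * paths.b[0]
            gap = ab - (paths.c[0] - paths.c_prime[0])
        return _UniverseEstimates(
            indirect=indirect_ci,
            direct=direct_ci,
            total=total_ci,
            paths=paths,
            effects=effects,
            verdicts=verdicts,
            ci_verdict=mediation_verdict_ci(indirect_ci),
            ab_identity_applicable=applicable,
            ab_identity_gap=gap,
            n_complete=paths.n_complete,
        )
    except Exception as exc:
        logger.warning(
            "universe %d failed: %s", ru.universe.universe_id, exc
        )
        return _UniverseEstimates(error=str(exc))


@dataclass
class MultiverseResult:
    """Long-format multiverse output.

    ``table`` holds one indirect and one direct row per universe, plus one
    total-effect row per distinct total-effect model.  ``canonical_map``
    records the redundancy collapse; ``selections`` the cached
    change-in-estimate results.
    """

    table: pd.DataFrame
    universes: list[UniverseSpec]
    resolved: list[ResolvedUniverse]
    canonical_map: dict[int, int]
    config: AnalysisConfig
    points: list[DecisionPoint] = field(default_factory=list)

    def rows(self, effect_type: str) -> pd.DataFrame:
        return self.table[self.table["effect_type"] == effect_type]


_COLUMNS = [
    "universe_id", "canonical_id", "redundant", "is_original",
    "effect_type", "estimand", "estimate", "ci_lower", "ci_upper",
    "significant", "ci_verdict", "causal_steps_verdict",
    "proportion_mediated", "proportion_defined", "inconsistent_mediation",
    "criteria_verdict", "ab_identity_applicable", "ab_identity_gap",
    "n_complete_cases", "warning",
]


def run_multiverse(
    data: pd.DataFrame,
    universes: Sequence[UniverseSpec],
    config: AnalysisConfig,
    points: Sequence[DecisionPoint] | None = None,
) -> MultiverseResult:
    """Execute the full mediation analysis across all universes.

    Estimates are computed once per canonical universe and reported for all
    redundant members.  Failures inside a universe are recorded in its
    ``warning`` column, never raised.
    """
    points = list(points) if points is not None else worked_example_decision_points()
    point_names = [p.name for p in points]
    required = {config.determinant, config.mediator, config.outcome,
                config.lowest_weight, config.current_weight, config.age}
    required |= set(config.confounders_full)
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"dataset lacks required columns: {sorted(missing)}")

    frame = prepare_frame(data, config)
    resolved = resolve_universes(frame, universes, config)
    canonical_map = detect_redundancy(resolved)
    by_id = {ru.universe.universe_id: ru for ru in resolved}

    estimates: dict[int, _UniverseEstimates] = {}
    for ru in resolved:
        uid = ru.universe.universe_id
        cid = canonical_map[uid]
        if cid not in estimates:
            estimates[cid] = analyze_universe(frame, by_id[cid], config, cid)

    rows: list[dict] = []

    def choice_cols(uni: UniverseSpec, drop: set[str] = frozenset()) -> dict:
        return {
            f"choice_{name}": (uni.choices[name] if name not in drop else "")
            for name in point_names
        }

    for ru in resolved:
        uni = ru.universe
        uid = uni.universe_id
        cid = canonical_map[uid]
        res = estimates[cid]
        base = {
            "universe_id": uid,
            "canonical_id": cid,
            "redundant": uid != cid,
            "is_original": uni.is_original,
            **choice_cols(uni),
            "n_complete_cases": res.n_complete,
            "warning": "; ".join(filter(None, [res.error, *ru.warnings])),
        }
        if res.error is not None:
            for etype, estimand in (
                ("indirect", ru.estimand_indirect),
                ("direct", ru.estimand_direct),
            ):
                rows.append({**base, "effect_type": etype, "estimand": estimand,
                             "estimate": np.nan, "ci_lower": np.nan,
                             "ci_upper": np.nan})
            continue
        v = res.verdicts
        shared = {
            "ci_verdict": res.ci_verdict,
            "causal_steps_verdict": v.causal_steps,
            "proportion_mediated": (
                v.proportion.value if v.proportion.defined else np.nan
            ),
            "proportion_defined": v.proportion.defined,
            "inconsistent_mediation": v.proportion.inconsistent,
            "criteria_verdict": v.criteria_verdict,
            "ab_identity_applicable": res.ab_identity_applicable,
            "ab_identity_gap": res.ab_identity_gap,
        }
        rows.append({
            **base, **shared, "effect_type": "indirect",
            "estimand": ru.estimand_indirect,
            "estimate": res.indirect.estimate,
            "ci_lower": res.indirect.lower, "ci_upper": res.indirect.upper,
            "significant": res.indirect.significant,
        })
        rows.append({
            **base, **shared, "effect_type": "direct",
            "estimand": ru.estimand_direct,
            "estimate": res.direct.estimate,
            "ci_lower": res.direct.lower, "ci_upper": res.direct.upper,
            "significant": res.direct.significant,
        })

    # Total-effect rows: one per distinct total-effect model.  The interaction
    # decision never reaches the total-effect equation; its column is blanked here.
    seen_totals: dict[tuple, int] = {}
    original_total_sig = next(
        ru.total_signature for ru in resolved if ru.universe.is_original
    )
    for ru in resolved:
        sig = ru.total_signature
        if sig in seen_totals:
            continue
        uid = ru.universe.universe_id
        cid = canonical_map[uid]
        res = estimates[cid]
        seen_totals[sig] = uid
        base = {
            "universe_id": uid,
            "canonical_id": cid,
            "redundant": False,
            "is_original": sig == original_total_sig,
            **choice_cols(ru.universe, drop={"interaction"}),
            "n_complete_cases": res.n_complete,
            "warning": "; ".join(filter(None, [res.error, *ru.warnings])),
        }
        if res.error is not None:
            rows.append({**base, "effect_type": "total", "estimand": "c",
                         "estimate": np.nan, "ci_lower": np.nan,
                         "ci_upper": np.nan})
            continue
        rows.append({
            **base, "effect_type": "total", "estimand": "c",
            "estimate": res.total.estimate,
            "ci_lower": res.total.lower, "ci_upper": res.total.upper,
            "significant": res.total.significant,
        })

    columns = (
        _COLUMNS[:4] + [f"choice_{n}" for n in point_names] + _COLUMNS[4:]
    )
    table = pd.DataFrame(rows)
    for col in columns:
        if col not in table.columns:
            table[col] = np.nan
    table = table[columns].reset_index(drop=True)
    return MultiverseResult(
        table=table,
        universes=list(universes),
        resolved=resolved,
        canonical_map=canonical_map,
        config=config,
        points=points,
    )


@dataclass(frozen=True)
class VerdictSummary:
    """Percent summaries over non-failed universes, each with its fraction."""

    pct_mediated_criteria: float
    pct_mediated_ci: float
    pct_direct_negative: float
    pct_direct_significant: float
    pct_total_positive: float
    pct_total_significant: float
    fractions: Mapping[str, tuple[int, int]]

    def as_dict(self) -> dict:
        return {
            "pct_mediated_criteria": self.pct_mediated_criteria,
            "pct_mediated_ci": self.pct_mediated_ci,
            "pct_direct_negative": self.pct_direct_negative,
            "pct_direct_significant": self.pct_direct_significant,
            "pct_total_positive": self.pct_total_positive,
            "pct_total_significant": self.pct_total_significant,
            "fractions": {k: list(v) for k, v in self.fractions.items()},
        }


def summarize_verdicts(result: MultiverseResult) -> VerdictSummary:
    """Fraction of conditions mediated under each criterion, and sign /
    significance summaries of the direct and total effects."""
    if result.table.empty:
        raise ValueError("empty multiverse result")

    def pct(frame: pd.DataFrame, mask: pd.Series) -> tuple[float, int, int]:
        denom = len(frame)
        num = int(mask.sum())
        return (100.0 * num / denom if denom else float("nan")), num, denom

    ind = result.rows("indirect")
    ind_ok = ind[ind["estimate"].notna()]
    dir_ok = result.rows("direct")
    dir_ok = dir_ok[dir_ok["estimate"].notna()]
    tot_ok = result.rows("total")
    tot_ok = tot_ok[tot_ok["estimate"].notna()]

    crit, n1, d1 = pct(ind_ok, ind_ok["criteria_verdict"].astype(bool))
    ci, n2, d2 = pct(ind_ok, ind_ok["ci_verdict"].astype(bool))
    dneg, n3, d3 = pct(dir_ok, dir_ok["estimate"] < 0)
    dsig, n4, d4 = pct(dir_ok, dir_ok["significant"].astype(bool))
    tpos, n5, d5 = pct(tot_ok, tot_ok["estimate"] > 0)
    tsig, n6, d6 = pct(tot_ok, tot_ok["significant"].astype(bool))
    return VerdictSummary(
        pct_mediated_criteria=crit,
        pct_mediated_ci=ci,
        pct_direct_negative=dneg,
        pct_direct_significant=dsig,
        pct_total_positive=tpos,
        pct_total_significant=tsig,
        fractions={
            "mediated_criteria": (n1, d1),
            "mediated_ci": (n2, d2),
            "direct_negative": (n3, d3),
            "direct_significant": (n4, d4),
            "total_positive": (n5, d5),
            "total_significant": (n6, d6),
        },
    )
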