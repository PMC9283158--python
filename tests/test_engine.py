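"""Tests of universe enumeration, redundancy collapse and the full engine."""

import numpy as np
import pandas as pd
import pytest

import medmultiverse as mv
from medmultiverse.engine import (
    DecisionOption,
    DecisionPoint,
    count_total_effect_specs,
    count_universes,
    detect_redundancy,
    enumerate_universes,
    resolve_universes,
    run_multiverse,
    summarize_verdicts,
    worked_example_decision_points,
)


def _points(*sizes, names=None):
    names = names or [f"p{i}" for i in range(len(sizes))]
    return [
        DecisionPoint(
            name, tuple(DecisionOption(f"o{j}") for j in range(k))
        )
        for name, k in zip(names, sizes)
    ]


class TestEnumeration:
    def test_worked_example_grid_has_108_universes(self):
        points = worked_example_decision_points()
        universes = enumerate_universes(points)
        assert len(universes) == 108
        assert count_universes(points) == 108
        assert count_total_effect_specs(points) == 36

    def test_single_option_single_point(self):
        universes = enumerate_universes(_points(1))
        assert len(universes) == 1 and universes[0].is_original

    def test_lexicographic_order_and_ids(self):
        universes = enumerate_universes(_points(2, 3))
        assert len(universes) == 6
        assert [u.universe_id for u in universes] == [1, 2, 3, 4, 5, 6]
        combos = [(u.choices["p0"], u.choices["p1"]) for u in universes]
        # brute-force product in declared order
        expected = [(f"o{i}", f"o{j}") for i in range(2) for j in range(3)]
        assert combos == expected
        assert universes[0].is_original and not any(
            u.is_original for u in universes[1:]
        )

    def test_count_matches_bigint_product(self):
        sizes = (3, 2, 2, 3, 3, 5, 7)
        points = _points(*sizes)
        product = 1
        for s in sizes:
            product *= s
        assert count_universes(points) == product

    def test_duplicate_point_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_universes(_points(2, 2, names=["same", "same"]))

    def test_duplicate_option_ids_rejected(self):
        with pytest.raises(ValueError, match="option ids"):
            DecisionPoint("p", (DecisionOption("a"), DecisionOption("a")))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_universes([])


class TestRedundancy:
    def test_identical_resolved_specs_collapse(self, cohort_data):
        config = mv.default_config(seed=0)
        frame = mv.engine.prepare_frame(cohort_data, config)
        universes = enumerate_universes(worked_example_decision_points())
        resolved = resolve_universes(frame, universes, config)
        # Force two universes to identical resolved specs
        resolved[1].covariates = resolved[0].covariates
        resolved[1].include_interaction = resolved[0].include_interaction
        resolved[1].estimand_indirect = resolved[0].estimand_indirect
        mapping = detect_redundancy(resolved[:2])
        assert mapping[2] == 1

    def test_distinct_specs_map_to_themselves(self, cohort_data):
        config = mv.default_config(seed=0)
        frame = mv.engine.prepare_frame(cohort_data, config)
        universes = enumerate_universes(worked_example_decision_points())
        resolved = resolve_universes(frame, universes, config)
        mapping = detect_redundancy(resolved)
        distinct = {ru.signature for ru in resolved}
        assert len(set(mapping.values())) == len(distinct)

    def test_selected_sets_differ_from_a_priori(self, full_run):
        # The >= 10%-selection universes resolve to different covariate sets
        # than the a-priori universes, so they are not redundant.
        by_id = {ru.universe.universe_id: ru for ru in full_run.resolved}
        apriori = next(
            ru for ru in full_run.resolved
            if ru.universe.choices["confounder_selection"] == "a_priori"
        )
        partner_choices = dict(apriori.universe.choices)
        partner_choices["confounder_selection"] = "change_in_estimate"
        partner = next(
            ru for ru in full_run.resolved if ru.universe.choices == partner_choices
        )
        assert set(partner.covariates) != set(apriori.covariates)
        assert full_run.canonical_map[partner.universe.universe_id] != \
            full_run.canonical_map[apriori.universe.universe_id]


class TestFullRun:
    def test_row_structure(self, full_run):
        table = full_run.table
        assert len(full_run.rows("indirect")) == 108
        assert len(full_run.rows("direct")) == 108
        assert len(full_run.rows("total")) == 36
        # every universe appears exactly once per indirect/direct estimand
        assert sorted(full_run.rows("indirect")["universe_id"]) == list(range(1, 109))

    def test_estimands_follow_interaction_option(self, full_run):
        ind = full_run.rows("indirect")
        assert set(ind[ind["choice_interaction"] == "none"]["estimand"]) == {"ab"}
        assert set(ind[ind["choice_interaction"] == "pure_natural"]["estimand"]) == {"PNIE"}
        assert set(ind[ind["choice_interaction"] == "total_natural"]["estimand"]) == {"TNIE"}

    def test_total_effect_ignores_interaction_axis(self, full_run):
        # Universes differing only in interaction handling share the total
        # effect -- that is what collapses 108 to 36.
        ind = full_run.rows("indirect")
        groups = ind.groupby(
            [c for c in ind.columns
             if c.startswith("choice_") and c != "choice_interaction"]
        )["canonical_id"]
        assert all(
            len(g) == 3 for _, g in groups
        )

    def test_product_difference_identity_across_engine_run(self, full_run):
        rows = full_run.rows("indirect")
        applicable = rows[rows["ab_identity_applicable"].astype(bool)]
        assert len(applicable) >= 12
        assert (applicable["ab_identity_gap"].abs() < 1e-8).all()

    def test_criteria_verdict_implies_causal_steps(self, full_run):
        rows = full_run.rows("indirect").dropna(subset=["estimate"])
        crit = rows["criteria_verdict"].astype(bool)
        steps = rows["causal_steps_verdict"].astype(bool)
        assert (~crit | steps).all()

    def test_deterministic_end_to_end(self, cohort_data):
        points = worked_example_decision_points()
        universes = enumerate_universes(points)
        config = mv.default_config(seed=3, mc_draws=1000)
        r1 = run_multiverse(cohort_data, universes, config, points)
        r2 = run_multiverse(cohort_data, universes, config, points)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_missing_columns_abort_before_fitting(self, cohort_data):
        config = mv.default_config(seed=0)
        bad = cohort_data.drop(columns=["fat_mass"])
        with pytest.raises(ValueError, match="fat_mass"):
            run_multiverse(bad, enumerate_universes(worked_example_decision_points()), config)

    def test_power_under_strong_mediation(self):
        # With the generating model truly mediated and a large sample, the
        # indirect effect is significant in essentially all well-powered
        # universes of a reduced grid.
        data = mv.generate(mv.lasa_like(seed=5, n=4000, missing_rate=0.0))
        points = [
            DecisionPoint("determinant", (DecisionOption("continuous"),)),
            DecisionPoint("confounder_set", (DecisionOption("no_hormonal"),)),
            DecisionPoint("confounder_selection", (DecisionOption("a_priori"),)),
            DecisionPoint(
                "age_moderation",
                (DecisionOption("all_ages"), DecisionOption("young_old"),
                 DecisionOption("old_old")),
            ),
            DecisionPoint(
                "interaction",
                (DecisionOption("none"), DecisionOption("pure_natural"),
                 DecisionOption("total_natural")),
                affects_total_effect=False,
            ),
        ]
        config = mv.default_config(seed=5, mc_draws=2000)
        result = run_multiverse(data, enumerate_universes(points), config, points)
        ind = result.rows("indirect").dropna(subset=["estimate"])
        assert ind["significant"].astype(bool).mean() == 1.0


class TestSummaries:
    def test_all_mediated_is_100_percent(self, full_run):
        table = full_run.table.copy()
        table.loc[table["effect_type"] == "indirect", "criteria_verdict"] = True
        table.loc[table["effect_type"] == "indirect", "ci_verdict"] = True
        forced = mv.MultiverseResult(
            table=table, universes=full_run.universes, resolved=full_run.resolved,
            canonical_map=full_run.canonical_map, config=full_run.config,
        )
        summary = summarize_verdicts(forced)
        assert summary.pct_mediated_criteria == 100.0
        assert summary.pct_mediated_ci == 100.0

    def test_hand_set_verdicts_fraction(self, full_run):
        table = full_run.rows("indirect").head(10).copy()
        table["criteria_verdict"] = [True] * 4 + [False] * 6
        table["ci_verdict"] = [True] * 4 + [False] * 6
        fixture = mv.MultiverseResult(
            table=table, universes=[], resolved=[], canonical_map={},
            config=full_run.config,
        )
        summary = summarize_verdicts(fixture)
        assert summary.pct_mediated_criteria == pytest.approx(40.0)
        assert summary.fractions["mediated_criteria"] == (4, 10)

    def test_ci_percentage_at_least_criteria_percentage(self, full_run):
        # Interval-based mediation is insensitive to a non-significant total
        # effect and to the proportion-mediated threshold, so it can only
        # declare mediation at least as often.
        summary = summarize_verdicts(full_run)
        assert summary.pct_mediated_ci >= summary.pct_mediated_criteria
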