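"""Tests of determinant recoding, confounder selection and simple slopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medmultiverse.transforms import (
    DECREASED,
    INCREASED,
    STABLE,
    change_in_estimate_select,
    edwards_nunnally_classify,
    percent_weight_change,
    simple_slopes,
)

from conftest import simple_mediation_data


class TestPercentWeightChange:
    @pytest.mark.parametrize(
        "lowest,current,expected",
        [(60.0, 66.0, 10.0), (70.0, 70.0, 0.0), (80.0, 72.0, -10.0)],
    )
    def test_arithmetic(self, lowest, current, expected):
        assert percent_weight_change(lowest, current) == pytest.approx(expected)

    def test_vectorized(self):
        out = percent_weight_change(np.array([50.0, 100.0]), np.array([55.0, 90.0]))
        np.testing.assert_allclose(out, [10.0, -10.0])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            percent_weight_change(0.0, 60.0)
        with pytest.raises(ValueError):
            percent_weight_change(60.0, -1.0)


class TestEdwardsNunnally:
    R = 0.822  # weight-scale reliability used throughout the worked example

    def test_unchanged_at_mean_is_stable(self):
        assert edwards_nunnally_classify(62.0, 62.0, self.R, 62.0, 8.0) == STABLE

    def test_band_boundary_is_stable_and_epsilon_beyond_is_not(self):
        # Boundary oracle straight from the band formula: for pre == pre_mean
        # the adjusted pretest is pre_mean and the band is +/- 2*sd*sqrt(1-r).
        pre_mean, sd = 62.0, 8.0
        bound = 2.0 * sd * np.sqrt(1.0 - self.R)
        at_bound = pre_mean + bound
        assert edwards_nunnally_classify(pre_mean, at_bound, self.R, pre_mean, sd) == STABLE
        assert (
            edwards_nunnally_classify(pre_mean, at_bound + 1e-9, self.R, pre_mean, sd)
            == INCREASED
        )
        assert (
            edwards_nunnally_classify(pre_mean, pre_mean - bound - 1e-9, self.R, pre_mean, sd)
            == DECREASED
        )

    def test_reliability_one_collapses_band_to_pretest(self):
        assert edwards_nunnally_classify(70.0, 70.0, 1.0, 62.0, 8.0) == STABLE
        assert edwards_nunnally_classify(70.0, 70.0 + 1e-9, 1.0, 62.0, 8.0) == INCREASED
        assert edwards_nunnally_classify(70.0, 70.0 - 1e-9, 1.0, 62.0, 8.0) == DECREASED

    def test_invalid_reliability_rejected(self):
        for r in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                edwards_nunnally_classify(60.0, 60.0, r, 62.0, 8.0)

    @given(
        pre=st.floats(30.0, 150.0),
        post=st.floats(30.0, 150.0),
        r=st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_partition_is_exhaustive_and_exclusive(self, pre, post, r):
        label = edwards_nunnally_classify(pre, post, r, 62.0, 8.0)
        assert label in {DECREASED, STABLE, INCREASED}

    def test_vectorized_with_missing(self):
        labels = edwards_nunnally_classify(
            np.array([62.0, 62.0, np.nan]),
            np.array([90.0, 40.0, 60.0]),
            self.R, 62.0, 8.0,
        )
        assert list(labels) == [INCREASED, DECREASED, None]


def _confounded_dataset(n=10_000, seed=0):
    """Planted common cause of M and Y (strong) plus an independent dud."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    common = rng.normal(size=n)
    dud = rng.normal(size=n)
    m = 0.5 * x + 0.8 * common + rng.normal(size=n)
    y = 0.3 * x + 0.4 * m + 0.8 * common + rng.normal(size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y, "common": common, "dud": dud})


def population_b_paths():
    """Omitted-variable-bias oracle: population b with and without the common
    cause, from the analytic covariance matrix of the generator above."""
    # Cov built from the structural equations of _confounded_dataset.
    var_m = 0.25 + 0.64 + 1.0
    cov_xm = 0.5
    cov_ym = 0.3 * cov_xm + 0.4 * var_m + 0.8 * 0.8
    cov_yx = 0.3 + 0.4 * 0.5
    design = np.array([[1.0, cov_xm], [cov_xm, var_m]])
    unadjusted = np.linalg.solve(design, np.array([cov_yx, cov_ym]))
    return unadjusted[1], 0.4  # unadjusted b, adjusted (true) b


class TestChangeInEstimate:
    def test_planted_common_cause_selected_and_dud_not(self):
        b_unadj, b_adj = population_b_paths()
        pct = abs(100.0 * (b_adj - b_unadj) / b_unadj)
        assert pct >= 10.0  # the generator plants a >= 10% shift by design
        sel = change_in_estimate_select(
            _confounded_dataset(), "x", "m", "y", ["common", "dud"], threshold=10.0
        )
        assert sel.selected == ("common",)
        assert sel.change_table["dud"] < 5.0
        # observed shift close to the population oracle
        assert sel.details["common"]["b"] == pytest.approx(
            100.0 * (b_adj - b_unadj) / b_unadj, abs=3.0
        )

    def test_threshold_is_inclusive(self):
        sel = change_in_estimate_select(
            _confounded_dataset(seed=1), "x", "m", "y", ["common"], threshold=10.0
        )
        exact = change_in_estimate_select(
            _confounded_dataset(seed=1), "x", "m", "y", ["common"],
            threshold=sel.change_table["common"],
        )
        assert exact.selected == ("common",)

    def test_order_invariance(self):
        data = _confounded_dataset(seed=2)
        forward = change_in_estimate_select(data, "x", "m", "y", ["common", "dud"])
        backward = change_in_estimate_select(data, "x", "m", "y", ["dud", "common"])
        assert set(forward.selected) == set(backward.selected)
        assert forward.change_table == backward.change_table

    def test_candidate_overlapping_model_variables_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            change_in_estimate_select(_confounded_dataset(), "x", "m", "y", ["m"])

    def test_near_zero_path_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        n = 2_000
        x = rng.normal(size=n)
        m = rng.normal(size=n)  # a = 0 exactly in the generator
        y = 0.4 * m + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "m": m, "y": y, "cand": rng.normal(size=n)})
        sel = change_in_estimate_select(
            data, "x", "m", "y", ["cand"], tolerance=1.0
        )  # large tolerance forces the skip path
        assert any("undefined" in w for w in sel.warnings)


class TestSimpleSlopes:
    @staticmethod
    def _moderated_data(n, a0, a1, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        z = (rng.random(n) < 0.5).astype(float)
        a = np.where(z == 1.0, a1, a0)
        m = a * x + rng.normal(size=n)
        y = 0.2 * x + 0.4 * m + rng.normal(size=n)
        return pd.DataFrame({"x": x, "m": m, "y": y, "z": z})

    def test_per_level_recovery(self):
        data = self._moderated_data(20_000, a0=0.5, a1=0.1, seed=4)
        young = simple_slopes(data, "x", "m", "y", "z", 0)
        old = simple_slopes(data, "x", "m", "y", "z", 1)
        assert abs(young.a[0] - 0.5) < 3 * young.a[1]
        assert abs(old.a[0] - 0.1) < 3 * old.a[1]

    def test_no_moderation_null(self):
        data = self._moderated_data(20_000, a0=0.4, a1=0.4, seed=5)
        young = simple_slopes(data, "x", "m", "y", "z", 0)
        old = simple_slopes(data, "x", "m", "y", "z", 1)
        gap_se = np.hypot(young.a[1], old.a[1])
        assert abs(young.a[0] - old.a[0]) < 3 * gap_se

    def test_reference_level_equals_main_effect_exactly(self):
        data = self._moderated_data(500, a0=0.5, a1=0.2, seed=6)
        paths = simple_slopes(data, "x", "m", "y", "z", 0)
        assert paths.a[0] == pytest.approx(paths.fit_mediator.coef("x"), abs=1e-14)
        assert paths.b[0] == pytest.approx(paths.fit_outcome.coef("m"), abs=1e-14)

    def test_slopes_match_stratified_refits(self):
        # Fully-interacted configuration (no extra covariates): pooled simple
        # slopes agree with per-stratum fits within standard error.
        from medmultiverse.traditional import estimate_paths

        data = self._moderated_data(5_000, a0=0.6, a1=0.2, seed=7)
        pooled = simple_slopes(data, "x", "m", "y", "z", 1)
        stratum = estimate_paths(data[data["z"] == 1.0], "x", "m", "y")
        assert abs(pooled.a[0] - stratum.a[0]) < 1e-9  # identical here: saturated
        assert abs(pooled.b[0] - stratum.b[0]) < 2 * stratum.b[1]

    def test_single_level_moderator_rejected(self):
        data = self._moderated_data(200, 0.5, 0.5, seed=8)
        data["z"] = 0.0
        with pytest.raises(ValueError, match="single level"):
            simple_slopes(data, "x", "m", "y", "z", 0)
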