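"""IPCW weights, time-dependent AUC/Brier, AUC comparison and importance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from t1dpred.fitting import ModelSpec, fit_cox, predict_risk
from t1dpred.metrics import (
    DegenerateInputError,
    censoring_weights,
    compare_auc,
    similar_performance_set,
    td_auc,
    td_auc_ci,
    td_brier,
    variable_importance,
)

from conftest import simulate_ph_frame


def brute_force_auc(preds, case, ctrl):
    """O(n^2) Mann-Whitney AUC with ties counted one half."""
    pairs = [
        1.0 if a > b else 0.5 if a == b else 0.0
        for a in preds[case]
        for b in preds[ctrl]
    ]
    return float(np.mean(pairs))


class TestCensoringWeights:
    def test_no_censoring_gives_equal_weights(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        w = censoring_weights(t, np.ones(4, bool), horizon=2.5)
        assert np.allclose(w, 1.0)

    def test_five_subject_hand_kaplan_meier(self):
        # censoring events at t=2 (4 at risk) and t=4 (2 at risk):
        # G(t) = 1 for t<2, 0.75 for 2<=t<4, 0.375 for t>=4
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([True, False, True, False, True])
        w = censoring_weights(times, events, horizon=4.5)
        expected = np.array([1.0, 0.0, 1 / 0.75, 0.0, 1 / 0.375])
        np.testing.assert_allclose(w, expected)

    def test_event_weight_is_reciprocal_left_limit(self):
        # the subject with an event exactly at a censoring time uses G(t-)
        times = np.array([2.0, 2.0, 3.0])
        events = np.array([True, False, True])
        w = censoring_weights(times, events, horizon=3.5)
        assert w[0] == pytest.approx(1.0)  # G(2-) = 1
        assert w[2] == pytest.approx(1.0 / (1 - 1 / 3))  # G(3-) = G(2) = 2/3

    def test_all_censored_before_horizon_degenerate(self):
        with pytest.raises(DegenerateInputError):
            censoring_weights([0.5, 0.6], [False, False], horizon=2.0)

    def test_truncation_clips_extreme_weights(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, 300) + 1e-3
        e = rng.uniform(size=300) < 0.3
        w = censoring_weights(t, e, horizon=np.quantile(t, 0.97), max_weight=10.0)
        assert w.max() <= 10.0


class TestTdAuc:
    @given(st.integers(5, 200), st.integers(0, 10_000))
    def test_uncensored_equals_mann_whitney_exactly(self, n, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(4.0, n) + 1e-3
        preds = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        h = float(np.median(t))
        case, ctrl = t <= h, t > h
        if not case.any() or not ctrl.any():
            return
        mine = td_auc(preds, t, np.ones(n, bool), h)
        assert mine == brute_force_auc(preds, case, ctrl)

    def test_perfect_ranking_gives_one(self):
        t = np.array([1.0, 2.0, 8.0, 9.0])
        preds = np.array([0.9, 0.8, 0.2, 0.1])
        assert td_auc(preds, t, np.ones(4, bool), 5.0) == 1.0

    def test_uninformative_predictions_near_half(self):
        rng = np.random.default_rng(1)
        n = 5000
        t = rng.exponential(4.0, n) + 1e-3
        preds = rng.uniform(size=n)
        assert td_auc(preds, t, np.ones(n, bool), 3.0) == pytest.approx(0.5, abs=0.03)

    def test_agrees_with_sksurv_under_censoring(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(2)
        n = 400
        t = rng.exponential(5.0, n) + 1e-3
        e = rng.uniform(size=n) < 0.65
        preds = rng.uniform(size=n)
        h = 3.0
        y = Surv.from_arrays(e, t)
        theirs, _ = cumulative_dynamic_auc(y, y, preds, [h])
        assert td_auc(preds, t, e, h) == pytest.approx(theirs[0], abs=1e-12)

    @given(st.integers(0, 500))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        t = rng.exponential(4.0, n) + 1e-3
        e = rng.uniform(size=n) < 0.7
        preds = rng.uniform(size=n)
        h = 2.5
        try:
            base = td_auc(preds, t, e, h)
        except DegenerateInputError:
            return
        for f in (lambda p: 2 * p + 1, np.exp, lambda p: p**3):
            assert td_auc(f(preds), t, e, h) == pytest.approx(base, abs=1e-12)

    def test_converges_to_uncensored_value_as_censoring_vanishes(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.standard_normal(n)
        t_event = 5.0 * np.exp(-0.8 * x) * rng.exponential(1.0, n) + 1e-3
        preds = x
        h = 3.0
        truth = td_auc(preds, t_event, np.ones(n, bool), h)
        errors = []
        for rate in (0.3, 0.1, 0.0):
            c = rng.exponential(1.0 / rate, n) if rate > 0 else np.full(n, np.inf)
            t_obs = np.minimum(t_event, c)
            e = t_event <= c
            errors.append(abs(td_auc(preds, np.maximum(t_obs, 1e-6), e, h) - truth))
        assert errors[0] < 0.05 and errors[1] < 0.03 and errors[2] < 1e-12

    def test_no_cases_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            td_auc([0.1, 0.2], [9.0, 8.0], [True, True], 1.0)


class TestTdBrier:
    def test_oracle_predictions_score_zero(self):
        t = np.array([1.0, 2.0, 8.0, 9.0])
        preds = np.array([1.0, 1.0, 0.0, 0.0])
        assert td_brier(preds, t, np.ones(4, bool), 5.0) == 0.0

    @given(st.floats(0.0, 1.0), st.integers(0, 100))
    def test_constant_prediction_closed_form(self, p, seed):
        rng = np.random.default_rng(seed)
        n = 80
        t = rng.exponential(4.0, n) + 1e-3
        h = 3.0
        q = float(np.mean(t <= h))
        score = td_brier(np.full(n, p), t, np.ones(n, bool), h)
        assert score == pytest.approx(q * (1 - p) ** 2 + (1 - q) * p**2, abs=1e-12)

    def test_censored_toy_matches_hand_weighted_sum(self):
        # same toy as the weight test: weights (1, 0, 4/3, 0, 8/3) at h=4.5
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([True, False, True, False, True])
        preds = np.array([0.8, 0.5, 0.6, 0.4, 0.3])
        expected = (1.0 * (1 - 0.8) ** 2 + (4 / 3) * (1 - 0.6) ** 2 + (8 / 3) * 0.3**2) / 5
        assert td_brier(preds, times, events, 4.5) == pytest.approx(expected)

    def test_agrees_with_sksurv_under_censoring(self):
        from sksurv.metrics import brier_score
        from sksurv.util import Surv

        rng = np.random.default_rng(4)
        n = 300
        t = rng.exponential(5.0, n) + 1e-3
        e = rng.uniform(size=n) < 0.6
        preds = rng.uniform(size=n)
        h = 2.0
        y = Surv.from_arrays(e, t)
        _, theirs = brier_score(y, y, (1 - preds)[:, None], [h])
        assert td_brier(preds, t, e, h) == pytest.approx(theirs[0], abs=1e-12)

    def test_true_conditional_risk_minimises_expected_brier(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.standard_normal(n)
        shape, scale = 1.2, 6.0
        t = scale * (-np.log(rng.uniform(size=n)) / np.exp(0.9 * x)) ** (1 / shape) + 1e-6
        h = 3.0
        true_risk = 1.0 - np.exp(-((h / scale) ** shape) * np.exp(0.9 * x))
        base = td_brier(true_risk, t, np.ones(n, bool), h)
        for distorted in (true_risk**2, np.sqrt(true_risk), np.full(n, true_risk.mean())):
            assert base <= td_brier(distorted, t, np.ones(n, bool), h) + 1e-3


class TestCompareAuc:
    def test_model_against_itself(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(4.0, 100) + 1e-3
        e = rng.uniform(size=100) < 0.7
        p = rng.uniform(size=100)
        r = compare_auc(p, p, t, e, 3.0)
        assert r.auc_difference == 0.0 and r.p_value == 1.0

    def test_antisymmetry_in_argument_order(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(4.0, 150) + 1e-3
        e = rng.uniform(size=150) < 0.7
        pa, pb = rng.uniform(size=150), rng.uniform(size=150)
        ab = compare_auc(pa, pb, t, e, 3.0)
        ba = compare_auc(pb, pa, t, e, 3.0)
        assert ab.auc_difference == pytest.approx(-ba.auc_difference)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_p_value_within_paired_bootstrap_bracket(self):
        """The influence-function p-value for two planted models must agree
        with a 2000-resample paired bootstrap on the same data."""
        rng = np.random.default_rng(8)
        n = 150
        x = rng.standard_normal(n)
        t = 5.0 * np.exp(-0.7 * x) * rng.exponential(1.0, n) + 1e-3
        c = rng.exponential(12.0, n)
        t_obs, e = np.minimum(t, c), t <= c
        pa = x + 0.3 * rng.standard_normal(n)  # informative
        pb = x + 1.5 * rng.standard_normal(n)  # noisier
        h = 3.0
        r = compare_auc(pa, pb, t_obs, e, h)

        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            try:
                d = td_auc(pa[idx], t_obs[idx], e[idx], h) - td_auc(
                    pb[idx], t_obs[idx], e[idx], h
                )
            except DegenerateInputError:
                continue
            diffs.append(d)
        diffs = np.asarray(diffs)
        boot_se = diffs.std(ddof=1)
        from scipy import stats

        boot_p = 2 * stats.norm.sf(abs(r.auc_difference) / boot_se)
        # same order of evidence: p-values within a factor-of-3 bracket
        assert 0.33 < (r.p_value + 1e-12) / (boot_p + 1e-12) < 3.0

    def test_uncensored_variance_matches_two_sample_decomposition(self):
        # under no censoring the influence-function variance must reproduce
        # the classic per-group (DeLong-type) variance
        rng = np.random.default_rng(9)
        n = 200
        t = rng.exponential(4.0, n) + 1e-3
        e = np.ones(n, bool)
        p = rng.uniform(size=n)
        h = 3.0
        r = compare_auc(p, np.zeros(n), t, e, h)  # second model has se 0 terms
        case, ctrl = t <= h, t > h
        auc = brute_force_auc(p, case, ctrl)
        v10 = np.var([brute_force_auc(p, np.eye(n, dtype=bool)[i], ctrl) for i in np.flatnonzero(case)], ddof=0)
        v01 = np.var([brute_force_auc(p, case, np.eye(n, dtype=bool)[j]) for j in np.flatnonzero(ctrl)], ddof=0)
        delong_se = np.sqrt(v10 / case.sum() + v01 / ctrl.sum())
        from scipy import stats

        # reconstruct the se the test used from its p-value
        z = stats.norm.isf(r.p_value / 2)
        se_used = abs(r.auc_difference) / z
        assert se_used == pytest.approx(delong_se, rel=0.15)


@pytest.fixture(scope="module")
def fitted_with_noise():
    df = simulate_ph_frame(1500, {"x": 1.2, "noise": 0.0}, seed=10)
    train, valid = df.iloc[:800], df.iloc[800:]
    fitted = fit_cox(train, ModelSpec(("x", "noise")))
    return fitted, valid


class TestVariableImportance:
    def test_noise_variable_has_negligible_importance(self, fitted_with_noise):
        fitted, valid = fitted_with_noise
        imp = variable_importance(fitted, valid, 3.0, n_repeats=20, seed=1)
        assert abs(imp["noise"]) < 0.02

    def test_informative_variable_outranks_noise(self, fitted_with_noise):
        fitted, valid = fitted_with_noise
        imp = variable_importance(fitted, valid, 3.0, n_repeats=20, seed=1)
        assert imp["x"] > imp["noise"]
        assert imp["x"] > 0.05

    def test_more_repeats_reduce_dispersion(self, fitted_with_noise):
        fitted, valid = fitted_with_noise
        few = [
            variable_importance(fitted, valid, 3.0, n_repeats=1, seed=s)["x"]
            for s in range(8)
        ]
        many = [
            variable_importance(fitted, valid, 3.0, n_repeats=25, seed=s)["x"]
            for s in range(8)
        ]
        assert np.std(many) < np.std(few)
        assert np.mean(many) == pytest.approx(np.mean(few), abs=3 * np.std(few))

    def test_single_subject_validation_undefined(self, fitted_with_noise):
        fitted, valid = fitted_with_noise
        with pytest.raises(DegenerateInputError):
            variable_importance(fitted, valid.iloc[:1], 3.0)


class TestSimilarPerformanceRule:
    AUCS = {"best": 0.80, "close": 0.79, "far": 0.75, "border": 0.771, "edge_p": 0.779}

    def test_quoted_inclusion_and_exclusion(self):
        out = similar_performance_set(
            self.AUCS, {"close": 0.5, "far": 0.3, "border": 0.5, "edge_p": 0.5}, "best"
        )
        assert "close" in out  # dAUC 0.01, p 0.5
        assert "far" not in out  # dAUC 0.05 despite p 0.3

    def test_boundary_requires_both_conditions(self):
        out = similar_performance_set(
            self.AUCS, {"close": 0.5, "far": 0.3, "border": 0.049, "edge_p": 0.5}, "best"
        )
        assert "border" not in out  # dAUC 0.029 but p 0.049
        assert "edge_p" in out  # dAUC 0.021, p 0.5

    def test_best_model_excluded_from_its_own_set(self):
        out = similar_performance_set(self.AUCS, {m: 1.0 for m in self.AUCS}, "best")
        assert "best" not in out
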