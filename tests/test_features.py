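"""Eligibility filtering, staging, derived predictors and the score registry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from t1dpred.cohort import Cohort
from t1dpred.features import (
    AgeRangeError,
    MissingInputError,
    ScoreRegistry,
    StagingError,
    apply_eligibility_filters,
    assign_stage,
    auc_over_ogtt,
    bmi_zscore,
    build_feature_vector,
    compute_score,
    flow_summary,
    load_study_flow,
)

from conftest import make_participant


class TestEligibility:
    def test_thresholds_are_inclusive(self):
        fasting = make_participant(pid="a", glucose=(7.0, 8.0, 8.5, 8.0, 7.5))
        two_hour = make_participant(pid="b", glucose=(5.0, 8.0, 9.0, 10.0, 11.1))
        a1c = make_participant(pid="c", hba1c=48.0)
        ok = make_participant(pid="d", glucose=(6.9, 8.0, 9.0, 10.0, 11.0), hba1c=47.9)
        eligible, log = apply_eligibility_filters(Cohort([fasting, two_hour, a1c, ok]))
        assert [p.id for p in eligible] == ["d"]
        assert set(log["id"]) == {"a", "b", "c"}
        assert log["reason"].str.startswith("hyperglycaemia").all()

    def test_planted_violations_counted(self):
        people = [make_participant(pid=f"p{i}") for i in range(7)]
        people += [
            make_participant(pid="x1", glucose=(7.2, 8.0, 8.5, 8.0, 7.5)),
            make_participant(pid="x2", hba1c=50.0),
            make_participant(pid="x3", glucose=(5.0, 9.0, 10.0, 11.0, 11.5)),
        ]
        eligible, log = apply_eligibility_filters(Cohort(people))
        assert len(eligible) == 7
        assert len(log) == 3

    def test_incomplete_records_logged_separately(self):
        bad = make_participant(pid="nan", hba1c=float("nan"))
        eligible, log = apply_eligibility_filters(Cohort([bad, make_participant(pid="ok")]))
        assert [p.id for p in eligible] == ["ok"]
        assert log.loc[log["id"] == "nan", "reason"].iloc[0] == "incomplete"

    def test_filter_idempotence(self):
        people = [
            make_participant(pid=f"p{i}", glucose=(4.5 + 0.3 * i, 7, 8, 7, 6.5))
            for i in range(10)
        ]
        once, _ = apply_eligibility_filters(Cohort(people))
        twice, log2 = apply_eligibility_filters(once)
        assert [p.id for p in twice] == [p.id for p in once]
        assert log2.empty


class TestStaging:
    def test_single_autoantibody(self):
        assert assign_stage(make_participant(abs_=("GADA",))).value == "single_ab"

    def test_multiple_normoglycaemic_is_stage1(self):
        p = make_participant(
            abs_=("GADA", "IAA"), glucose=(4.8, 6.5, 7.0, 6.5, 6.0), hba1c=34.0
        )
        assert assign_stage(p).value == "stage1"

    def test_multiple_dysglycaemic_is_stage2(self):
        p = make_participant(
            abs_=("GADA", "IAA"), glucose=(4.8, 7.5, 8.2, 8.4, 8.5), hba1c=34.0
        )
        assert assign_stage(p).value == "stage2"

    def test_zero_autoantibodies_rejected(self):
        with pytest.raises(StagingError):
            assign_stage(make_participant(abs_=()))

    def test_stage_partition_is_exhaustive(self):
        from t1dpred.cohort import GeneratorConfig, generate_cohort, summarize_cohort

        cohort = generate_cohort(GeneratorConfig(n_participants=500, seed=3))
        counts = summarize_cohort(cohort)["stage_counts"]
        assert sum(counts.values()) == len(cohort)


class TestOgttAuc:
    def test_constant_curve_returns_constant(self):
        assert auc_over_ogtt([0, 30, 60, 90, 120], [3.3] * 5) == pytest.approx(3.3)

    def test_linear_ramp_gives_midpoint(self):
        assert auc_over_ogtt([0, 120], [0, 120]) == pytest.approx(60.0)

    def test_matches_dense_grid_integration(self):
        rng = np.random.default_rng(4)
        times = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        values = rng.uniform(2, 12, 5)
        fine = np.linspace(0, 120, 200_001)
        oracle = np.trapezoid(np.interp(fine, times, values), fine) / 120.0
        assert auc_over_ogtt(times, values) == pytest.approx(oracle, abs=1e-9)

    def test_raw_area_switch(self):
        assert auc_over_ogtt([0, 120], [1, 1], time_average=False) == pytest.approx(120.0)

    @pytest.mark.parametrize("times", [[0, 0, 60], [60, 30, 0], [0]])
    def test_bad_grids_rejected(self, times):
        with pytest.raises(ValueError):
            auc_over_ogtt(times, [1.0] * len(times))

    @given(
        st.lists(st.floats(0.1, 20), min_size=5, max_size=5),
        st.floats(0.01, 5.0),
    )
    def test_pointwise_larger_curve_has_larger_auc(self, values, bump):
        t = [0, 30, 60, 90, 120]
        assert auc_over_ogtt(t, [v + bump for v in values]) > auc_over_ogtt(t, values)


PLANTED_LMS = pd.DataFrame(
    {
        "gender": ["female"] * 3 + ["male"] * 3,
        "age": [5.0, 10.0, 20.0] * 2,
        "L": [1.0] * 6,
        "M": [15.0, 17.0, 22.0, 15.4, 17.4, 22.4],
        "S": [0.1] * 6,
    }
)


class TestBmiZscore:
    def test_reference_median_maps_to_zero(self):
        assert bmi_zscore(17.0, 10.0, "female", PLANTED_LMS) == pytest.approx(0.0)

    def test_adults_use_age_twenty_row(self):
        z35 = bmi_zscore(25.0, 35.0, "male", PLANTED_LMS)
        z20 = bmi_zscore(25.0, 20.0, "male", PLANTED_LMS)
        assert z35 == pytest.approx(z20)

    def test_l_equal_one_reduces_to_relative_deviation(self):
        # with L=1 the LMS transform is (bmi/M - 1)/S
        z = bmi_zscore(18.7, 10.0, "female", PLANTED_LMS)
        assert z == pytest.approx((18.7 / 17.0 - 1.0) / 0.1)

    def test_age_below_support_raises(self):
        with pytest.raises(AgeRangeError):
            bmi_zscore(16.0, 2.0, "female", PLANTED_LMS)

    def test_packaged_table_round_trip(self, lms):
        z = bmi_zscore(18.0, 10.0, "female", lms)
        assert np.isfinite(z)


class TestScoreRegistry:
    def test_zero_coefficients_give_zero(self):
        reg = ScoreRegistry(
            {"null": {"terms": [{"input": "age", "coef": 0.0}, {"input": "bmi", "coef": 0.0}]}}
        )
        assert compute_score("null", make_participant(), reg) == 0.0

    def test_toy_linear_combination(self):
        reg = ScoreRegistry(
            {"toy": {"terms": [{"input": "age", "coef": 2.0}, {"input": "bmi", "coef": 3.0}]}}
        )
        p = make_participant(age=1.0, bmi=1.0)
        assert compute_score("toy", p, reg) == pytest.approx(5.0)

    def test_index60_matches_hand_arithmetic(self, registry):
        # independent evaluation of the published formula on a planted input
        p = make_participant(
            glucose=(4.8, 8.0, 10.0, 9.0, 8.0), cpeptide=(2.0, 4.0, 5.0, 4.8, 4.2)
        )
        expected = 0.3695 * np.log(2.0) + 0.0165 * (10.0 * 18.016) - 0.3644 * 5.0
        assert compute_score("index60", p, registry) == pytest.approx(expected)

    def test_missing_input_names_the_field(self):
        reg = ScoreRegistry({"s": {"terms": [{"input": "unobtainium", "coef": 1.0}]}})
        with pytest.raises(MissingInputError, match="unobtainium"):
            compute_score("s", make_participant(), reg)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(-3, 3))
    def test_score_is_additive_in_coefficients(self, c1, c2, scale):
        p = make_participant()

        def score(coefs):
            reg = ScoreRegistry(
                {"s": {"terms": [{"input": "age", "coef": coefs[0]}, {"input": "hba1c", "coef": coefs[1]}]}}
            )
            return compute_score("s", p, reg)

        combined = score((c1 + scale * c2, 0.0))
        assert combined == pytest.approx(score((c1, 0.0)) + scale * score((c2, 0.0)), rel=1e-9, abs=1e-9)


class TestFeatureVector:
    def test_log_age_at_one_year_is_zero(self, registry, lms):
        vec = build_feature_vector(make_participant(age=1.0), registry, lms)
        assert vec["log_age"] == pytest.approx(0.0)

    def test_ab_combination_level_and_flag(self, registry, lms):
        vec = build_feature_vector(
            make_participant(abs_=("GADA", "IA2A")), registry, lms
        )
        assert vec["ab_combination"] == "GADA+IA2A"
        assert vec["ia2a_flag"] == 1.0

    def test_full_vector_matches_field_by_field_hand_computation(self, registry, lms):
        p = make_participant(
            age=12.0,
            gender="male",
            bmi=19.0,
            grs2=13.1,
            abs_=("GADA", "IAA", "IA2A"),
            glucose=(5.0, 7.5, 8.0, 7.0, 6.0),
            cpeptide=(1.8, 3.6, 4.8, 4.4, 3.9),
            hba1c=36.0,
        )
        vec = build_feature_vector(p, registry, lms)
        minutes = np.array([0, 30, 60, 90, 120], dtype=float)
        assert vec["age"] == 12.0
        assert vec["log_age"] == pytest.approx(np.log(12.0))
        assert vec["gender"] == 0.0
        assert vec["grs2"] == 13.1
        assert vec["fasting_cpeptide"] == 1.8
        assert vec["auc_glucose"] == pytest.approx(
            np.trapezoid([5.0, 7.5, 8.0, 7.0, 6.0], minutes) / 120.0
        )
        assert vec["auc_cpeptide"] == pytest.approx(
            np.trapezoid([1.8, 3.6, 4.8, 4.4, 3.9], minutes) / 120.0
        )
        assert vec["hba1c"] == 36.0
        assert vec["ab_combination"] == "GADA+IAA+IA2A"
        assert vec["index60"] == pytest.approx(
            0.3695 * np.log(1.8) + 0.0165 * 8.0 * 18.016 - 0.3644 * 4.8
        )


def test_flow_summary_reproduces_published_counts():
    flow = load_study_flow()
    out = flow_summary(flow)
    assert out["eligible_n"] == 4377 - 355 - 55
    assert out["pct_progressed"] == pytest.approx(100.0 * 1311 / 3967)
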