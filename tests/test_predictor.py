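import json
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvcost.model_spec import (
    AnnualEventState,
    CancerDuration,
    CohortStratum,
    CovariateProfile,
    DiabetesDuration,
    EventDuration,
    Service,
    Sex,
    Smoking,
    default_fixture_path,
    reference_profile,
    reference_state,
)
from cvcost.predictor import (
    DesignRow,
    annual_states,
    duration_category,
    encode_design_row,
    extract_features,
    predict_hospital_cost,
    predict_primary_cost,
    predict_trajectory,
    term_value,
)
from cvcost.simulator import sample_baseline

W, C = CohortStratum.WITHOUT_CVD, CohortStratum.WITH_CVD


class TestDurationCategory:
    @pytest.mark.parametrize("first,now,want", [
        (3, 3, EventDuration.SAME_YEAR),
        (3, 4, EventDuration.ONE_YEAR_AGO),
        (3, 5, EventDuration.TWO_YEARS_AGO),
        (0, 7, EventDuration.THREE_PLUS_YEARS_AGO),
        (None, 5, EventDuration.NONE),
    ])
    def test_five_level_scheme(self, first, now, want):
        assert duration_category(first, now, "mi") == want
        assert duration_category(first, now, "stroke") == want
        assert duration_category(first, now, "crv") == want

    def test_diabetes_scheme(self):
        assert duration_category(0, 0, "diabetes") == DiabetesDuration.LT10Y
        assert duration_category(0, 9, "diabetes") == DiabetesDuration.LT10Y
        assert duration_category(0, 10, "diabetes") == DiabetesDuration.GE10Y

    def test_cancer_scheme(self):
        got = [duration_category(0, y, "cancer") for y in
               (0, 1, 2, 3, 4, 5, 9, 10, 25)]
        assert got == [
            CancerDuration.SAME_YEAR, CancerDuration.ONE_YEAR_AGO,
            CancerDuration.TWO_YEARS_AGO, CancerDuration.THREE_YEARS_AGO,
            CancerDuration.FOUR_YEARS_AGO,
            CancerDuration.FIVE_TO_TEN_YEARS_AGO,
            CancerDuration.FIVE_TO_TEN_YEARS_AGO,
            CancerDuration.GE10Y, CancerDuration.GE10Y]

    def test_future_event_rejected(self):
        with pytest.raises(ValueError):
            duration_category(5, 3, "mi")

    @given(first=st.integers(0, 30), later=st.integers(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_progression(self, first, later):
        # category index never decreases as years advance
        order = list(EventDuration)
        if later < first:
            return
        cats = [order.index(duration_category(first, y, "mi"))
                for y in range(first, first + 5)]
        assert cats == sorted(cats)


class TestEncodeDesignRow:
    def test_reference_row_all_zero(self, models, ref_without):
        profile, state = ref_without
        for service in Service:
            row = encode_design_row(profile, state, models[(W, service)])
            for name, v in row.values.items():
                if name == "intercept":
                    assert v == 1.0
                else:
                    assert v == 0.0, name

    def test_ln_hdl_unit_is_zero(self, models, ref_without):
        profile, state = ref_without
        assert profile.hdl_mmol_per_l == 1.0
        row = encode_design_row(profile, state, models[(W, Service.PRIMARY)])
        assert row["ln_hdl"] == 0.0

    def test_male_age_70(self, models, ref_without):
        profile, state = ref_without
        profile = replace(profile, sex=Sex.MALE)
        state = replace(state, current_age_years=70.0)
        row = encode_design_row(profile, state, models[(W, Service.PRIMARY)])
        assert row["sex:male"] == 1.0
        assert row["age"] == pytest.approx(1.0)

    def test_interaction_is_product(self, models, ref_without):
        profile, state = ref_without
        m = models[(W, Service.PRIMARY)]
        s_mi = replace(state, mi_duration=EventDuration.TWO_YEARS_AGO)
        row = encode_design_row(profile, s_mi, m)
        assert row["mi_any_x_crv_same_year"] == 0.0
        s_both = replace(s_mi, crv_duration=EventDuration.SAME_YEAR)
        row = encode_design_row(profile, s_both, m)
        assert row["mi_any_x_crv_same_year"] == 1.0
        assert row["mi:any"] * row["crv:same_year"] == 1.0


class TestPredictPrimary:
    def test_reference_without_cvd(self, models, ref_without):
        profile, state = ref_without
        m = models[(W, Service.PRIMARY)]
        cost, flags = predict_primary_cost(
            encode_design_row(profile, state, m), m)
        assert cost == 262.0
        assert flags == ()

    def test_reference_plus_male(self, models, ref_without):
        profile, state = ref_without
        m = models[(W, Service.PRIMARY)]
        cost, _ = predict_primary_cost(
            encode_design_row(replace(profile, sex=Sex.MALE), state, m), m)
        assert cost == 262.0 - 51.0

    def test_reference_with_cvd(self, models, ref_with):
        profile, state = ref_with
        m = models[(C, Service.PRIMARY)]
        cost, _ = predict_primary_cost(
            encode_design_row(profile, state, m), m)
        assert cost == 302.0

    def test_negative_floored(self, models):
        m = models[(W, Service.PRIMARY)]
        # implausible profile engineered to push the linear predictor < 0
        profile = CovariateProfile(sex=Sex.MALE, ldl_mmol_per_l=9.0,
                                   hdl_mmol_per_l=5.0)
        state = replace(reference_state(), current_age_years=40.0,
                        vd_this_year=True)
        cost, flags = predict_primary_cost(
            encode_design_row(profile, state, m), m)
        assert cost == 0.0
        assert "negative_linear_predictor_floored" in flags


class TestPredictHospital:
    def _predict(self, models, stratum, profile, state):
        p1 = models[(stratum, Service.HOSPITAL_PART1)]
        p2 = models[(stratum, Service.HOSPITAL_PART2)]
        feats = extract_features(profile, state)
        r1 = DesignRow({t.name: term_value(t, feats) for t in p1.terms})
        r2 = DesignRow({t.name: term_value(t, feats) for t in p2.terms})
        return predict_hospital_cost(r1, r2, p1, p2, features=feats)

    def test_reference_without_cvd(self, models, ref_without):
        pred = self._predict(models, W, *ref_without)
        assert pred.hospital_probability == pytest.approx(0.13 / 1.13)
        assert pred.hospital_conditional_gbp == 2102.0
        assert pred.hospital_gbp == pytest.approx(0.13 / 1.13 * 2102.0)
        # printed value (244) derives from unrounded coefficients: within 2%
        assert abs(pred.hospital_gbp - 244.0) / 244.0 < 0.02

    def test_reference_with_cvd(self, models, ref_with):
        pred = self._predict(models, C, *ref_with)
        assert pred.hospital_gbp == pytest.approx(0.19 / 1.19 * 2326.0)
        assert abs(pred.hospital_gbp - 376.0) / 376.0 < 0.02

    def test_crv_certainty_rule(self, models, ref_without):
        profile, state = ref_without
        state = replace(state, crv_duration=EventDuration.SAME_YEAR)
        pred = self._predict(models, W, profile, state)
        assert pred.hospital_probability == 1.0
        assert pred.hospital_gbp == pred.hospital_conditional_gbp
        assert "crv_certainty_rule_applied" in pred.flags

    def test_identity_total(self, models, random_population):
        for profile, state in random_population[:20]:
            pred = self._predict(models, W, profile, state)
            assert pred.hospital_gbp == pred.hospital_probability * \
                pred.hospital_conditional_gbp

    def test_two_part_bound(self, models, random_population):
        for profile, state in random_population[:20]:
            pred = self._predict(models, W, profile, state)
            assert 0.0 <= pred.hospital_gbp <= pred.hospital_conditional_gbp

    def test_monotone_odds(self, models, ref_without):
        profile, state = ref_without
        base = self._predict(models, W, profile, state)
        smoker = self._predict(models, W,
                               replace(profile, smoking=Smoking.CURRENT),
                               state)
        assert smoker.hospital_probability > base.hospital_probability


class TestLinearity:
    def test_primary_excess_profile_invariant(self, models,
                                              random_population):
        m = models[(W, Service.PRIMARY)]
        diffs = []
        for profile, state in random_population[:30]:
            on = replace(state, mi_duration=EventDuration.SAME_YEAR)
            lp_on, _ = predict_primary_cost(
                encode_design_row(profile, on, m), m)
            lp_off, _ = predict_primary_cost(
                encode_design_row(profile, state, m), m)
            diffs.append(lp_on - lp_off)
        assert np.ptp(diffs) < 1e-9
        assert diffs[0] == pytest.approx(194.0)


class TestOracleEquivalence:
    """Predictions agree with a brute-force evaluator that works straight
    off the raw fixture JSON, bypassing the design-row machinery."""

    @staticmethod
    def _flatten(profile, state):
        yn = lambda b: "yes" if b else "no"
        return {
            "sex": profile.sex.value, "ethnicity": profile.ethnicity.value,
            "townsend_quintile": profile.townsend_quintile.value,
            "smoking": profile.smoking.value,
            "physical_activity": profile.physical_activity.value,
            "diet": profile.diet.value,
            "bmi_category": profile.bmi_category.value,
            "ldl_mmol_per_l": profile.ldl_mmol_per_l,
            "hdl_mmol_per_l": profile.hdl_mmol_per_l,
            "creatinine_umol_per_l": profile.creatinine_umol_per_l,
            "sbp_mmhg": profile.sbp_mmhg, "dbp_mmhg": profile.dbp_mmhg,
            "on_antihypertensive": yn(profile.on_antihypertensive),
            "severe_mental_illness": yn(profile.severe_mental_illness),
            "prior_type1_diabetes": yn(profile.prior_type1_diabetes),
            "prior_cvd_category": profile.prior_cvd_category.value,
            "current_age_years": state.current_age_years,
            "mi_duration": state.mi_duration.value,
            "stroke_duration": state.stroke_duration.value,
            "crv_duration": state.crv_duration.value,
            "diabetes_duration": state.diabetes_duration.value,
            "cancer_duration": state.cancer_duration.value,
            "vd_this_year": yn(state.vd_this_year),
            "nvd_this_year": yn(state.nvd_this_year),
            "observed_fraction": state.observed_fraction,
        }

    @classmethod
    def _oracle_lp(cls, raw_model, feats):
        resolved = []
        total = 0.0
        for t in raw_model["terms"]:
            if raw_model["scale"] == "log_odds":
                if t["kind"] == "intercept":
                    coef = math.log(t["odds"])
                elif t.get("merged_with_preceding"):
                    coef = resolved[-1]
                else:
                    coef = math.log(t["odds_ratio"])
            elif t.get("merged_with_preceding"):
                coef = resolved[-1]
            else:
                coef = t["coefficient"]
            resolved.append(coef)
            if t["kind"] == "intercept":
                x = 1.0
            elif t["kind"] == "categorical_level":
                x = 1.0 if feats[t["field"]] in t["levels"] else 0.0
            elif t["kind"] == "continuous":
                tr = t["transform"]
                v = feats[t["field"]]
                if tr["type"] == "linear":
                    x = (v - tr["center"]) / tr["scale"]
                elif tr["type"] == "log":
                    x = math.log(v)
                else:
                    x = (math.log(v) - tr["center"]) / tr["scale"]
            else:
                x = 1.0
                for comp in t["components"]:
                    x *= (1.0 if feats[comp["field"]] in comp["levels"]
                          else 0.0)
            total += coef * x
        return total

    def test_thousand_random_profiles(self, models, raw_fixture):
        rng = np.random.default_rng(2024)
        profiles = sample_baseline(1000, W, seed=7)
        durations = list(EventDuration)
        raw_by_key = {(m["stratum"], m["service"]): m
                      for m in raw_fixture["models"]}
        for i, profile in enumerate(profiles):
            state = AnnualEventState(
                year_index=0,
                current_age_years=profile.age_at_entry_years,
                mi_duration=durations[rng.integers(0, 5)],
                stroke_duration=durations[rng.integers(0, 5)],
                crv_duration=durations[rng.integers(0, 5)],
                vd_this_year=bool(rng.random() < 0.05),
            )
            feats = self._flatten(profile, state)
            for service in ("primary", "hospital_part1", "hospital_part2"):
                model = models[(W, Service(service))]
                row = encode_design_row(profile, state, model)
                lp = sum(t.coefficient * row.values[t.name]
                         for t in model.terms)
                oracle = self._oracle_lp(raw_by_key[("without_cvd",
                                                     service)], feats)
                assert lp == pytest.approx(oracle, abs=1e-9), (i, service)


class TestTrajectory:
    def test_mi_excess_constant_from_event(self, models, ref_without):
        profile, _ = ref_without
        with_mi = predict_trajectory(profile, {"mi": 2}, 5, models, W)
        without = predict_trajectory(profile, {}, 5, models, W)
        excess = [a.primary_gbp - b.primary_gbp
                  for a, b in zip(with_mi, without)]
        assert excess[:2] == [0.0, 0.0]
        assert excess[2:] == pytest.approx([194.0] * 3)

    def test_no_events_probability_drifts_with_age_only(self, models,
                                                        ref_without):
        profile, _ = ref_without
        preds = predict_trajectory(profile, {}, 4, models, W)
        probs = [p.hospital_probability for p in preds]
        assert probs == sorted(probs)  # age OR > 1

    def test_death_truncates(self, models, ref_without):
        profile, _ = ref_without
        preds = predict_trajectory(profile, {"vd": 1}, 5, models, W)
        assert len(preds) == 2

    def test_event_after_death_rejected(self, models, ref_without):
        profile, _ = ref_without
        with pytest.raises(ValueError, match="death"):
            predict_trajectory(profile, {"vd": 1, "mi": 3}, 5, models, W)

    def test_prior_diabetes_crosses_threshold(self, models):
        profile = CovariateProfile(
            prior_type2_diabetes=True,
            years_since_diabetes_diagnosis_at_entry=8.0)
        states = annual_states(profile, {}, 4)
        assert [s.diabetes_duration.value for s in states] == \
            ["lt10y", "lt10y", "ge10y", "ge10y"]
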