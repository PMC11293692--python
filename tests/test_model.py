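"""Smart Triage risk engine: spec validation, scoring, threshold mapping,
trigger merge, and recalibration-in-the-large."""

from __future__ import annotations

import math

import numpy as np
import pytest

from triagekit import (
    ModelSpec,
    ModelSpecError,
    TriageCategory,
    TriggerResult,
    admission_probability,
    classify_by_risk,
    cohort_linear_predictors,
    combine_with_triggers,
    default_model_spec,
    linear_predictor,
    load_model_spec,
    recalibrate_in_the_large,
    recalibrate_model,
    triage_cohort,
)

from conftest import make_record, zero_coefficients


def model_with(coeffs=None, intercept=0.0, low=0.08, high=0.40, **kw) -> ModelSpec:
    c = zero_coefficients()
    c.update(coeffs or {})
    return ModelSpec(
        intercept=intercept, coefficients=c, low_threshold=low, high_threshold=high, **kw
    )


class TestModelSpec:
    def test_requires_exactly_nine_predictors(self):
        c = zero_coefficients()
        c.pop("pallor")
        with pytest.raises(ModelSpecError, match="missing predictor"):
            ModelSpec(intercept=0, coefficients=c, low_threshold=0.1, high_threshold=0.4)
        c = zero_coefficients()
        c["weight_kg"] = 1.0
        with pytest.raises(ModelSpecError, match="unknown predictor"):
            ModelSpec(intercept=0, coefficients=c, low_threshold=0.1, high_threshold=0.4)

    @pytest.mark.parametrize("low,high", [(0.4, 0.08), (0.0, 0.4), (0.08, 1.0), (0.2, 0.2)])
    def test_threshold_order_enforced(self, low, high):
        with pytest.raises(ModelSpecError, match="thresholds"):
            model_with(low=low, high=high)

    def test_yaml_loading_strict_schema(self, tmp_path):
        path = tmp_path / "m.yaml"
        path.write_text(
            "intercept: -2.0\n"
            "coefficients:\n"
            + "".join(f"  {k}: 0.0\n" for k in zero_coefficients())
            + "low_threshold: 0.08\nhigh_threshold: 0.4\nbogus_key: 1\n"
        )
        with pytest.raises(ModelSpecError, match="unknown key"):
            load_model_spec(path)

    def test_packaged_placeholder_loads(self):
        spec = default_model_spec()
        assert spec.low_threshold == 0.08 and spec.high_threshold == 0.40
        assert set(spec.coefficients) == set(zero_coefficients())


class TestLinearPredictor:
    def test_intercept_only(self):
        m = model_with(intercept=-2.0)
        assert linear_predictor(make_record(), m) == -2.0

    def test_single_categorical_term(self):
        m = model_with({"pallor": 1.5})
        assert linear_predictor(make_record(pallor=True), m) == 1.5
        assert linear_predictor(make_record(pallor=False), m) == 0.0

    def test_identity_spo2_term(self):
        m = model_with({"spo2_transformed": -0.1})
        assert linear_predictor(make_record(spo2_percent=90.0), m) == pytest.approx(-9.0)

    def test_affine_spo2_transform(self):
        m = model_with(
            {"spo2_transformed": 1.0},
            spo2_transform_name="affine",
            spo2_transform_params={"offset": 100.0, "scale": -1.0},
        )
        # transform maps saturation to deficit: 100 - x
        assert linear_predictor(make_record(spo2_percent=92.0), m) == pytest.approx(8.0)

    def test_missing_predictor_named_in_error(self):
        m = model_with()
        rec = make_record(muac_mm=float("nan"))
        with pytest.raises(ValueError, match="muac_mm"):
            linear_predictor(rec, m)


class TestProbabilityAndThresholds:
    def test_logistic_symmetry_and_inverse(self):
        m = model_with()
        assert admission_probability(make_record(), m) == pytest.approx(0.5)
        m8 = model_with(intercept=math.log(0.08 / 0.92))
        assert admission_probability(make_record(), m8) == pytest.approx(0.08)

    def test_extreme_linear_predictor_limits(self):
        lo = model_with(intercept=-800.0)
        hi = model_with(intercept=800.0)
        assert admission_probability(make_record(), lo) == pytest.approx(0.0)
        assert admission_probability(make_record(), hi) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "prob,low,high,expected",
        [
            (0.05, 0.08, 0.40, TriageCategory.NON_URGENT),
            (0.10, 0.026, 0.13, TriageCategory.PRIORITY),
            (0.40, 0.08, 0.40, TriageCategory.EMERGENCY),  # inclusive high boundary
            (0.08, 0.08, 0.40, TriageCategory.PRIORITY),  # inclusive low boundary
            (0.0799, 0.08, 0.40, TriageCategory.NON_URGENT),
            (0.9, 0.026, 0.13, TriageCategory.EMERGENCY),
        ],
    )
    def test_dual_threshold_mapping(self, prob, low, high, expected):
        assert classify_by_risk(prob, model_with(low=low, high=high)) == expected

    def test_monotone_in_risk(self):
        m = model_with()
        cats = [classify_by_risk(p, m) for p in np.linspace(0, 1, 101)]
        assert cats == sorted(cats)


class TestCombineWithTriggers:
    E = frozenset({"shock"})
    P = frozenset({"burn"})
    empty = frozenset()

    def test_emergency_trigger_forces_emergency(self):
        t = TriggerResult(self.E, self.empty)
        assert combine_with_triggers(TriageCategory.NON_URGENT, t) == TriageCategory.EMERGENCY

    def test_priority_trigger_raises_non_urgent(self):
        t = TriggerResult(self.empty, self.P)
        assert combine_with_triggers(TriageCategory.NON_URGENT, t) == TriageCategory.PRIORITY

    def test_never_demotes(self):
        for t in [
            TriggerResult(self.empty, self.empty),
            TriggerResult(self.empty, self.P),
            TriggerResult(self.E, self.P),
        ]:
            for cat in TriageCategory:
                assert combine_with_triggers(cat, t) >= cat


class TestRecalibration:
    def test_closed_form_equal_linear_predictors(self):
        # lp all zero, prevalence 1/4 -> delta = logit(0.25)
        lp = np.zeros(8)
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0], dtype=bool)
        delta = recalibrate_in_the_large(lp, y)
        assert delta == pytest.approx(math.log(0.25 / 0.75), abs=1e-8)

    def test_score_equation_holds_at_optimum(self):
        rng = np.random.default_rng(11)
        lp = rng.normal(-2, 1, size=5000)
        y = rng.random(5000) < 1 / (1 + np.exp(-(lp - 0.7)))
        delta = recalibrate_in_the_large(lp, y)
        p = 1 / (1 + np.exp(-(lp + delta)))
        assert abs(p.mean() - y.mean()) < 1e-8

    def test_self_consistency_null_shift(self):
        rng = np.random.default_rng(5)
        lp = rng.normal(-2, 1, size=50_000)
        y = rng.random(lp.size) < 1 / (1 + np.exp(-lp))
        delta = recalibrate_in_the_large(lp, y)
        assert abs(delta) < 0.05

    @pytest.mark.parametrize("true_delta", [-1.0, 0.5])
    def test_parameter_recovery(self, true_delta):
        rng = np.random.default_rng(42)
        lp = rng.normal(-2, 1, size=50_000)
        y = rng.random(lp.size) < 1 / (1 + np.exp(-(lp + true_delta)))
        delta = recalibrate_in_the_large(lp, y)
        assert delta == pytest.approx(true_delta, abs=0.05)

    def test_agrees_with_statsmodels_offset_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        lp = rng.normal(-1.5, 0.8, size=2000)
        y = (rng.random(lp.size) < 1 / (1 + np.exp(-(lp - 0.4)))).astype(float)
        delta = recalibrate_in_the_large(lp, y)
        fit = sm.GLM(
            y, np.ones((lp.size, 1)), family=sm.families.Binomial(), offset=lp
        ).fit()
        assert delta == pytest.approx(fit.params[0], abs=1e-6)

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            recalibrate_in_the_large(np.zeros(10), np.ones(10, dtype=bool))
        with pytest.raises(ValueError, match="degenerate"):
            recalibrate_in_the_large(np.zeros(10), np.zeros(10, dtype=bool))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recalibrate_in_the_large(np.zeros(3), np.array([True, False]))

    def test_rank_order_preserved_under_recalibration(self):
        """Only the intercept moves, so patient probability ranks are
        identical between original and recalibrated models."""
        records = [
            make_record(patient_id=str(i), temperature_c=36 + i * 0.5, admitted=i % 3 == 0)
            for i in range(12)
        ]
        m = default_model_spec()
        m_recal = recalibrate_model(records, m)
        lp0 = cohort_linear_predictors(records, m)
        lp1 = cohort_linear_predictors(records, m_recal)
        assert np.array_equal(np.argsort(lp0), np.argsort(lp1))


class TestTriageCohort:
    def test_empty_cohort(self):
        m = default_model_spec()
        assert triage_cohort([], m, m) == []

    def test_trigger_overrides_low_model_probability(self):
        m = model_with(intercept=-5.0)  # prob ~ 0.7%
        rec = make_record(unresponsive=True)
        (a,) = triage_cohort([rec], m, m)
        assert a.st_model_only == TriageCategory.NON_URGENT
        assert a.st_with_triggers == TriageCategory.EMERGENCY
        assert a.st_recalibrated_with_triggers == TriageCategory.EMERGENCY

    def test_identical_records_get_identical_assignments(self):
        m = default_model_spec()
        recs = [make_record(patient_id="A"), make_record(patient_id="A")]
        a, b = triage_cohort(recs, m, m)
        assert a == b

    def test_with_triggers_never_below_model_only(self):
        rng = np.random.default_rng(3)
        m = default_model_spec()
        records = [
            make_record(
                patient_id=str(i),
                temperature_c=float(rng.uniform(35, 41)),
                spo2_percent=float(rng.uniform(85, 100)),
                irritable=bool(rng.random() < 0.3),
                chest_indrawing=bool(rng.random() < 0.2),
            )
            for i in range(200)
        ]
        for a in triage_cohort(records, m, m):
            assert a.st_with_triggers >= a.st_model_only
            if a.triggers.any_emergency:
                assert a.st_with_triggers == TriageCategory.EMERGENCY

    def test_error_carries_patient_context(self):
        m = model_with()
        bad = make_record(patient_id="P9", muac_mm=float("nan"))
        with pytest.raises(ValueError, match="P9"):
            triage_cohort([bad], m, m)
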