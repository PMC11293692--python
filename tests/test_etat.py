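"""ETAT rule engine: threshold strictness, rule composition, monotonicity,
and equivalence with an independent brute-force evaluation."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from triagekit import (
    EtatConfig,
    TriageCategory,
    classify_etat,
    etat_emergency_signs,
    etat_priority_signs,
    fast_breathing,
)

from conftest import make_record


class TestFastBreathing:
    @pytest.mark.parametrize(
        "age,rr,expected",
        [
            (1.0, 61, True),  # <2 mo band: RR > 60
            (1.0, 60, False),  # strict
            (2.0, 51, True),  # 2-11 mo band: RR > 50
            (10.0, 50, False),  # strict boundary
            (11.99, 51, True),
            (12.0, 41, True),  # >=12 mo band: RR > 40
            (24.0, 41, True),
            (24.0, 40, False),
            (1.99, 55, False),  # still in the <2 mo band
        ],
    )
    def test_age_banded_thresholds(self, age, rr, expected):
        assert fast_breathing(age, rr) is expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fast_breathing(-1, 30)
        with pytest.raises(ValueError):
            fast_breathing(12, 0)


class TestEmergencySigns:
    def test_well_child_fires_nothing(self, well_child):
        assert etat_emergency_signs(well_child) == set()

    def test_low_spo2_is_severe_respiratory_distress(self):
        fired = etat_emergency_signs(make_record(spo2_percent=88.0))
        assert fired == {"severe respiratory distress"}

    def test_spo2_threshold_strict(self):
        assert etat_emergency_signs(make_record(spo2_percent=90.0)) == set()

    def test_dehydration_requires_diarrhoea_plus_two(self):
        fired = etat_emergency_signs(
            make_record(diarrhoea=True, sunken_eyes=True, slow_skin_pinch=True)
        )
        assert fired == {"severe dehydration"}
        # one sub-sign is not enough
        assert (
            etat_emergency_signs(make_record(diarrhoea=True, sunken_eyes=True)) == set()
        )
        # two sub-signs without diarrhoea do not fire
        assert (
            etat_emergency_signs(make_record(sunken_eyes=True, slow_skin_pinch=True))
            == set()
        )

    @pytest.mark.parametrize(
        "signs,fires",
        [
            # circulation = refill>3s AND (weak central OR weak radial) AND cool skin
            (dict(capillary_refill_gt3s=True, weak_radial_pulse=True), False),
            (
                dict(capillary_refill_gt3s=True, weak_radial_pulse=True, cool_skin=True),
                True,
            ),
            (
                dict(
                    capillary_refill_gt3s=True, weak_central_pulse=True, cool_skin=True
                ),
                True,
            ),
            (dict(weak_central_pulse=True, cool_skin=True), False),
        ],
    )
    def test_circulation_conjunction(self, signs, fires):
        fired = etat_emergency_signs(make_record(**signs))
        assert ("circulation" in fired) is fires

    def test_obstructed_breathing_excluded_by_default(self):
        rec = make_record(obstructed_breathing=True, not_breathing=True)
        assert etat_emergency_signs(rec) == set()
        enabled = EtatConfig(include_obstructed_breathing=True)
        assert etat_emergency_signs(rec, enabled) == {"obstructed or absent breathing"}


class TestPrioritySigns:
    def test_tiny_infant_fractional_months(self):
        assert "tiny infant" in etat_priority_signs(make_record(age_months=1.5))
        assert "tiny infant" not in etat_priority_signs(make_record(age_months=2.0))

    def test_fever_threshold_inclusive(self):
        assert "fever" in etat_priority_signs(make_record(temperature_c=37.5))
        assert "fever" not in etat_priority_signs(make_record(temperature_c=37.49))

    def test_no_fast_breathing_no_indrawing(self):
        rec = make_record(age_months=36, respiratory_rate_bpm=39)
        assert etat_priority_signs(rec) == set()

    def test_respiratory_distress_via_either_route(self):
        assert "respiratory distress" in etat_priority_signs(
            make_record(chest_indrawing=True)
        )
        assert "respiratory distress" in etat_priority_signs(
            make_record(age_months=24, respiratory_rate_bpm=41)
        )


class TestClassify:
    def test_emergency_precedence_over_priority(self):
        res = classify_etat(make_record(spo2_percent=88.0, temperature_c=38.5))
        assert res.category == TriageCategory.EMERGENCY
        assert "fever" in res.priority_signs  # still recorded in the audit trail

    def test_priority_only(self):
        res = classify_etat(make_record(temperature_c=38.5))
        assert res.category == TriageCategory.PRIORITY

    def test_no_signs_is_non_urgent(self, well_child):
        res = classify_etat(well_child)
        assert res.category == TriageCategory.NON_URGENT
        assert not res.emergency_signs and not res.priority_signs

    def test_category_matches_fired_sets(self, well_child):
        # partition invariant: category is determined by the fired sets
        for rec in [
            well_child,
            make_record(pallor=True),
            make_record(cyanosis=True),
            make_record(diarrhoea=True, sunken_eyes=True, cannot_sit_or_drink=True),
        ]:
            res = classify_etat(rec)
            if res.emergency_signs:
                assert res.category == TriageCategory.EMERGENCY
            elif res.priority_signs:
                assert res.category == TriageCategory.PRIORITY
            else:
                assert res.category == TriageCategory.NON_URGENT


# Signs that can influence the ETAT category (vitals held normal).
_ETAT_SIGNS = [
    "cyanosis",
    "grunting",
    "stridor",
    "capillary_refill_gt3s",
    "weak_central_pulse",
    "weak_radial_pulse",
    "cool_skin",
    "convulsions_now",
    "not_alert_avpu",
    "diarrhoea",
    "sunken_eyes",
    "cannot_sit_or_drink",
    "slow_skin_pinch",
    "trauma",
    "pallor",
    "severe_pain",
    "poisoning",
    "chest_indrawing",
    "urgent_referral",
    "irritable",
    "visible_severe_wasting",
    "oedema",
    "burns",
]


def brute_force_etat_category(rec) -> TriageCategory:
    """Independent re-statement of the ETAT mapping, written directly from
    the guideline table, deliberately without reusing the engine's helpers."""
    emergency = (
        rec.sign("cyanosis")
        or rec.spo2_percent < 90
        or rec.sign("grunting")
        or rec.sign("stridor")
        or (
            rec.sign("capillary_refill_gt3s")
            and (rec.sign("weak_central_pulse") or rec.sign("weak_radial_pulse"))
            and rec.sign("cool_skin")
        )
        or rec.sign("convulsions_now")
        or rec.sign("not_alert_avpu")
        or (
            rec.sign("diarrhoea")
            and (
                rec.sign("sunken_eyes")
                + rec.sign("cannot_sit_or_drink")
                + rec.sign("slow_skin_pinch")
            )
            >= 2
        )
    )
    if emergency:
        return TriageCategory.EMERGENCY
    age, rr = rec.age_months, rec.respiratory_rate_bpm
    fast = (
        (age < 2 and rr > 60) or (2 <= age < 12 and rr > 50) or (age >= 12 and rr > 40)
    )
    priority = (
        age < 2
        or rec.temperature_c >= 37.5
        or rec.sign("trauma")
        or rec.sign("pallor")
        or rec.sign("severe_pain")
        or rec.sign("poisoning")
        or rec.sign("chest_indrawing")
        or fast
        or rec.sign("urgent_referral")
        or rec.sign("irritable")
        or rec.sign("visible_severe_wasting")
        or rec.sign("oedema")
        or rec.sign("burns")
    )
    return TriageCategory.PRIORITY if priority else TriageCategory.NON_URGENT


def test_exhaustive_oracle_equivalence_on_sign_subset():
    """Engine and brute-force oracle agree on all 2^10 combinations of a
    ten-sign subset spanning every emergency composite."""
    subset = [
        "cyanosis",
        "grunting",
        "capillary_refill_gt3s",
        "weak_radial_pulse",
        "cool_skin",
        "diarrhoea",
        "sunken_eyes",
        "slow_skin_pinch",
        "pallor",
        "irritable",
    ]
    for values in itertools.product([False, True], repeat=len(subset)):
        rec = make_record(**dict(zip(subset, values)))
        assert classify_etat(rec).category == brute_force_etat_category(rec)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    flips=st_.dictionaries(st_.sampled_from(_ETAT_SIGNS), st_.booleans(), max_size=8),
    extra=st_.sampled_from(_ETAT_SIGNS),
)
def test_setting_one_sign_never_lowers_category(flips, extra):
    base = make_record(**flips)
    raised = make_record(**{**flips, extra: True})
    assert classify_etat(raised).category >= classify_etat(base).category
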