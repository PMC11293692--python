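"""WHO Emergency Triage Assessment and Treatment (ETAT) rule engine.

ETAT assigns one of three acuity levels from bedside clinical signs using
the "ABCD" logic: Airway/Breathing, Circulation, Convulsions/Coma, and
severe Dehydration define the emergency block; a second block of signs
(fever, trauma, pallor, malnutrition, ...) defines priority; a child with
no sign from either block is non-urgent.

Threshold strictness follows the guideline wording literally: SpO2 < 90 %
is strict, temperature >= 37.5 °C is inclusive, and the age-banded fast
breathing cut-offs (respiratory rate > 60 / > 50 / > 40 per minute) are
strict.

The airway sign "obstructed/absent breathing" is excluded from the default
emergency block — the study dataset this engine mirrors did not collect
it — but can be re-enabled via ``EtatConfig(include_obstructed_breathing=
True)`` for non-replication use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import PatientRecord, TriageCategory

__all__ = [
    "EtatConfig",
    "EtatResult",
    "fast_breathing",
    "etat_emergency_signs",
    "etat_priority_signs",
    "classify_etat",
]


@dataclass(frozen=True)
class EtatConfig:
    """Tunable rule-engine conventions.

    include_obstructed_breathing
        Count obstructed/absent breathing as an emergency sign (off by
        default; see module docstring).
    """

    include_obstructed_breathing: bool = False
    fever_threshold_c: float = 37.5
    spo2_emergency_threshold: float = 90.0
    tiny_infant_age_months: float = 2.0


DEFAULT_ETAT_CONFIG = EtatConfig()


@dataclass(frozen=True)
class EtatResult:
    """ETAT classification with the audit trail of fired criteria."""

    category: TriageCategory
    emergency_signs: frozenset[str]
    priority_signs: frozenset[str]


def fast_breathing(age_months: float, rr: float) -> bool:
    """Age-banded fast-breathing criterion.

    Bands (months): [0, 2) -> RR > 60; [2, 12) -> RR > 50; [12, inf) ->
    RR > 40. All comparisons strict.
    """
    if age_months < 0:
        raise ValueError(f"age_months must be >= 0, got {age_months}")
    if rr <= 0:
        raise ValueError(f"respiratory rate must be > 0, got {rr}")
    if age_months < 2:
        return rr > 60
    if age_months < 12:
        return rr > 50
    return rr > 40


def etat_emergency_signs(
    p: PatientRecord, config: EtatConfig = DEFAULT_ETAT_CONFIG
) -> set[str]:
    """Return every firing emergency criterion label.

    Criteria: central cyanosis; severe respiratory distress (SpO2 below
    threshold OR cyanosis OR grunting OR stridor); circulation failure
    (capillary refill > 3 s AND a weak central or radial pulse AND cool
    skin); convulsions now; not alert on the AVPU scale; severe dehydration
    (diarrhoea plus at least two of sunken eyes / cannot sit or drink /
    slow skin pinch).
    """
    fired: set[str] = set()
    spo2 = p.spo2_percent
    if p.sign("cyanosis"):
        fired.add("cyanosis")
    if (
        (spo2 == spo2 and spo2 < config.spo2_emergency_threshold)
        or p.sign("cyanosis")
        or p.sign("grunting")
        or p.sign("stridor")
    ):
        fired.add("severe respiratory distress")
    if (
        p.sign("capillary_refill_gt3s")
        and (p.sign("weak_central_pulse") or p.sign("weak_radial_pulse"))
        and p.sign("cool_skin")
    ):
        fired.add("circulation")
    if p.sign("convulsions_now"):
        fired.add("convulsions")
    if p.sign("not_alert_avpu"):
        fired.add("not alert")
    dehydration_count = sum(
        p.sign(s) for s in ("sunken_eyes", "cannot_sit_or_drink", "slow_skin_pinch")
    )
    if p.sign("diarrhoea") and dehydration_count >= 2:
        fired.add("severe dehydration")
    if config.include_obstructed_breathing and (
        p.sign("obstructed_breathing") or p.sign("not_breathing")
    ):
        fired.add("obstructed or absent breathing")
    return fired


def etat_priority_signs(
    p: PatientRecord, config: EtatConfig = DEFAULT_ETAT_CONFIG
) -> set[str]:
    """Return every firing priority criterion label."""
    fired: set[str] = set()
    if p.age_months < config.tiny_infant_age_months:
        fired.add("tiny infant")
    t = p.temperature_c
    if t == t and t >= config.fever_threshold_c:
        fired.add("fever")
    if p.sign("trauma"):
        fired.add("trauma")
    if p.sign("pallor"):
        fired.add("pallor")
    if p.sign("severe_pain"):
        fired.add("severe pain")
    if p.sign("poisoning"):
        fired.add("poisoning")
    rr = p.respiratory_rate_bpm
    if p.sign("chest_indrawing") or (rr == rr and fast_breathing(p.age_months, rr)):
        fired.add("respiratory distress")
    if p.sign("urgent_referral"):
        fired.add("urgent referral")
    if p.sign("irritable"):
        fired.add("irritable")
    if p.sign("visible_severe_wasting"):
        fired.add("visible severe wasting")
    if p.sign("oedema"):
        fired.add("oedema")
    if p.sign("burns"):
        fired.add("burns")
    return fired


def classify_etat(
    p: PatientRecord, config: EtatConfig = DEFAULT_ETAT_CONFIG
) -> EtatResult:
    """Classify a record under ETAT; emergency takes precedence over priority."""
    emergency = etat_emergency_signs(p, config)
    priority = etat_priority_signs(p, config)
    if emergency:
        category = TriageCategory.EMERGENCY
    elif priority:
        category = TriageCategory.PRIORITY
    else:
        category = TriageCategory.NON_URGENT
    return EtatResult(
        category=category,
        emergency_signs=frozenset(emergency),
        priority_signs=frozenset(priority),
    )
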