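"""Smart Triage independent emergency and priority triggers.

Independent triggers are single clinical signs or vital-sign thresholds
that force a child directly into the emergency or priority category,
regardless of the model's predicted admission probability. They exist so
that rare but unmistakably critical presentations (unresponsiveness,
shock, apnoea, ...) are never down-triaged by a probability model that
saw few such cases in training.

All numeric comparisons are strict as stated by the trigger definitions
(HR < 45, SpO2 < 90, RR > 60, temperature > 40 or < 35, MUAC < 115 mm).

Note one deliberate asymmetry against the ETAT rules: the trigger-set
dehydration criterion (at least two of sunken eyes / slow skin pinch /
lethargy) does NOT require diarrhoea, whereas ETAT's severe-dehydration
rule does.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PatientRecord

__all__ = [
    "TriggerConfig",
    "TriggerResult",
    "emergency_triggers",
    "priority_triggers",
    "evaluate_triggers",
]


@dataclass(frozen=True)
class TriggerConfig:
    """Trigger-engine conventions.

    shock_requires_cool_skin
        The shock composite is printed as "Cool hands with Capillary
        refill > 3 sec or Weak and fast pulse". The default reading is
        cool skin AND (capillary refill > 3 s OR weak pulse). Setting this
        to False selects the alternative parse
        (cool skin AND capillary refill > 3 s) OR weak pulse.
    """

    shock_requires_cool_skin: bool = True
    low_heart_rate_bpm: float = 45.0
    low_spo2_percent: float = 90.0
    high_respiratory_rate_bpm: float = 60.0
    high_temperature_c: float = 40.0
    low_temperature_c: float = 35.0
    low_muac_mm: float = 115.0


DEFAULT_TRIGGER_CONFIG = TriggerConfig()


@dataclass(frozen=True)
class TriggerResult:
    """Fired independent triggers, by severity tier."""

    emergency_triggers: frozenset[str]
    priority_triggers: frozenset[str]

    @property
    def any_emergency(self) -> bool:
        return bool(self.emergency_triggers)

    @property
    def any_priority(self) -> bool:
        return bool(self.priority_triggers)


def _shock(p: PatientRecord, config: TriggerConfig) -> bool:
    weak_pulse = p.sign("weak_central_pulse") or p.sign("weak_radial_pulse")
    if config.shock_requires_cool_skin:
        return p.sign("cool_skin") and (p.sign("capillary_refill_gt3s") or weak_pulse)
    return (p.sign("cool_skin") and p.sign("capillary_refill_gt3s")) or weak_pulse


def emergency_triggers(
    p: PatientRecord, config: TriggerConfig = DEFAULT_TRIGGER_CONFIG
) -> set[str]:
    """Return every firing emergency trigger label."""
    fired: set[str] = set()
    if p.sign("unresponsive"):
        fired.add("unresponsive")
    if p.sign("convulsions_now"):
        fired.add("convulsion")
    if _shock(p, config):
        fired.add("shock")
    if p.sign("major_trauma"):
        fired.add("major trauma")
    if p.sign("severe_pain"):
        fired.add("severe pain")
    if p.sign("not_breathing"):
        fired.add("not breathing")
    if p.sign("obstructed_breathing"):
        fired.add("obstructed breathing")
    if p.sign("cyanosis"):
        fired.add("central cyanosis")
    if sum(p.sign(s) for s in ("sunken_eyes", "slow_skin_pinch", "lethargy")) >= 2:
        fired.add("dehydration")
    hr = p.heart_rate_bpm
    if hr == hr and hr < config.low_heart_rate_bpm:
        fired.add("low heart rate")
    spo2 = p.spo2_percent
    if spo2 == spo2 and spo2 < config.low_spo2_percent:
        fired.add("low oxygen saturation")
    return fired


def priority_triggers(
    p: PatientRecord, config: TriggerConfig = DEFAULT_TRIGGER_CONFIG
) -> set[str]:
    """Return every firing priority trigger label."""
    fired: set[str] = set()
    if p.sign("trauma"):
        fired.add("trauma")
    if p.sign("burns"):
        fired.add("burn")
    if p.sign("poisoning"):
        fired.add("poisoning")
    if p.sign("urgent_referral"):
        fired.add("urgent referral")
    if (
        p.sign("not_eating_drinking_respiratory")
        or p.sign("chest_indrawing")
        or p.sign("accessory_muscle_use")
        or p.sign("head_nodding")
    ):
        fired.add("difficulty breathing")
    if p.sign("irritable"):
        fired.add("irritable")
    rr = p.respiratory_rate_bpm
    if rr == rr and rr > config.high_respiratory_rate_bpm:
        fired.add("high respiratory rate")
    t = p.temperature_c
    if t == t and (t > config.high_temperature_c or t < config.low_temperature_c):
        fired.add("temperature extreme")
    muac = p.muac_mm
    if muac == muac and muac < config.low_muac_mm:
        fired.add("low MUAC")
    return fired


def evaluate_triggers(
    p: PatientRecord, config: TriggerConfig = DEFAULT_TRIGGER_CONFIG
) -> TriggerResult:
    """Evaluate both trigger tiers on one record."""
    return TriggerResult(
        emergency_triggers=frozenset(emergency_triggers(p, config)),
        priority_triggers=frozenset(priority_triggers(p, config)),
    )
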