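"""Score a child with the Smart Triage risk model and merge the
independent triggers.

Uses the packaged placeholder coefficients (structure-correct, not the
published clinical values). The model maps an admission probability to a
category via the 8% / 40% thresholds; independent triggers can only raise
the category, never lower it.
"""

from triagekit import (
    PatientRecord,
    admission_probability,
    classify_by_risk,
    combine_with_triggers,
    default_model_spec,
    evaluate_triggers,
)

model = default_model_spec()

# Moderately unwell child: model risk alone lands below the high threshold,
# but an unmistakable danger sign (unresponsiveness) trips an emergency
# trigger.
child = PatientRecord(
    patient_id="demo",
    age_months=18,
    temperature_c=38.2,
    heart_rate_bpm=145,
    respiratory_rate_bpm=45,
    spo2_percent=94,
    muac_mm=125,
    unresponsive=True,
)

prob = admission_probability(child, model)
model_cat = classify_by_risk(prob, model)
triggers = evaluate_triggers(child)
final_cat = combine_with_triggers(model_cat, triggers)

print(f"admission probability: {prob:.3f}")
print(f"model-only category:   {model_cat}")
print(f"fired emergency triggers: {sorted(triggers.emergency_triggers)}")
print(f"fired priority triggers:  {sorted(triggers.priority_triggers)}")
print(f"final category (model + triggers): {final_cat}")

# The probability alone would make this child priority or non-urgent, but
# the unresponsive trigger forces the emergency category — the safety net
# the trigger layer exists to provide.
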