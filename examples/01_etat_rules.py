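"""Classify children with the WHO ETAT sign-based rules.

Builds three presentations — a hypoxic infant, a febrile toddler, and a
well child — and prints the assigned acuity with the fired criteria.
"""

from triagekit import PatientRecord, classify_etat

children = [
    PatientRecord(
        patient_id="hypoxic-infant",
        age_months=5,
        temperature_c=37.0,
        heart_rate_bpm=150,
        respiratory_rate_bpm=62,
        spo2_percent=87,
        muac_mm=130,
        grunting=True,
    ),
    PatientRecord(
        patient_id="febrile-toddler",
        age_months=30,
        temperature_c=38.6,
        heart_rate_bpm=130,
        respiratory_rate_bpm=32,
        spo2_percent=98,
        muac_mm=150,
    ),
    PatientRecord(
        patient_id="well-child",
        age_months=48,
        temperature_c=36.9,
        heart_rate_bpm=100,
        respiratory_rate_bpm=24,
        spo2_percent=99,
        muac_mm=160,
    ),
]

for child in children:
    result = classify_etat(child)
    print(f"{child.patient_id}: {result.category}")
    if result.emergency_signs:
        print(f"  emergency signs: {sorted(result.emergency_signs)}")
    if result.priority_signs:
        print(f"  priority signs:  {sorted(result.priority_signs)}")

# The hypoxic infant is an emergency (SpO2 < 90% and grunting both count as
# severe respiratory distress; RR 62 > 50 would only be a priority sign).
# The febrile toddler is priority (temperature >= 37.5 C). The well child,
# with no sign fired, waits in the queue as non-urgent.
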