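# Placeholder Smart Triage model specification — NOT CLINICAL.
#
# The published model's nine coefficients and its oxygen-saturation
# transform are not reproduced here (they were published separately and
# are not packaged). These placeholder values have the correct structure
# and adverse directions (risk rises with temperature, heart rate and
# respiratory danger signs; falls with SpO2 and MUAC) and are used by the
# synthetic-cohort tests and examples only. Users holding the published
# coefficients should copy model_published_template.yaml and fill it in.
name: placeholder-original
notes: synthetic placeholder coefficients; not for clinical use
intercept: 3.6
coefficients:
  age_months: -0.010
  temperature_c: 0.25
  heart_rate_bpm: 0.010
  spo2_transformed: -0.15
  muac_mm: -0.020
  difficulty_breathing: 1.0
  pallor: 0.8
  oedema: 0.8
  parental_concern: 0.3
spo2_transform:
  name: identity
low_threshold: 0.08
high_threshold: 0.40
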