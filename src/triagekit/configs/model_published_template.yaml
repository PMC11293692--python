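# Template for the published Smart Triage model coefficients.
#
# Fill in the intercept, the nine coefficients and the oxygen-saturation
# transform from the original model publication, then pass this file via
# --model / load_model_spec(). The threshold pairs below are the
# published ones: original 8% / 40%; recalibrated 2.6% / 13%.
name: smart-triage-published
notes: REPLACE the null values with the published coefficients
intercept: null
coefficients:
  age_months: null
  temperature_c: null
  heart_rate_bpm: null
  spo2_transformed: null
  muac_mm: null
  difficulty_breathing: null
  pallor: null
  oedema: null
  parental_concern: null
spo2_transform:
  name: identity   # replace with the published transform
low_threshold: 0.08
high_threshold: 0.40
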