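# triagekit

Pediatric emergency-department triage systems, run and compared side by
side.

When a child arrives at a busy low-resource emergency department, triage
decides who is seen immediately and who can safely wait. `triagekit`
implements and evaluates two approaches to that decision:

* **ETAT** — the WHO Emergency Triage Assessment and Treatment
  guidelines: a checklist of clinical signs. Any *emergency* sign
  (central cyanosis, SpO2 < 90 %, circulation failure, convulsions,
  coma, severe dehydration, ...) means immediate treatment; any
  *priority* sign (fever ≥ 37.5 °C, tiny infant < 2 months, trauma,
  fast breathing, ...) means prompt assessment; a child with no sign is
  *non-urgent*.
* **Smart Triage** — a nine-predictor logistic regression for the
  probability of hospital admission
  (age, temperature, heart rate, transformed SpO2, MUAC, difficulty
  breathing, pallor, oedema, parental concern):

  p = logistic(β₀ + Σᵢ βᵢ xᵢ)

  mapped to a category by two risk thresholds (original 8 % / 40 %;
  recalibrated 2.6 % / 13 %), and combined by max severity with
  **independent triggers** — single signs or vital thresholds
  (unresponsive, HR < 45, SpO2 < 90, MUAC < 115 mm, ...) that force
  emergency or priority status regardless of the model.

The toolkit covers the full comparison workflow: record validation and
cohort CSV I/O, both rule engines, the dual-threshold classifier,
**recalibration-in-the-large** (refit the intercept δ so the mean
predicted probability equals the observed prevalence, leaving every
coefficient — and hence the patient risk ranking — unchanged),
reclassification (Sankey flow) tables, dichotomized 2×2 diagnostics
(sensitivity, specificity, PPV, NPV) with Wilson 95 % confidence
intervals, and a synthetic cohort generator driven by a latent severity
so that every stage is testable end to end. The aggregate count tables
of a published two-hospital Kenyan evaluation (5605 evaluable children,
395 admissions, 49 deaths) are packaged in `triagekit.study_counts`,
from which every published diagnostic statistic is recomputed.

The published model's clinical coefficients are not included; a
structure-correct, clearly-labelled placeholder spec ships for testing,
plus a template (`configs/model_published_template.yaml`) for users who
hold the published values.

## Worked example

Recompute the published admission diagnostics from the packaged counts
(`python examples/04_reproduce_published_diagnostics.py`):

```
=== Diagnostic tests for hospital admission ===
etat  (tp=191, fp=322, fn=204, tn=4888)
  sensitivity  48.4%  (95% CI 43.5% - 53.3%)
  specificity  93.8%  (95% CI 93.1% - 94.4%)
  ppv          37.2%  (95% CI 33.2% - 41.5%)
  npv          96.0%  (95% CI 95.4% - 96.5%)
st_with_triggers  (tp=296, fp=867, fn=99, tn=4343)
  sensitivity  74.9%  (95% CI 70.4% - 79.0%)
  specificity  83.4%  (95% CI 82.3% - 84.3%)
  ...
```

Reading: of 395 admitted children, the sign-based rules flagged 191
(48.4 %) as emergencies, while the risk model with triggers flagged 296
(74.9 %) — higher sensitivity bought with lower specificity (more
low-risk children in the emergency queue). The 2×2 cells come from
dichotomizing each system to high acuity (emergency) vs low acuity
(priority + non-urgent) among the 5605 outcome-known children.

Other examples in `examples/`: ETAT rule classification, risk scoring
with trigger merge, recalibration-in-the-large, and the full synthetic
simulate → triage → evaluate pipeline.

## Command line

```bash
triagekit simulate --n 10000 --seed 1 --out cohort.csv
triagekit triage   --cohort cohort.csv --out assignments.csv
triagekit evaluate --assignments assignments.csv --cohort cohort.csv --out results/
triagekit recalibrate --cohort cohort.csv --out model_recal.yaml
triagekit reproduce-tables --out tables/
```

`evaluate` writes per-system outcome tables, the combined diagnostics
CSV, pairwise transition tables and Sankey flow JSON. `triage`
recalibrates on the cohort automatically unless `--model-recal` supplies
an explicit spec.

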