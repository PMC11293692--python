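# Methods

## The triage systems

**Sign-based rules (ETAT).** A child is *emergency* if any emergency
criterion fires: central cyanosis; severe respiratory distress (SpO2
< 90 %, or cyanosis, grunting or stridor); circulation failure
(capillary refill > 3 s AND a weak central or radial pulse AND cool
skin); convulsions now; not alert on the AVPU scale; severe dehydration
(diarrhoea plus at least two of sunken eyes, cannot sit or drink, slow
skin pinch). Otherwise *priority* if any priority criterion fires: age
< 2 months (fractional months), temperature ≥ 37.5 °C, trauma, pallor,
severe pain, poisoning, respiratory distress (chest indrawing or
age-banded fast breathing: RR > 60 under 2 months, > 50 at 2–11 months,
> 40 from 12 months), urgent referral, irritability, visible severe
wasting, oedema, burns. Otherwise *non-urgent*. Threshold strictness is
as written: SpO2 and RR comparisons strict, fever inclusive.

The airway criterion "obstructed/absent breathing" is excluded from the
default emergency block because the evaluation dataset this engine
mirrors did not collect it; `EtatConfig(include_obstructed_breathing=
True)` re-enables it for other uses. The dehydration sub-signs counted
are the three available in that dataset mapping (sunken eyes, cannot
sit or drink, slow skin pinch), not the four of the generic guideline
text, and "not alert (AVPU)" is taken at face value as a single boolean.

**Risk model (Smart Triage).** A logistic regression on nine
predictors — age (months), temperature (°C), heart rate (/min),
transformed SpO2, MUAC (mm), and 0/1 indicators for difficulty
breathing, pallor, oedema and parental concern — yielding the
probability of hospital admission. Dual thresholds map probability to
category; the boundary convention is half-open "at least this risk":
non-urgent on [0, low), priority on [low, high), emergency on [high, 1].
The published wording does not fix boundary inclusivity; ties at a
threshold are vanishingly rare for continuous predictors, and the
inclusive-upper convention is covered by tests. Threshold pairs: 8 % /
40 % (original) and 2.6 % / 13 % (recalibrated).

**Independent triggers.** Evaluated separately from the model and
merged by max severity, so triggers can only raise acuity. The shock
composite "cool hands with capillary refill > 3 s or weak pulse" is
parsed as cool skin AND (refill OR weak pulse); the alternative parse
((cool AND refill) OR weak pulse) sits behind
`TriggerConfig(shock_requires_cool_skin=False)`. The trigger
dehydration criterion (two of sunken eyes / slow skin pinch / lethargy)
deliberately does not require diarrhoea, and severe pain is an
emergency trigger here while only a priority sign in the sign-based
rules — the systems genuinely disagree, and both are implemented as
specified. "Weak and fast pulse" is represented by the weak-pulse
booleans alone (no tachycardia threshold is specified for that line),
and "skin pinch longer than 2 s" maps onto the single slow-skin-pinch
boolean.

## Recalibration-in-the-large

Given per-patient linear predictors `lp` from a fixed-coefficient model
and binary outcomes `y`, the intercept shift δ maximizes the Bernoulli
log-likelihood of `logistic(lp + δ)`. The score equation at the optimum
is mean(logistic(lp + δ)) = mean(y): mean predicted risk equals observed
prevalence. The solver is a safeguarded Newton iteration on this
monotone score (Fisher-information step, bisection fallback within a
bracketing interval), tolerance 1e−10 on the score, at most 100
iterations; degenerate outcomes (all one class) are rejected because δ
would be unbounded. Because only the intercept moves, the ranking of
patients by risk is invariant — a property the tests assert. The
implementation is cross-checked against an intercept-only binomial GLM
with offset.

## Diagnostic evaluation

Each system is dichotomized to high acuity (emergency) vs low acuity
(priority + non-urgent) and crossed with a binary outcome (admission or
death) into a 2×2 table, restricted to outcome-known children.
Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), NPV
tn/(tn+fn); a zero denominator yields NaN for that statistic only. 95 %
intervals use the continuity-uncorrected Wilson score method
(z = Φ⁻¹(0.975) ≈ 1.959964), with the x = 0 and x = n bounds returned
exactly as 0 and 1. Wilson was chosen because it reproduces every
published interval this package recomputes, whereas Clopper–Pearson does
not (e.g. 191/395 gives a 43.3 % lower bound under Clopper–Pearson vs
the published 43.5 %). Reported percentages are rounded to one decimal
with half-away-from-zero ties, matching the published tables.

One published bound is irreproducible: the mortality NPV lower bound for
the sign-based system prints 99.2 %, but both Wilson and Clopper–Pearson
give 99.300 % for 5068/5092; it is treated as a typographic error. The
published CI columns for the recalibrated model repeat the
with-triggers columns verbatim although the underlying counts differ
slightly (fp 865 vs 867); CI equality with print is therefore asserted
only for the other two systems.

## Packaged aggregate counts

`study_counts` carries the published per-category counts of a
two-hospital Kenyan evaluation: 5618 enrolled, 13 with missing hospital
outcome (excluded everywhere, leaving 5605), 395 admissions and 49
deaths (day-of-enrolment + in-hospital + follow-up). The participant
characteristics elsewhere sum to 394 admissions (383 + 11 readmissions);
the distribution table's 395 is used as printed and the discrepancy
documented. Closing the 2×2 with these totals reproduces every published
point estimate to one decimal place.

## Synthetic cohort generator

The study's per-patient data were not deposited, so a generator
produces cohorts with the documented marginals and the structural
assumption every triage system relies on: a latent severity s ~ N(0, 1)
that makes danger signs, adverse vitals and bad outcomes co-occur.

* **Age**: mixture over bands <1, 1–12, 12–60, 60–144, 144–180 months
  with weights 0.032 / 0.294 / 0.554 / 0.108 / 0.012 (the study's age
  distribution), uniform within band.
* **Signs**: each drawn from logistic(intercept + slope·s), slopes ≥ 0.
  Baseline intercepts are clinically motivated one-time choices: danger
  signs rare (intercepts −8 to −4.5, prevalence well under 1 % at
  s = 0), respiratory/febrile-illness signs common (diarrhoea ≈ 6 %,
  difficulty breathing ≈ 7 %, parental concern ≈ 14 %).
* **Vitals**: normal laws shifted adversely by s (temperature +0.35 °C,
  HR +9, RR +5 per severity SD; SpO2 −1.6, MUAC −4), rejection-resampled
  into the physiologic validation bounds (never clipped, except a
  vanishing-probability guard).
* **Outcomes**: death ~ logistic(d₀ + 2.2 s) and admission ~
  logistic(a₀ + 1.6 s), with d₀ and a₀ calibrated by bisection on the
  realized severities so the expected rates equal the targets (defaults
  0.9 % and 7 %, the study's overall rates); the admission solve
  accounts for the probability floor contributed by deaths, since death
  implies admission except for an ED-death fraction (default 6/49, the
  share of deaths on the day of enrolment). Deaths always have a known
  outcome; a fraction 13/5618 of the others have the outcome flagged
  unknown.

What the generator does **not** emulate: age-dependent vital-sign norms
(one law per vital regardless of age), correlations between signs beyond
the single severity factor, site or seasonal effects, and the study's
exact per-category counts (those depend on the undeposited data and the
unpublished model coefficients). Passing pipeline tests on synthetic
cohorts therefore demonstrates internal consistency — calibrated
marginals, a positive acuity-outcome gradient, no trigger demotions,
determinism — not clinical performance on real children.

## Placeholder model coefficients

The published model's nine coefficients and its SpO2 transform are not
reproduced in this package. The shipped `configs/model_original.yaml`
is a clearly-labelled, non-clinical placeholder with the correct
structure and adverse directions (risk rises with temperature, heart
rate and the categorical danger indicators; falls with SpO2 and MUAC),
an identity SpO2 transform, and the original 8 % / 40 % thresholds. Its
intercept puts a typical well child's predicted risk at a few percent.
No recomputed published statistic depends on these values — the table
reproductions run entirely from aggregate counts.

## Numerical and interface choices

* Units are fixed (months, °C, /min, %, mm); no conversion layer.
* Unknown (not elicited) signs are treated as absent by both rule
  engines — a checklist sign never assessed cannot fire; cohort reading
  logs a summary warning so the convention is visible.
* Vitals outside validation bounds (temperature 30–43 °C, HR 20–300,
  RR 5–150, SpO2 0–100, MUAC 50–300 mm, configurable) are rejected with
  the row and field named, never clipped.
* Model specs load from strict-schema YAML: exactly the nine predictor
  keys, unknown keys rejected, 0 < low < high < 1 enforced.
* All pipeline stages are deterministic given seeds and configs; cohort
  CSV round-trips are lossless (reals at ≥ 10 significant digits).

## Problem sizes

Stochastic checks use n = 50 000 synthetic children (binomial SE of the
7 % admission rate ≈ 0.11 percentage points) and n = 50 000 for
recalibration recovery (recovery error empirically ≲ 0.03 across seeds,
asserted within ±0.05). The exhaustive rule-engine oracle sweep covers
all 2¹² combinations of a twelve-sign subset crossed with 21 vital
profiles at ±0.05 around every numeric threshold. The whole suite runs
in well under a minute on one CPU.
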