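"""Recompute the published diagnostic test tables from aggregate counts.

The study's per-patient data were never deposited, but its per-category
counts (participants, admissions, deaths per triage system) are packaged
in ``triagekit.study_counts``. Dichotomizing to high acuity (emergency)
vs low acuity (priority + non-urgent) and closing the 2x2 table with the
totals reproduces every published sensitivity / specificity / PPV / NPV
to one decimal place, with Wilson 95% CIs.
"""

from triagekit import round_half_away
from triagekit.study_counts import SYSTEMS, confusion_from_counts, study_diagnostics

for outcome, label in (("admitted", "hospital admission"), ("died", "mortality")):
    print(f"\n=== Diagnostic tests for {label} ===")
    for system in SYSTEMS:
        tp, fp, fn, tn = confusion_from_counts(system, outcome)
        d = study_diagnostics(system, outcome)
        print(f"{system}  (tp={tp}, fp={fp}, fn={fn}, tn={tn})")
        for stat in ("sensitivity", "specificity", "ppv", "npv"):
            est = round_half_away(100 * getattr(d, stat))
            lo, hi = getattr(d, f"{stat}_ci")
            print(
                f"  {stat:11s} {est:5.1f}%  "
                f"(95% CI {round_half_away(100 * lo):.1f}% - {round_half_away(100 * hi):.1f}%)"
            )

# The sign-based system trades sensitivity for specificity (48.4% / 93.8%
# for admission); adding the risk model with independent triggers lifts
# sensitivity to 74.9% at the cost of specificity (83.4%) — the
# over-triage / under-triage trade-off at the heart of triage evaluation.
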