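"""Published aggregate counts from the Kenyan two-hospital triage study.

The per-patient dataset behind the study was not deposited, but its
printed aggregate tables are sufficient to recompute every dichotomized
diagnostic statistic: per triage system and category, the number of
participants, admissions, and deaths (day-of-enrolment, in-hospital, and
during follow-up). These counts are packaged here as analysis inputs.

Of the 5618 enrolled children, 13 had a missing hospital outcome; all
outcome-based denominators therefore use the 5605 evaluable children.
Admission rows sum to 395 (the participant-characteristics breakdown
gives 383 admitted on the day of enrolment + 11 readmitted = 394; the
distribution-by-system table's 395 is used as printed — the one-count
discrepancy is documented, not resolved). Deaths total 49.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

from .cohort import TriageCategory
from .evaluation import DiagnosticSummary, diagnostic_summary

__all__ = [
    "ENROLLED",
    "MISSING_OUTCOME",
    "EVALUABLE",
    "TOTAL_ADMISSIONS",
    "TOTAL_DEATHS",
    "SYSTEMS",
    "CategoryCounts",
    "STUDY_COUNTS",
    "AGE_BAND_COUNTS",
    "confusion_from_counts",
    "study_diagnostics",
]

ENROLLED = 5618
MISSING_OUTCOME = 13
EVALUABLE = ENROLLED - MISSING_OUTCOME  # 5605
TOTAL_ADMISSIONS = 395
TOTAL_DEATHS = 49

SYSTEMS = (
    "etat",
    "st_with_triggers",
    "st_recalibrated_with_triggers",
)


@dataclass(frozen=True)
class CategoryCounts:
    """Counts for one triage system and category among evaluable children."""

    participants: int
    admitted: int
    died_enrolment_day: int
    died_in_hospital: int
    died_follow_up: int

    @property
    def died(self) -> int:
        return self.died_enrolment_day + self.died_in_hospital + self.died_follow_up


_E = TriageCategory.EMERGENCY
_P = TriageCategory.PRIORITY
_N = TriageCategory.NON_URGENT

#: system -> category -> CategoryCounts, among the 5605 evaluable children.
STUDY_COUNTS = MappingProxyType(
    {
        "etat": MappingProxyType(
            {
                _E: CategoryCounts(513, 191, 4, 13, 8),
                _P: CategoryCounts(2003, 168, 2, 8, 12),
                _N: CategoryCounts(3089, 36, 0, 0, 2),
            }
        ),
        "st_with_triggers": MappingProxyType(
            {
                _E: CategoryCounts(1163, 296, 5, 18, 16),
                _P: CategoryCounts(2345, 83, 1, 3, 6),
                _N: CategoryCounts(2097, 16, 0, 0, 0),
            }
        ),
        "st_recalibrated_with_triggers": MappingProxyType(
            {
                _E: CategoryCounts(1161, 296, 5, 18, 16),
                _P: CategoryCounts(1827, 74, 1, 3, 6),
                _N: CategoryCounts(2617, 25, 0, 0, 0),
            }
        ),
    }
)

#: Age-band counts among the 5618 enrolled (participant characteristics).
AGE_BAND_COUNTS = MappingProxyType(
    {
        "<1 month": 182,
        "1-12 months": 1653,
        "1-5 years": 3113,
        "5-12 years": 605,
        ">12 years": 65,
    }
)

#: Published risk-threshold pairs for the Smart Triage model.
ORIGINAL_THRESHOLDS = (0.08, 0.40)
RECALIBRATED_THRESHOLDS = (0.026, 0.13)


def confusion_from_counts(
    system: str, outcome: str = "admitted"
) -> tuple[int, int, int, int]:
    """Dichotomized (tp, fp, fn, tn) from the packaged aggregate counts.

    High acuity = emergency; outcome is ``admitted`` or ``died``. The
    total outcome-positive count and the evaluable total close the table:
    fn is the outcome-positives outside emergency, tn the remainder.
    """
    counts = STUDY_COUNTS[system]
    if outcome == "admitted":
        positive_in_emergency = counts[_E].admitted
        total_positive = TOTAL_ADMISSIONS
    elif outcome == "died":
        positive_in_emergency = counts[_E].died
        total_positive = TOTAL_DEATHS
    else:
        raise ValueError(f"outcome must be 'admitted' or 'died', got {outcome!r}")
    tp = positive_in_emergency
    fp = counts[_E].participants - tp
    fn = total_positive - tp
    tn = EVALUABLE - total_positive - fp
    return tp, fp, fn, tn


def study_diagnostics(system: str, outcome: str = "admitted") -> DiagnosticSummary:
    """Diagnostic statistics (with Wilson CIs) recomputed from the counts."""
    tp, fp, fn, tn = confusion_from_counts(system, outcome)
    return diagnostic_summary(tp, fp, fn, tn)
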