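"""triagekit: pediatric emergency triage systems, compared.

A toolkit for running and evaluating pediatric ED triage systems side by
side: the WHO ETAT sign-based rules, the Smart Triage logistic risk model
with dual probability thresholds and independent clinical triggers,
recalibration-in-the-large, reclassification (Sankey) tables, and
dichotomized diagnostic statistics with Wilson confidence intervals —
plus a synthetic cohort generator for end-to-end testing.
"""

from importlib import resources as _resources

from .cohort import (
    CohortValidationError,
    PatientRecord,
    TriageCategory,
    VitalBounds,
    DEFAULT_BOUNDS,
    SIGN_FIELDS,
    read_cohort,
    write_cohort,
    read_assignments,
    write_assignments,
    validate_record,
)
from .etat import (
    EtatConfig,
    EtatResult,
    classify_etat,
    etat_emergency_signs,
    etat_priority_signs,
    fast_breathing,
)
from .triggers import (
    TriggerConfig,
    TriggerResult,
    emergency_triggers,
    evaluate_triggers,
    priority_triggers,
)
from .model import (
    ModelSpec,
    ModelSpecError,
    PREDICTOR_LABELS,
    TriageAssignment,
    admission_probability,
    classify_by_risk,
    cohort_linear_predictors,
    combine_with_triggers,
    linear_predictor,
    load_model_spec,
    recalibrate_in_the_large,
    recalibrate_model,
    triage_cohort,
)
from .evaluation import (
    DiagnosticSummary,
    TransitionTable,
    agreement_proportion,
    category_outcome_table,
    confusion_2x2,
    diagnostic_summary,
    dichotomize,
    round_half_away,
    transition_table,
    wilson_interval,
)
from .synthetic import (
    GradientReport,
    SignLoading,
    SyntheticCohort,
    SyntheticCohortConfig,
    VitalLaw,
    generate_cohort,
    severity_gradient_check,
)
from . import study_counts

__version__ = "0.1.0"


def packaged_model_path(name: str = "model_original.yaml"):
    """Path to a packaged model config (placeholder, non-clinical)."""
    return _resources.files("triagekit") / "configs" / name


def default_model_spec() -> ModelSpec:
    """The packaged placeholder model spec (original thresholds 8% / 40%)."""
    return load_model_spec(packaged_model_path())
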