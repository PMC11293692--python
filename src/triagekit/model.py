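"""Smart Triage risk model: logistic score, dual thresholds, trigger merge,
and recalibration-in-the-large.

The Smart Triage model is a nine-predictor logistic regression for the
probability of hospital admission. Predictors: age (months), temperature
(°C), heart rate (/min), transformed oxygen saturation, MUAC (mm),
difficulty breathing, pallor, oedema, and parental concern — the last
four encoded 0/1. Two probability thresholds map the risk to an acuity
category: below the low threshold -> non-urgent, between the thresholds
-> priority, at or above the high threshold -> emergency. The model's
category is then merged with the independent triggers by max severity.

Threshold boundary convention: categories are half-open intervals
[low, high) for priority and [high, 1] for emergency — "at least this
risk" semantics — since the published wording does not fix inclusivity.

Recalibration-in-the-large re-estimates only the intercept on a new
population, leaving every coefficient unchanged, so that the mean
predicted probability equals the observed outcome prevalence. Because
only the intercept moves, patient risk ranks are invariant under
recalibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .cohort import PatientRecord, TriageCategory
from .etat import EtatConfig, DEFAULT_ETAT_CONFIG, EtatResult, classify_etat
from .triggers import (
    DEFAULT_TRIGGER_CONFIG,
    TriggerConfig,
    TriggerResult,
    evaluate_triggers,
)

__all__ = [
    "PREDICTOR_LABELS",
    "ModelSpec",
    "ModelSpecError",
    "TriageAssignment",
    "load_model_spec",
    "linear_predictor",
    "admission_probability",
    "classify_by_risk",
    "combine_with_triggers",
    "recalibrate_in_the_large",
    "recalibrate_model",
    "triage_cohort",
    "cohort_linear_predictors",
]

#: The nine predictor labels, exactly; a ModelSpec must cover all and only these.
PREDICTOR_LABELS: tuple[str, ...] = (
    "age_months",
    "temperature_c",
    "heart_rate_bpm",
    "spo2_transformed",
    "muac_mm",
    "difficulty_breathing",
    "pallor",
    "oedema",
    "parental_concern",
)

_CATEGORICAL_PREDICTORS = frozenset(
    {"difficulty_breathing", "pallor", "oedema", "parental_concern"}
)


class ModelSpecError(ValueError):
    """Raised for malformed model specifications."""


def _identity(x: float) -> float:
    return x


def _make_affine(params: Mapping[str, float]) -> Callable[[float], float]:
    a = float(params.get("offset", 0.0))
    b = float(params.get("scale", 1.0))
    return lambda x: a + b * x


def _make_power(params: Mapping[str, float]) -> Callable[[float], float]:
    # e.g. squared saturation deficit transforms used by some risk scores
    a = float(params.get("offset", 0.0))
    b = float(params.get("scale", 1.0))
    k = float(params.get("exponent", 1.0))
    return lambda x: b * (x + a) ** k


_SPO2_TRANSFORMS: dict[str, Callable[[Mapping[str, float]], Callable[[float], float]]] = {
    "identity": lambda params: _identity,
    "affine": _make_affine,
    "power": _make_power,
}


@dataclass(frozen=True)
class ModelSpec:
    """Coefficients, intercept, SpO2 transform and risk thresholds.

    ``spo2_transform`` is a named transform applied to the raw SpO2 value
    before multiplication by its coefficient; built-ins are ``identity``,
    ``affine`` (offset + scale*x) and ``power`` (scale*(x+offset)**exponent).
    """

    intercept: float
    coefficients: Mapping[str, float]
    low_threshold: float
    high_threshold: float
    spo2_transform_name: str = "identity"
    spo2_transform_params: Mapping[str, float] = field(default_factory=dict)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        keys = set(self.coefficients)
        expected = set(PREDICTOR_LABELS)
        if keys != expected:
            unknown = sorted(keys - expected)
            missing = sorted(expected - keys)
            parts = []
            if unknown:
                parts.append(f"unknown predictor key(s): {', '.join(unknown)}")
            if missing:
                parts.append(f"missing predictor key(s): {', '.join(missing)}")
            raise ModelSpecError("; ".join(parts))
        if not (0.0 < self.low_threshold < self.high_threshold < 1.0):
            raise ModelSpecError(
                "thresholds must satisfy 0 < low < high < 1, got "
                f"low={self.low_threshold}, high={self.high_threshold}"
            )
        if self.spo2_transform_name not in _SPO2_TRANSFORMS:
            raise ModelSpecError(
                f"unknown spo2_transform {self.spo2_transform_name!r}; "
                f"available: {sorted(_SPO2_TRANSFORMS)}"
            )

    @property
    def spo2_transform(self) -> Callable[[float], float]:
        return _SPO2_TRANSFORMS[self.spo2_transform_name](self.spo2_transform_params)

    def with_intercept(self, intercept: float, *, name: Optional[str] = None) -> "ModelSpec":
        return replace(self, intercept=intercept, name=name or self.name)

    def with_thresholds(self, low: float, high: float) -> "ModelSpec":
        return replace(self, low_threshold=low, high_threshold=high)


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load a ModelSpec from a strict-schema YAML/JSON file."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelSpecError(f"{path}: expected a mapping at top level")
    allowed = {
        "name",
        "intercept",
        "coefficients",
        "spo2_transform",
        "low_threshold",
        "high_threshold",
        "notes",
    }
    extra = set(raw) - allowed
    if extra:
        raise ModelSpecError(f"{path}: unknown key(s): {', '.join(sorted(extra))}")
    try:
        coefficients = {k: float(v) for k, v in dict(raw["coefficients"]).items()}
        transform = raw.get("spo2_transform") or {"name": "identity"}
        spec = ModelSpec(
            intercept=float(raw["intercept"]),
            coefficients=coefficients,
            low_threshold=float(raw["low_threshold"]),
            high_threshold=float(raw["high_threshold"]),
            spo2_transform_name=str(transform.get("name", "identity")),
            spo2_transform_params={
                k: float(v) for k, v in (transform.get("params") or {}).items()
            },
            name=str(raw.get("name", path.stem)),
        )
    except KeyError as exc:
        raise ModelSpecError(f"{path}: missing required key {exc}") from None
    return spec


def _predictor_values(p: PatientRecord, m: ModelSpec) -> dict[str, float]:
    values: dict[str, float] = {}
    missing: list[str] = []
    raw = {
        "age_months": p.age_months,
        "temperature_c": p.temperature_c,
        "heart_rate_bpm": p.heart_rate_bpm,
        "spo2_transformed": p.spo2_percent,
        "muac_mm": p.muac_mm,
    }
    for label, value in raw.items():
        if value != value:  # NaN
            missing.append(label)
            continue
        values[label] = (
            m.spo2_transform(value) if label == "spo2_transformed" else float(value)
        )
    for label in _CATEGORICAL_PREDICTORS:
        flag = getattr(p, label)
        values[label] = 0.0 if flag is None else float(bool(flag))
    if missing:
        raise ValueError(
            f"patient {p.patient_id!r}: missing predictor value(s): "
            f"{', '.join(missing)}"
        )
    return values


def linear_predictor(p: PatientRecord, m: ModelSpec) -> float:
    """Intercept plus the coefficient-weighted sum of the nine predictors."""
    values = _predictor_values(p, m)
    return m.intercept + sum(m.coefficients[k] * values[k] for k in PREDICTOR_LABELS)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def admission_probability(p: PatientRecord, m: ModelSpec) -> float:
    """Predicted probability of admission: logistic(linear predictor)."""
    return _logistic(linear_predictor(p, m))


def classify_by_risk(prob: float, m: ModelSpec) -> TriageCategory:
    """Map an admission probability to a category via the dual thresholds."""
    if not (0.0 <= prob <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {prob}")
    if prob >= m.high_threshold:
        return TriageCategory.EMERGENCY
    if prob >= m.low_threshold:
        return TriageCategory.PRIORITY
    return TriageCategory.NON_URGENT


def combine_with_triggers(
    model_cat: TriageCategory, t: TriggerResult
) -> TriageCategory:
    """Max severity of the model category and any fired triggers.

    Triggers only ever raise acuity; they never demote.
    """
    cat = model_cat
    if t.any_emergency:
        cat = max(cat, TriageCategory.EMERGENCY)
    if t.any_priority:
        cat = max(cat, TriageCategory.PRIORITY)
    return cat


def recalibrate_in_the_large(
    linear_predictors: Sequence[float] | np.ndarray,
    outcomes: Sequence[bool] | np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """Maximum-likelihood intercept shift for a fixed-coefficient model.

    Finds the offset delta maximizing the Bernoulli log-likelihood of
    ``logistic(lp + delta)`` against the observed outcomes. At the optimum
    the score equation holds: the mean predicted probability equals the
    observed prevalence. Solved by a safeguarded Newton iteration
    (bisection fallback) on the monotone score function.

    Parameters
    ----------
    linear_predictors
        Per-patient linear predictors from the original model (logit scale).
    outcomes
        Per-patient binary outcomes; must contain at least one of each class.
    tol
        Convergence tolerance on the score (mean probability minus
        prevalence).

    Returns
    -------
    float
        The intercept offset delta to add to the original intercept.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if lp.shape != y.shape or lp.ndim != 1:
        raise ValueError("linear_predictors and outcomes must be equal-length 1-d")
    n = lp.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    prevalence = y.mean()
    if prevalence in (0.0, 1.0):
        raise ValueError(
            "outcomes are degenerate (all identical); the intercept shift "
            "is unbounded"
        )

    def score(delta: float) -> float:
        # strictly increasing in delta
        p = 1.0 / (1.0 + np.exp(-(lp + delta)))
        return float(p.mean() - prevalence)

    # Bracket the root: score(-inf) = -prev < 0 < score(+inf) = 1 - prev.
    lo, hi = -1.0, 1.0
    while score(lo) > 0:
        lo *= 2
        if lo < -1e6:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket recalibration root (low side)")
    while score(hi) < 0:
        hi *= 2
        if hi > 1e6:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket recalibration root (high side)")

    delta = 0.5 * (lo + hi)
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(lp + delta)))
        s = float(p.mean() - prevalence)
        if abs(s) <= tol:
            return float(delta)
        if s > 0:
            hi = delta
        else:
            lo = delta
        fisher = float((p * (1.0 - p)).mean())
        step = s / fisher if fisher > 0 else 0.0
        candidate = delta - step
        if not (lo < candidate < hi):  # Newton left the bracket: bisect
            candidate = 0.5 * (lo + hi)
        delta = candidate
    raise RuntimeError(
        f"recalibration did not converge in {max_iter} iterations; "
        f"last score {score(delta):.3e}, delta {delta:.6f}"
    )


def recalibrate_model(
    records: Sequence[PatientRecord],
    m: ModelSpec,
    *,
    outcome: str = "admitted",
    low_threshold: Optional[float] = None,
    high_threshold: Optional[float] = None,
) -> ModelSpec:
    """Recalibrate a model's intercept in the large on a cohort.

    Only records with a known outcome contribute. Optionally installs new
    risk thresholds alongside the refitted intercept.
    """
    usable = [p for p in records if p.outcome_known]
    lp = np.array([linear_predictor(p, m) for p in usable])
    y = np.array([bool(getattr(p, outcome)) for p in usable])
    delta = recalibrate_in_the_large(lp, y)
    out = m.with_intercept(m.intercept + delta, name=f"{m.name} (recalibrated)")
    if low_threshold is not None and high_threshold is not None:
        out = out.with_thresholds(low_threshold, high_threshold)
    return out


def cohort_linear_predictors(
    records: Sequence[PatientRecord], m: ModelSpec
) -> np.ndarray:
    """Linear predictors for a whole cohort, in order."""
    return np.array([linear_predictor(p, m) for p in records], dtype=float)


@dataclass(frozen=True)
class TriageAssignment:
    """Per-patient categories under every compared system plus audit trail."""

    patient_id: str
    etat: EtatResult
    st_probability: float
    st_model_only: TriageCategory
    st_with_triggers: TriageCategory
    st_recalibrated_with_triggers: TriageCategory
    triggers: TriggerResult


def triage_cohort(
    records: Iterable[PatientRecord],
    m_original: ModelSpec,
    m_recalibrated: ModelSpec,
    *,
    etat_config: EtatConfig = DEFAULT_ETAT_CONFIG,
    trigger_config: TriggerConfig = DEFAULT_TRIGGER_CONFIG,
) -> list[TriageAssignment]:
    """Run every triage system on every record.

    Produces, per patient: the ETAT result, the Smart Triage admission
    probability under the original model, the model-only category, the
    model+triggers category, and the recalibrated-model+triggers category.
    Deterministic given inputs.
    """
    assignments: list[TriageAssignment] = []
    for p in records:
        try:
            etat_result = classify_etat(p, etat_config)
            trig = evaluate_triggers(p, trigger_config)
            prob = admission_probability(p, m_original)
            model_cat = classify_by_risk(prob, m_original)
            prob_recal = admission_probability(p, m_recalibrated)
            recal_cat = classify_by_risk(prob_recal, m_recalibrated)
        except Exception as exc:
            raise type(exc)(f"patient {p.patient_id!r}: {exc}") from exc
        assignments.append(
            TriageAssignment(
                patient_id=p.patient_id,
                etat=etat_result,
                st_probability=prob,
                st_model_only=model_cat,
                st_with_triggers=combine_with_triggers(model_cat, trig),
                st_recalibrated_with_triggers=combine_with_triggers(recal_cat, trig),
                triggers=trig,
            )
        )
    return assignments
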