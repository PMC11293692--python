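"""Patient records, triage categories, validation, and cohort CSV I/O.

The canonical unit system is fixed: age in months, temperature in degrees
Celsius, heart rate and respiratory rate per minute, SpO2 in percent, and
mid-upper arm circumference (MUAC) in millimetres. Both rule engines state
their thresholds in these units, so no conversion layer exists.

Clinical signs are tri-state: ``True``/``False``/``None`` (not elicited).
Rule engines treat an unknown sign as absent — a checklist sign that was
never assessed cannot fire — and :func:`read_cohort` logs how many records
carry unknown signs so the convention is visible to the user.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TriageCategory",
    "PatientRecord",
    "VitalBounds",
    "DEFAULT_BOUNDS",
    "CohortValidationError",
    "SIGN_FIELDS",
    "VITAL_FIELDS",
    "read_cohort",
    "write_cohort",
    "write_assignments",
    "read_assignments",
    "validate_record",
]


class TriageCategory(IntEnum):
    """Ordered acuity level: non-urgent < priority < emergency."""

    NON_URGENT = 0
    PRIORITY = 1
    EMERGENCY = 2

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "TriageCategory":
        key = label.strip().lower().replace("_", "-")
        try:
            return _CATEGORY_FROM_LABEL[key]
        except KeyError:
            raise ValueError(f"unknown triage category label: {label!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_CATEGORY_LABELS = {
    TriageCategory.NON_URGENT: "non-urgent",
    TriageCategory.PRIORITY: "priority",
    TriageCategory.EMERGENCY: "emergency",
}
_CATEGORY_FROM_LABEL = {v: k for k, v in _CATEGORY_LABELS.items()}


#: Boolean clinical signs known to the rule engines, in canonical order.
SIGN_FIELDS: tuple[str, ...] = (
    "cyanosis",
    "grunting",
    "stridor",
    "capillary_refill_gt3s",
    "weak_central_pulse",
    "weak_radial_pulse",
    "cool_skin",
    "convulsions_now",
    "not_alert_avpu",
    "diarrhoea",
    "sunken_eyes",
    "cannot_sit_or_drink",
    "slow_skin_pinch",
    "lethargy",
    "trauma",
    "major_trauma",
    "burns",
    "pallor",
    "severe_pain",
    "poisoning",
    "chest_indrawing",
    "urgent_referral",
    "irritable",
    "visible_severe_wasting",
    "oedema",
    "unresponsive",
    "not_breathing",
    "obstructed_breathing",
    "accessory_muscle_use",
    "head_nodding",
    "not_eating_drinking_respiratory",
    "difficulty_breathing",
    "parental_concern",
)

VITAL_FIELDS: tuple[str, ...] = (
    "temperature_c",
    "heart_rate_bpm",
    "respiratory_rate_bpm",
    "spo2_percent",
    "muac_mm",
)


@dataclass(frozen=True)
class VitalBounds:
    """Physiologic validation bounds; out-of-bounds vitals are rejected,
    never silently clipped."""

    temperature_c: tuple[float, float] = (30.0, 43.0)
    heart_rate_bpm: tuple[float, float] = (20.0, 300.0)
    respiratory_rate_bpm: tuple[float, float] = (5.0, 150.0)
    spo2_percent: tuple[float, float] = (0.0, 100.0)
    muac_mm: tuple[float, float] = (50.0, 300.0)


DEFAULT_BOUNDS = VitalBounds()


class CohortValidationError(ValueError):
    """Raised when a record (or CSV row) violates schema or bounds."""


@dataclass
class PatientRecord:
    """One child's ED presentation: demographics, vitals, signs, outcomes.

    Signs default to ``None`` (unknown / not elicited).
    """

    patient_id: str
    age_months: float
    sex: str = "unknown"  # {male, female, unknown}
    temperature_c: float = float("nan")
    heart_rate_bpm: float = float("nan")
    respiratory_rate_bpm: float = float("nan")
    spo2_percent: float = float("nan")
    muac_mm: float = float("nan")

    cyanosis: Optional[bool] = None
    grunting: Optional[bool] = None
    stridor: Optional[bool] = None
    capillary_refill_gt3s: Optional[bool] = None
    weak_central_pulse: Optional[bool] = None
    weak_radial_pulse: Optional[bool] = None
    cool_skin: Optional[bool] = None
    convulsions_now: Optional[bool] = None
    not_alert_avpu: Optional[bool] = None
    diarrhoea: Optional[bool] = None
    sunken_eyes: Optional[bool] = None
    cannot_sit_or_drink: Optional[bool] = None
    slow_skin_pinch: Optional[bool] = None
    lethargy: Optional[bool] = None
    trauma: Optional[bool] = None
    major_trauma: Optional[bool] = None
    burns: Optional[bool] = None
    pallor: Optional[bool] = None
    severe_pain: Optional[bool] = None
    poisoning: Optional[bool] = None
    chest_indrawing: Optional[bool] = None
    urgent_referral: Optional[bool] = None
    irritable: Optional[bool] = None
    visible_severe_wasting: Optional[bool] = None
    oedema: Optional[bool] = None
    unresponsive: Optional[bool] = None
    not_breathing: Optional[bool] = None
    obstructed_breathing: Optional[bool] = None
    accessory_muscle_use: Optional[bool] = None
    head_nodding: Optional[bool] = None
    not_eating_drinking_respiratory: Optional[bool] = None
    difficulty_breathing: Optional[bool] = None
    parental_concern: Optional[bool] = None

    admitted: bool = False
    died: bool = False
    outcome_known: bool = True

    def sign(self, name: str) -> bool:
        """Sign value with the unknown-is-absent convention."""
        return bool(getattr(self, name)) if getattr(self, name) is not None else False

    def unknown_signs(self) -> list[str]:
        return [s for s in SIGN_FIELDS if getattr(self, s) is None]

    @property
    def tiny_infant(self) -> bool:
        """Age under 2 months, fractional months counted."""
        return self.age_months < 2.0


def validate_record(
    record: PatientRecord, bounds: VitalBounds = DEFAULT_BOUNDS
) -> PatientRecord:
    """Validate one record against physiologic bounds and logical invariants.

    Returns the record unchanged on success; raises
    :class:`CohortValidationError` naming the offending field otherwise.
    Validation is idempotent: an accepted record is accepted, bit for bit,
    on re-validation.
    """
    if record.age_months < 0 or record.age_months != record.age_months:
        raise CohortValidationError(
            f"patient {record.patient_id!r}: age_months must be >= 0, "
            f"got {record.age_months!r}"
        )
    if record.sex not in ("male", "female", "unknown"):
        raise CohortValidationError(
            f"patient {record.patient_id!r}: sex must be male/female/unknown, "
            f"got {record.sex!r}"
        )
    for name in VITAL_FIELDS:
        value = getattr(record, name)
        if value != value:  # NaN — vital not measured
            continue
        lo, hi = getattr(bounds, name)
        if not (lo <= value <= hi):
            raise CohortValidationError(
                f"patient {record.patient_id!r}: {name}={value} outside "
                f"validation bounds [{lo}, {hi}]"
            )
    if record.died and not record.outcome_known:
        raise CohortValidationError(
            f"patient {record.patient_id!r}: died=True requires outcome_known=True"
        )
    return record


_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


def _parse_bool(token: str, *, row: int, column: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise CohortValidationError(
        f"row {row}, column {column!r}: cannot parse boolean from {token!r}"
    )


def _parse_float(token: str, *, row: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise CohortValidationError(
            f"row {row}, column {column!r}: cannot parse number from {token!r}"
        ) from None


#: Columns that must be present (possibly renamed via the schema mapping).
REQUIRED_COLUMNS = ("patient_id", "age_months") + VITAL_FIELDS


def read_cohort(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    *,
    bounds: VitalBounds = DEFAULT_BOUNDS,
    allow_missing_vitals: bool = False,
) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Parameters
    ----------
    path
        UTF-8 comma-separated file with a header row.
    schema
        Optional mapping ``canonical field name -> column name in the file``;
        unmapped fields use their canonical names.
    bounds
        Physiologic validation bounds applied to each row.
    allow_missing_vitals
        When False (default), an empty cell in a vital column is an error;
        when True it is stored as NaN.

    Rows are returned in file order. Empty sign cells become unknown
    (``None``). Errors report the 1-based data row and the column.
    """
    schema = dict(schema or {})
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file (no header row)")
        header = set(reader.fieldnames)
        colmap = {f: schema.get(f, f) for f in _RECORD_FIELDS}
        missing = [colmap[f] for f in REQUIRED_COLUMNS if colmap[f] not in header]
        if missing:
            raise CohortValidationError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )

        records: list[PatientRecord] = []
        n_with_unknown_signs = 0
        for i, row in enumerate(reader, start=1):
            kwargs: dict = {}
            for fname in _RECORD_FIELDS:
                col = colmap[fname]
                raw = row.get(col)
                cell = "" if raw is None else raw.strip()
                if fname == "patient_id":
                    kwargs[fname] = cell or str(i)
                elif fname == "sex":
                    kwargs[fname] = cell.lower() or "unknown"
                elif fname == "age_months" or fname in VITAL_FIELDS:
                    if cell == "":
                        if fname != "age_months" and allow_missing_vitals:
                            kwargs[fname] = float("nan")
                        else:
                            raise CohortValidationError(
                                f"row {i}, column {col!r}: empty value for "
                                f"required numeric field"
                            )
                    else:
                        kwargs[fname] = _parse_float(cell, row=i, column=col)
                elif fname in SIGN_FIELDS:
                    kwargs[fname] = (
                        None if cell == "" else _parse_bool(cell, row=i, column=col)
                    )
                else:  # outcomes
                    if cell == "":
                        kwargs[fname] = fname == "outcome_known"
                    else:
                        kwargs[fname] = _parse_bool(cell, row=i, column=col)
            record = PatientRecord(**kwargs)
            try:
                validate_record(record, bounds)
            except CohortValidationError as exc:
                raise CohortValidationError(f"row {i}: {exc}") from None
            if record.unknown_signs():
                n_with_unknown_signs += 1
            records.append(record)

    if n_with_unknown_signs:
        logger.warning(
            "%s: %d of %d records have unknown (blank) clinical signs; "
            "rule engines treat unknown signs as absent",
            path,
            n_with_unknown_signs,
            len(records),
        )
    return records


_RECORD_FIELDS = tuple(f.name for f in fields(PatientRecord))


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if value != value:
            return ""
        return format(value, ".10g")  # >= 6 significant digits, lossless here
    return str(value)


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema (round-trips losslessly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RECORD_FIELDS)
        for rec in records:
            writer.writerow(_format_cell(getattr(rec, f)) for f in _RECORD_FIELDS)


ASSIGNMENT_COLUMNS = (
    "patient_id",
    "etat_category",
    "st_probability",
    "st_model_only",
    "st_with_triggers",
    "st_recalibrated_with_triggers",
    "etat_emergency_signs",
    "etat_priority_signs",
    "emergency_triggers",
    "priority_triggers",
)


def write_assignments(assignments: Iterable, path: str | Path) -> None:
    """Write per-patient triage assignments with their audit trail.

    One row per patient: the category under each system plus the
    semicolon-joined lists of fired signs and triggers. Reading the file back
    reproduces every category label exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ASSIGNMENT_COLUMNS)
        for a in assignments:
            writer.writerow(
                [
                    a.patient_id,
                    a.etat.category.label,
                    format(a.st_probability, ".10g"),
                    a.st_model_only.label,
                    a.st_with_triggers.label,
                    a.st_recalibrated_with_triggers.label,
                    ";".join(sorted(a.etat.emergency_signs)),
                    ";".join(sorted(a.etat.priority_signs)),
                    ";".join(sorted(a.triggers.emergency_triggers)),
                    ";".join(sorted(a.triggers.priority_triggers)),
                ]
            )


def read_assignments(path: str | Path) -> list[dict]:
    """Read an assignments CSV back as dictionaries with parsed categories."""
    path = Path(path)
    out: list[dict] = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            parsed = dict(row)
            for col in (
                "etat_category",
                "st_model_only",
                "st_with_triggers",
                "st_recalibrated_with_triggers",
            ):
                parsed[col] = TriageCategory.from_label(row[col])
            parsed["st_probability"] = float(row["st_probability"])
            for col in (
                "etat_emergency_signs",
                "etat_priority_signs",
                "emergency_triggers",
                "priority_triggers",
            ):
                parsed[col] = set(filter(None, row[col].split(";")))
            out.append(parsed)
    return out
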