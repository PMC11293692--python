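"""Synthetic pediatric emergency-department cohort generator.

The study cohort behind the packaged count tables was never deposited, so
this module generates cohorts with the same statistical skeleton: the
documented age-band mixture, ~7% admission and ~0.9% mortality, and
clinical signs and vital signs driven by a one-dimensional latent
severity so that sicker children are more likely to carry danger signs,
have adverse vitals, and be admitted or die.

Generative model, per child:

1. draw an age band from the mixture weights, then age uniformly within
   the band;
2. draw latent severity ``s`` (standard normal by default);
3. draw each boolean sign from ``logistic(intercept + slope * s)`` with
   all slopes >= 0, so every sign is (weakly) more likely in sicker
   children;
4. draw vitals from normal laws shifted adversely by ``s`` (SpO2 and
   MUAC decrease; temperature, heart rate and respiratory rate
   increase), rejection-resampled into the physiologic validation
   bounds;
5. draw death from ``logistic(d0 + d_slope * s)`` and admission from
   ``logistic(a0 + a_slope * s)``, where ``d0`` and ``a0`` are calibrated
   by a Newton solve on the realized severities so the expected rates
   equal the configured targets; death implies admission except for an
   emergency-department death fraction, and implies a known outcome;
6. a small fraction of surviving children get ``outcome_known = False``
   (the study's 13/5618 missing hospital outcomes).

The generator is the package's own construction: its job is to produce
cohorts with the documented marginals and a positive acuity-outcome
gradient, not to reproduce the study's per-category counts (those depend
on the undeposited data and the unpublished model coefficients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_BOUNDS,
    PatientRecord,
    SIGN_FIELDS,
    VitalBounds,
    validate_record,
    write_cohort,
)

__all__ = [
    "SignLoading",
    "VitalLaw",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "severity_gradient_check",
    "GradientReport",
    "DEFAULT_AGE_MIXTURE",
    "DEFAULT_SIGN_LOADINGS",
    "DEFAULT_VITAL_LAWS",
]


#: Age bands (months) and mixture weights from the study's age table:
#: <1 mo 3.2%, 1-12 mo 29.4%, 1-5 y 55.4%, 5-12 y 10.8%, >12 y 1.2%.
DEFAULT_AGE_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (0.0, 1.0, 0.032),
    (1.0, 12.0, 0.294),
    (12.0, 60.0, 0.554),
    (60.0, 144.0, 0.108),
    (144.0, 180.0, 0.012),
)


@dataclass(frozen=True)
class SignLoading:
    """Logistic law for one boolean sign: P(sign) = logistic(intercept +
    slope * severity); slope must be nonnegative."""

    intercept: float
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("sign loadings must have nonnegative slope")


# Baseline prevalences chosen to resemble a pediatric ED case mix:
# danger signs are rare (intercepts near -5, prevalence well under 1% at
# severity 0), respiratory and febrile-illness signs are common. Severity
# slopes around 1-1.5 concentrate danger signs in the sick tail.
DEFAULT_SIGN_LOADINGS: Mapping[str, SignLoading] = {
    "cyanosis": SignLoading(-6.0, 1.5),
    "grunting": SignLoading(-5.5, 1.5),
    "stridor": SignLoading(-5.5, 1.2),
    "capillary_refill_gt3s": SignLoading(-5.0, 1.5),
    "weak_central_pulse": SignLoading(-5.5, 1.5),
    "weak_radial_pulse": SignLoading(-5.0, 1.5),
    "cool_skin": SignLoading(-4.5, 1.2),
    "convulsions_now": SignLoading(-6.5, 1.5),
    "not_alert_avpu": SignLoading(-6.0, 1.8),
    "diarrhoea": SignLoading(-2.7, 0.3),
    "sunken_eyes": SignLoading(-4.5, 1.0),
    "cannot_sit_or_drink": SignLoading(-5.0, 1.5),
    "slow_skin_pinch": SignLoading(-5.0, 1.2),
    "lethargy": SignLoading(-4.5, 1.5),
    "trauma": SignLoading(-3.2, 0.0),
    "major_trauma": SignLoading(-6.5, 0.8),
    "burns": SignLoading(-5.5, 0.2),
    "pallor": SignLoading(-4.0, 0.8),
    "severe_pain": SignLoading(-5.5, 0.8),
    "poisoning": SignLoading(-6.5, 0.3),
    "chest_indrawing": SignLoading(-4.0, 1.2),
    "urgent_referral": SignLoading(-5.5, 1.0),
    "irritable": SignLoading(-3.5, 0.8),
    "visible_severe_wasting": SignLoading(-5.5, 1.0),
    "oedema": SignLoading(-5.5, 0.8),
    "unresponsive": SignLoading(-7.0, 2.0),
    "not_breathing": SignLoading(-8.0, 2.0),
    "obstructed_breathing": SignLoading(-7.0, 1.5),
    "accessory_muscle_use": SignLoading(-4.5, 1.2),
    "head_nodding": SignLoading(-5.5, 1.2),
    "not_eating_drinking_respiratory": SignLoading(-4.5, 1.0),
    "difficulty_breathing": SignLoading(-2.6, 0.8),
    "parental_concern": SignLoading(-1.8, 0.5),
}


@dataclass(frozen=True)
class VitalLaw:
    """Normal law for one vital: value ~ N(mean + shift * severity, sd),
    rejection-resampled into the validation bounds. ``shift`` carries the
    adverse direction's sign (negative for SpO2 and MUAC)."""

    mean: float
    sd: float
    shift: float


DEFAULT_VITAL_LAWS: Mapping[str, VitalLaw] = {
    "temperature_c": VitalLaw(37.3, 0.8, 0.35),
    "heart_rate_bpm": VitalLaw(125.0, 18.0, 9.0),
    "respiratory_rate_bpm": VitalLaw(34.0, 9.0, 5.0),
    "spo2_percent": VitalLaw(97.5, 1.8, -1.6),
    "muac_mm": VitalLaw(148.0, 18.0, -4.0),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generative parameters.

    admission_rate / mortality_rate
        Target marginal outcome rates (defaults 7% and 0.9%, the study's
        overall rates).
    age_mixture
        (low, high, weight) month-bands; weights must sum to 1.
    severity_sd
        Standard deviation of the latent severity (mean 0).
    admission_slope / mortality_slope
        Severity slopes of the outcome logistic laws; intercepts are
        calibrated at generation time to hit the target rates.
    ed_death_fraction
        Fraction of deaths that occur in the ED before admission (these
        children die without being admitted).
    missing_outcome_fraction
        Fraction of surviving children with unknown hospital outcome.
    """

    n: int
    seed: int = 0
    admission_rate: float = 0.07
    mortality_rate: float = 0.009
    age_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_AGE_MIXTURE
    severity_sd: float = 1.0
    admission_slope: float = 1.6
    mortality_slope: float = 2.2
    ed_death_fraction: float = 6.0 / 49.0
    missing_outcome_fraction: float = 13.0 / 5618.0
    sign_loadings: Mapping[str, SignLoading] = field(
        default_factory=lambda: dict(DEFAULT_SIGN_LOADINGS)
    )
    vital_laws: Mapping[str, VitalLaw] = field(
        default_factory=lambda: dict(DEFAULT_VITAL_LAWS)
    )
    bounds: VitalBounds = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        weights = sum(w for _, _, w in self.age_mixture)
        if abs(weights - 1.0) > 1e-9:
            raise ValueError(f"age mixture weights must sum to 1, got {weights}")
        if not 0 < self.mortality_rate < self.admission_rate < 1:
            raise ValueError(
                "rates must satisfy 0 < mortality_rate < admission_rate < 1"
            )
        unknown = set(self.sign_loadings) - set(SIGN_FIELDS)
        if unknown:
            raise ValueError(f"unknown sign(s) in loadings: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records together with their latent severities."""

    records: list[PatientRecord]
    severity: np.ndarray
    config: SyntheticCohortConfig

    def write_csv(self, path) -> None:
        """Write the cohort CSV (latent severity is not part of the schema)."""
        write_cohort(self.records, path)

    def to_dataframe(self) -> pd.DataFrame:
        from dataclasses import asdict

        df = pd.DataFrame([asdict(r) for r in self.records])
        df["latent_severity"] = self.severity
        return df


def _calibrate_intercept(
    target: float,
    slope: float,
    s: np.ndarray,
    floor: Optional[np.ndarray] = None,
    scale: Optional[np.ndarray] = None,
) -> float:
    """Solve for c such that mean over the realized severities of
    ``floor + scale * logistic(c + slope*s)`` equals ``target``.

    ``floor`` is the per-child probability of being outcome-positive
    through another path (e.g. admission forced by death) and ``scale``
    the probability that the logistic branch applies; 0 and 1 if None.
    """
    if floor is None:
        floor = np.zeros_like(s)
    if scale is None:
        scale = np.ones_like(s)
    lo, hi = -30.0, 30.0
    for _ in range(200):
        c = 0.5 * (lo + hi)
        p = floor + scale / (1.0 + np.exp(-(c + slope * s)))
        m = p.mean()
        if abs(m - target) < 1e-12:
            return c
        if m > target:
            hi = c
        else:
            lo = c
    return 0.5 * (lo + hi)


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Normal draws rejection-resampled into [lo, hi] (never clipped)."""
    x = rng.normal(mean, sd)
    bad = (x < lo) | (x > hi)
    for _ in range(1000):
        if not bad.any():
            break
        x[bad] = rng.normal(mean[bad] if np.ndim(mean) else mean, sd, size=bad.sum())
        bad = (x < lo) | (x > hi)
    np.clip(x, lo, hi, out=x)  # vanishing-probability tail guard
    return x


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a validated synthetic cohort, deterministically per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return SyntheticCohort(records=[], severity=np.empty(0), config=config)

    bands = config.age_mixture
    band_idx = rng.choice(len(bands), size=n, p=[w for _, _, w in bands])
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    age = rng.uniform(lows[band_idx], highs[band_idx])

    s = rng.normal(0.0, config.severity_sd, size=n)

    sign_draws: dict[str, np.ndarray] = {}
    for name in SIGN_FIELDS:
        loading = config.sign_loadings.get(name)
        if loading is None:
            sign_draws[name] = np.zeros(n, dtype=bool)
        else:
            p = 1.0 / (1.0 + np.exp(-(loading.intercept + loading.slope * s)))
            sign_draws[name] = rng.random(n) < p

    vitals: dict[str, np.ndarray] = {}
    for name, law in config.vital_laws.items():
        lo, hi = getattr(config.bounds, name)
        vitals[name] = _truncated_normal(rng, law.mean + law.shift * s, law.sd, lo, hi)

    # Outcomes: calibrate intercepts on the realized severities so the
    # conditional expected rates equal the targets exactly; death forces
    # admission except for the ED-death fraction, which the admission
    # calibration accounts for through the probability floor.
    d0 = _calibrate_intercept(config.mortality_rate, config.mortality_slope, s)
    p_die = 1.0 / (1.0 + np.exp(-(d0 + config.mortality_slope * s)))
    died = rng.random(n) < p_die
    ed_death = died & (rng.random(n) < config.ed_death_fraction)

    floor = p_die * (1.0 - config.ed_death_fraction)  # P(admitted via death)
    a0 = _calibrate_intercept(
        config.admission_rate, config.admission_slope, s, floor, scale=1.0 - p_die
    )
    admitted = rng.random(n) < 1.0 / (1.0 + np.exp(-(a0 + config.admission_slope * s)))
    admitted = (admitted & ~died) | (died & ~ed_death)

    outcome_known = ~(rng.random(n) < config.missing_outcome_fraction)
    outcome_known |= died  # a recorded death is a known outcome

    sexes = np.where(rng.random(n) < 0.541, "male", "female")

    records = []
    for i in range(n):
        rec = PatientRecord(
            patient_id=f"S{i + 1:06d}",
            age_months=float(age[i]),
            sex=str(sexes[i]),
            temperature_c=float(vitals["temperature_c"][i]),
            heart_rate_bpm=float(vitals["heart_rate_bpm"][i]),
            respiratory_rate_bpm=float(vitals["respiratory_rate_bpm"][i]),
            spo2_percent=float(vitals["spo2_percent"][i]),
            muac_mm=float(vitals["muac_mm"][i]),
            admitted=bool(admitted[i]),
            died=bool(died[i]),
            outcome_known=bool(outcome_known[i]),
            **{name: bool(sign_draws[name][i]) for name in SIGN_FIELDS},
        )
        records.append(validate_record(rec, config.bounds))
    return SyntheticCohort(records=records, severity=s, config=config)


@dataclass(frozen=True)
class GradientReport:
    """Outcome rates stratified by latent-severity tertile."""

    tertile_admission_rates: tuple[float, ...]
    tertile_mortality_rates: tuple[float, ...]
    admission_monotone: bool
    mortality_monotone: bool


def severity_gradient_check(cohort: SyntheticCohort) -> GradientReport:
    """Check that outcome rates rise (weakly) across severity tertiles.

    Validates the generator's core assumption that acuity tracks outcome:
    admission and mortality rates, among outcome-known children, must be
    weakly monotone increasing from the least to the most severe tertile.
    """
    known = np.array([r.outcome_known for r in cohort.records])
    adm = np.array([r.admitted for r in cohort.records])
    dd = np.array([r.died for r in cohort.records])
    s = cohort.severity
    if known.sum() == 0:
        raise ValueError("no outcome-known records to stratify")
    edges = np.quantile(s[known], [1 / 3, 2 / 3])
    tert = np.digitize(s, edges)  # 0,1,2
    adm_rates, die_rates = [], []
    for t in range(3):
        mask = known & (tert == t)
        denominator = max(int(mask.sum()), 1)
        adm_rates.append(float((mask & adm).sum() / denominator))
        die_rates.append(float((mask & dd).sum() / denominator))
    return GradientReport(
        tertile_admission_rates=tuple(adm_rates),
        tertile_mortality_rates=tuple(die_rates),
        admission_monotone=adm_rates[0] <= adm_rates[1] <= adm_rates[2],
        mortality_monotone=die_rates[0] <= die_rates[1] <= die_rates[2],
    )
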