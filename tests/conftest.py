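from __future__ import annotations

import pytest

from triagekit import ModelSpec, PatientRecord, SIGN_FIELDS


NORMAL_VITALS = dict(
    age_months=24.0,
    temperature_c=36.8,
    heart_rate_bpm=110.0,
    respiratory_rate_bpm=28.0,
    spo2_percent=98.0,
    muac_mm=150.0,
)


def make_record(**overrides) -> PatientRecord:
    """A well child (all signs explicitly absent, normal vitals) with
    selective overrides — the base case for rule-engine tests."""
    kwargs = dict(patient_id="T1", **NORMAL_VITALS)
    kwargs.update({s: False for s in SIGN_FIELDS})
    kwargs.update(overrides)
    return PatientRecord(**kwargs)


@pytest.fixture
def well_child() -> PatientRecord:
    return make_record()


def zero_coefficients() -> dict[str, float]:
    from triagekit import PREDICTOR_LABELS

    return {k: 0.0 for k in PREDICTOR_LABELS}


@pytest.fixture
def zero_model() -> ModelSpec:
    """All-zero coefficients: probability depends on the intercept only."""
    return ModelSpec(
        intercept=0.0,
        coefficients=zero_coefficients(),
        low_threshold=0.08,
        high_threshold=0.40,
    )
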