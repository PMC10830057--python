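import numpy as np
import pytest

from cvdval.cohort_model import Cohort, ParticipantRecord

RECORD_DEFAULTS = dict(
    id="p0",
    sex="male",
    age=55.0,
    total_cholesterol=213.0,
    hdl=50.0,
    ldl=120.0,
    triglycerides=150.0,
    fasting_glucose=90.0,
    bmi=24.0,
    sbp=120.0,
    bp_treated=False,
    smoker=False,
    diabetes=False,
    prior_cvd=False,
    event=False,
    event_code=None,
    followup_years=10.0,
)


def make_record(**overrides) -> ParticipantRecord:
    return ParticipantRecord(**{**RECORD_DEFAULTS, **overrides})


def make_cohort(rows: list[dict]) -> Cohort:
    """Build a cohort from per-row overrides of the default record."""
    return Cohort.from_records([make_record(id=f"p{i}", **row) for i, row in enumerate(rows)])


@pytest.fixture
def reference_record() -> ParticipantRecord:
    """55-year-old untreated non-smoking non-diabetic man at typical lab values."""
    return make_record()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240131)
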