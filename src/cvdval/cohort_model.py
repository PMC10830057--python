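"""Cohort data model, eligibility filters, ICD-10 outcome composite and incidence rates.

The unit of analysis is a participant followed for up to 10 years from a
baseline health examination, with the covariates used by the Framingham and
pooled-cohort (ASCVD) risk equations plus the extra lipid/glucose/BMI
predictors considered by the data-driven model. A cohort is a validated
pandas DataFrame with one row per participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "CONTINUOUS_FIELDS",
    "COMPOSITE_CODES",
    "SUBTYPE_LABELS",
    "ParticipantRecord",
    "Cohort",
    "CohortValidationError",
    "ExclusionRules",
    "ExclusionLog",
    "IncidenceEstimate",
    "apply_exclusions",
    "engine_eligibility",
    "map_outcome",
    "incidence_rate",
    "rate_ratio_test",
    "derive_hypertension",
    "derive_t2dm",
]

CONTINUOUS_FIELDS = (
    "age",
    "total_cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
    "fasting_glucose",
    "bmi",
    "sbp",
)

BOOLEAN_FIELDS = ("bp_treated", "smoker", "diabetes", "prior_cvd", "event")

COHORT_COLUMNS = (
    "id",
    "sex",
    *CONTINUOUS_FIELDS,
    *BOOLEAN_FIELDS,
    "event_code",
    "followup_years",
)

#: 3-character ICD-10 categories forming the composite CVD outcome:
#: ischemic heart disease (I20-I21), atrial fibrillation/flutter and heart
#: failure (I48, I50), cardiac arrest (I46), hemorrhagic stroke (I60-I62),
#: ischemic stroke and TIA (I63-I64, G45).
COMPOSITE_CODES = frozenset(
    {"I20", "I21", "I46", "I48", "I50", "I60", "I61", "I62", "I63", "I64", "G45"}
)

SUBTYPE_LABELS = {
    "I20": "Angina pectoris",
    "I21": "Acute myocardial infarction",
    "I46": "Cardiac arrest",
    "I48": "Atrial fibrillation and flutter",
    "I50": "Heart failure",
    "I60": "Subarachnoid hemorrhage",
    "I61": "Intracerebral hemorrhage",
    "I62": "Other nontraumatic intracranial hemorrhage",
    "I63": "Cerebral infarction",
    "I64": "Stroke, not specified as hemorrhage or infarction",
    "G45": "Transient cerebral ischemic attacks and related syndromes",
}

FOLLOWUP_HORIZON = 10.0


class CohortValidationError(ValueError):
    """Raised when cohort rows violate the record schema; carries row numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"{len(problems)} invalid cohort row(s): {preview}{more}")


class ParticipantRecord(BaseModel):
    """One participant: baseline covariates, flags, and the 10-year outcome."""

    id: str
    sex: Literal["male", "female"]
    age: float
    total_cholesterol: float
    hdl: float
    ldl: float
    triglycerides: float
    fasting_glucose: float
    bmi: float
    sbp: float
    bp_treated: bool
    smoker: bool
    diabetes: bool
    prior_cvd: bool
    event: bool
    event_code: Optional[str] = None
    followup_years: float

    @model_validator(mode="after")
    def _check_invariants(self) -> "ParticipantRecord":
        for name in CONTINUOUS_FIELDS:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")
        if self.event != (self.event_code is not None and self.event_code != ""):
            raise ValueError("event must be true exactly when event_code is present")
        if self.event:
            label, _ = map_outcome(self.event_code)
            if label != "composite_cvd":
                raise ValueError(f"event_code {self.event_code!r} is not a composite CVD code")
            if not (0 < self.followup_years <= FOLLOWUP_HORIZON):
                raise ValueError("followup_years must lie in (0, 10] for events")
        else:
            if self.followup_years != FOLLOWUP_HORIZON:
                raise ValueError("non-events are administratively censored at exactly 10 years")
        return self


@dataclass
class Cohort:
    """A validated cohort; thin wrapper around a DataFrame with the record schema.

    ``has_outcomes=False`` marks a covariates-only cohort (as produced by the
    synthetic covariate generator before outcome simulation); outcome columns
    are then absent.
    """

    df: pd.DataFrame
    has_outcomes: bool = True

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[ParticipantRecord]) -> "Cohort":
        rows = [r.model_dump() for r in records]
        df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
        df["event_code"] = df["event_code"].fillna("")
        return cls(df)

    def to_records(self) -> list[ParticipantRecord]:
        return [
            ParticipantRecord(**{**row, "event_code": row["event_code"] or None})
            for row in self.df.to_dict("records")
        ]

    def validate(self) -> None:
        """Check every row against the record invariants; raise with row numbers."""
        problems = validate_cohort_frame(self.df, require_outcomes=self.has_outcomes)
        if problems:
            raise CohortValidationError(problems)


def validate_cohort_frame(df: pd.DataFrame, require_outcomes: bool = True) -> list[str]:
    """Vectorized row validation; returns one message per offending row/field."""
    problems: list[str] = []
    expected = list(COHORT_COLUMNS) if require_outcomes else (
        ["id", "sex"] + list(CONTINUOUS_FIELDS) + ["bp_treated", "smoker", "diabetes", "prior_cvd"]
    )
    missing = [c for c in expected if c not in df.columns]
    if missing:
        return [f"missing column(s): {', '.join(missing)}"]

    def report(mask: pd.Series, msg: str) -> None:
        for idx in df.index[np.asarray(mask, dtype=bool)][:50]:
            problems.append(f"row {idx}: {msg}")

    bad_sex = ~df["sex"].isin(["male", "female"])
    report(bad_sex, "sex must be 'male' or 'female'")
    for name in CONTINUOUS_FIELDS:
        col = pd.to_numeric(df[name], errors="coerce")
        report(col.isna() | ~np.isfinite(col) | (col <= 0), f"{name} must be strictly positive")
    if require_outcomes:
        code = df["event_code"].fillna("").astype(str)
        event = df["event"].astype(bool)
        report(event != (code != ""), "event must be true exactly when event_code is present")
        known = code.str.slice(0, 3).isin(COMPOSITE_CODES)
        report((code != "") & ~known, "event_code is not a composite CVD code")
        fu = pd.to_numeric(df["followup_years"], errors="coerce")
        report(event & ~((fu > 0) & (fu <= FOLLOWUP_HORIZON)), "event followup_years must be in (0, 10]")
        report(~event & (fu != FOLLOWUP_HORIZON), "non-event followup_years must equal 10")
    return problems


# ---------------------------------------------------------------------------
# Eligibility and exclusion filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRules:
    """Study-entry filters: minimum age, prior CVD, and lab/BMI outlier caps."""

    min_age: float = 30.0
    exclude_prior_cvd: bool = True
    total_cholesterol_max: float = 300.0
    hdl_max: float = 100.0
    bmi_max: float = 100.0
    ldl_max: float = 1000.0
    triglycerides_max: float = 1500.0

    def __post_init__(self) -> None:
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")
        for f in ("total_cholesterol_max", "hdl_max", "bmi_max", "ldl_max", "triglycerides_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


#: fixed attribution order: a record violating several rules is counted once,
#: under the first rule in this order.
EXCLUSION_ORDER = (
    "under_age",
    "prior_cvd",
    "tc_outlier",
    "hdl_outlier",
    "bmi_outlier",
    "ldl_outlier",
    "tg_outlier",
)


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(default_factory=lambda: {k: 0 for k in EXCLUSION_ORDER})
    n_input: int = 0
    n_included: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.counts), "excluded": list(self.counts.values())}
        )


def apply_exclusions(cohort: Cohort, rules: ExclusionRules | None = None) -> tuple[Cohort, ExclusionLog]:
    """Apply study-entry filters; each record is attributed to its first violated rule."""
    rules = rules or ExclusionRules()
    df = cohort.df
    masks = {
        "under_age": df["age"] < rules.min_age,
        "prior_cvd": df["prior_cvd"].astype(bool) if rules.exclude_prior_cvd
        else pd.Series(False, index=df.index),
        "tc_outlier": df["total_cholesterol"] > rules.total_cholesterol_max,
        "hdl_outlier": df["hdl"] > rules.hdl_max,
        "bmi_outlier": df["bmi"] > rules.bmi_max,
        "ldl_outlier": df["ldl"] > rules.ldl_max,
        "tg_outlier": df["triglycerides"] > rules.triglycerides_max,
    }
    log = ExclusionLog(n_input=len(df))
    already = pd.Series(False, index=df.index)
    for rule in EXCLUSION_ORDER:
        hit = masks[rule] & ~already
        log.counts[rule] = int(hit.sum())
        already = already | masks[rule]
    kept = Cohort(df[~already].reset_index(drop=True), has_outcomes=cohort.has_outcomes)
    log.n_included = len(kept)
    return kept, log


ENGINE_AGE_WINDOWS = {"framingham": (30.0, 74.0), "ascvd": (40.0, 79.0)}


def engine_eligibility(
    cohort: Cohort,
    engine: str,
    age_window: tuple[float, float] | None = None,
) -> Cohort:
    """Restrict a filtered cohort to the age window a risk engine was developed for."""
    if age_window is None:
        if engine not in ENGINE_AGE_WINDOWS:
            raise ValueError(f"unknown engine {engine!r}; expected one of {sorted(ENGINE_AGE_WINDOWS)}")
        age_window = ENGINE_AGE_WINDOWS[engine]
    lo, hi = age_window
    mask = (cohort.df["age"] >= lo) & (cohort.df["age"] <= hi)
    return Cohort(cohort.df[mask].reset_index(drop=True), has_outcomes=cohort.has_outcomes)


def map_outcome(icd_code: str) -> tuple[str, Optional[str]]:
    """Classify an ICD-10 code against the composite CVD outcome.

    Matching is on the 3-character category, so subcodes like ``I21.4`` map to
    ``I21``. Returns ``("composite_cvd", subtype_label)`` or ``("not_cvd", None)``.
    """
    if not icd_code:
        raise ValueError("icd_code must be a non-empty string")
    category = icd_code.strip().upper()[:3]
    if category in COMPOSITE_CODES:
        return "composite_cvd", SUBTYPE_LABELS[category]
    return "not_cvd", None


# ---------------------------------------------------------------------------
# Incidence rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncidenceEstimate:
    """Events per 100,000 person-years with an exact-Poisson confidence interval."""

    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


def incidence_rate(events: int, person_years: float, ci_level: float = 0.95) -> IncidenceEstimate:
    """Incidence per 100,000 person-years with the chi-square-quantile exact Poisson CI.

    The CI bounds on the count k are chi2.ppf(alpha/2, 2k)/2 and
    chi2.ppf(1-alpha/2, 2k+2)/2, then scaled by person-years.
    """
    if person_years <= 0:
        raise ValueError("person_years must be strictly positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    scale = 1e5 / person_years
    alpha = 1.0 - ci_level
    lo = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return IncidenceEstimate(
        events=int(events),
        person_years=float(person_years),
        rate=events * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
        ci_level=ci_level,
    )


def rate_ratio_test(a: IncidenceEstimate, b: IncidenceEstimate) -> float:
    """Two-sided exact test of equal incidence rates.

    Conditional on the total event count, the events in group *a* are binomial
    with success probability proportional to its person-years; the exact
    two-sided binomial test of that proportion is the standard two-sample
    Poisson rate comparison.
    """
    total = a.events + b.events
    if total == 0:
        return 1.0
    p0 = a.person_years / (a.person_years + b.person_years)
    return float(stats.binomtest(a.events, total, p0).pvalue)


# ---------------------------------------------------------------------------
# Reporting helpers (baseline-characteristics style flags)
# ---------------------------------------------------------------------------

def derive_hypertension(df: pd.DataFrame, sbp_threshold: float = 140.0) -> pd.Series:
    """Hypertension flag for descriptive tables: SBP >= threshold or treated."""
    return (df["sbp"] >= sbp_threshold) | df["bp_treated"].astype(bool)


def derive_t2dm(df: pd.DataFrame, glucose_threshold: float = 126.0) -> pd.Series:
    """Type-2 diabetes flag for descriptive tables: glucose >= threshold or diagnosed."""
    return (df["fasting_glucose"] >= glucose_threshold) | df["diabetes"].astype(bool)
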