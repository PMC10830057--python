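"""Synthetic claims-style cohorts with the statistical structure the analysis assumes.

Covariates are drawn from a Gaussian copula: correlated standard-normal
latents are mapped to each continuous covariate by an affine transform to its
target mean/SD, and to each binary flag by thresholding at the prevalence
quantile. The packaged parameter sets ``table1_male`` / ``table1_female``
transcribe the study population's published baseline characteristics
(means, SDs and prevalences by sex); the latent correlation matrix is
invented (no correlation data are published) and fully overridable.

Outcomes come from one of two generating modes:

- ``engine_true_risk``: a risk-equation spec acts as ground truth; each
  participant's event indicator is Bernoulli in their true 10-year risk, with
  the event time uniform on (0, 10].
- ``subtype_hazards``: competing constant-hazard exponential times per ICD-10
  subtype, first arrival before the horizon wins; defaults are calibrated so
  the subtype event-per-person-year rates equal the published incidence rates
  (``table2_subtype_hazards``).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import COHORT_COLUMNS, Cohort, ExclusionRules, FOLLOWUP_HORIZON
from .risk_engines import RiskEngineSpec, score_cohort

__all__ = [
    "CONTINUOUS_ORDER",
    "BINARY_ORDER",
    "CovariateSpec",
    "OutcomeSpec",
    "table1_male",
    "table1_female",
    "table2_incidence_rates",
    "table2_subtype_hazards",
    "default_correlation",
    "generate_covariates",
    "simulate_outcomes",
    "generate_raw_cohort",
]

CONTINUOUS_ORDER = (
    "age", "bmi", "fasting_glucose", "total_cholesterol",
    "ldl", "hdl", "triglycerides", "sbp",
)
BINARY_ORDER = ("smoker", "diabetes", "bp_treated")
LATENT_ORDER = CONTINUOUS_ORDER + BINARY_ORDER

#: floor applied to continuous draws so the strict-positivity record
#: invariant always holds; the normal location/scale are re-solved so the
#: clipped marginal keeps the target mean and SD exactly (material only for
#: triglycerides, whose published SD puts ~6% of an untruncated normal
#: below zero).
POSITIVE_FLOOR = 1.0


def _clipped_normal_params(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """(loc, scale) such that max(N(loc, scale), floor) has the target mean and SD.

    Closed-form moments of the floored normal (a = (c - loc)/scale):
    E[X]  = loc + scale * (a * Phi(a) + phi(a))
    E[X^2] = c^2 Phi(a) + (loc^2 + scale^2)(1 - Phi(a)) + (2 loc + a scale) scale phi(a)
    solved for (loc, scale) by a two-dimensional root find. When the floor is
    >5 SD below the mean the adjustment is numerically zero and the published
    parameters are returned unchanged.
    """
    if (mean - floor) / sd > 5.0:
        return mean, sd

    def moments(loc: float, scale: float) -> tuple[float, float]:
        a = (floor - loc) / scale
        cdf, pdf = stats.norm.cdf(a), stats.norm.pdf(a)
        m1 = loc + scale * (a * cdf + pdf)
        m2 = (floor**2) * cdf + (loc**2 + scale**2) * (1 - cdf) + (2 * loc + a * scale) * scale * pdf
        return m1, m2

    from scipy.optimize import root

    def residual(p):
        m1, m2 = moments(p[0], p[1])
        return [m1 - mean, np.sqrt(max(m2 - m1**2, 1e-12)) - sd]

    sol = root(residual, x0=[mean, sd], tol=1e-12)
    if not sol.success:  # pragma: no cover - smooth 2D system, converges
        raise RuntimeError(f"clipped-normal calibration failed for mean={mean}, sd={sd}")
    return float(sol.x[0]), float(sol.x[1])


def default_correlation() -> pd.DataFrame:
    """Invented latent correlation: modest metabolic-syndrome-style structure.

    Positive couplings among BMI/SBP/triglycerides/glucose, strong
    glucose-diabetes and SBP-treatment links, TC-LDL collinearity, negative
    HDL-triglycerides. Override freely; only symmetry and positive
    definiteness are required.
    """
    r = pd.DataFrame(np.eye(len(LATENT_ORDER)), index=LATENT_ORDER, columns=LATENT_ORDER)

    def s(a: str, b: str, v: float) -> None:
        r.loc[a, b] = r.loc[b, a] = v

    s("age", "sbp", 0.25); s("age", "fasting_glucose", 0.15)
    s("age", "total_cholesterol", 0.15); s("age", "bp_treated", 0.30)
    s("age", "diabetes", 0.20)
    s("bmi", "sbp", 0.25); s("bmi", "triglycerides", 0.30); s("bmi", "hdl", -0.25)
    s("bmi", "fasting_glucose", 0.20); s("bmi", "total_cholesterol", 0.20); s("bmi", "ldl", 0.20)
    s("fasting_glucose", "diabetes", 0.60); s("fasting_glucose", "triglycerides", 0.20)
    s("fasting_glucose", "sbp", 0.15)
    s("total_cholesterol", "ldl", 0.85); s("total_cholesterol", "hdl", 0.15)
    s("total_cholesterol", "triglycerides", 0.30)
    s("ldl", "triglycerides", 0.20)
    s("hdl", "triglycerides", -0.40)
    s("sbp", "bp_treated", 0.45)
    s("smoker", "hdl", -0.15); s("smoker", "triglycerides", 0.15)
    return r


@dataclass
class CovariateSpec:
    """Per-sex covariate marginals plus the latent correlation of the copula."""

    sex: Literal["male", "female"]
    means: dict[str, float]
    sds: dict[str, float]
    prevalences: dict[str, float]
    correlation: pd.DataFrame = field(default_factory=default_correlation)

    def __post_init__(self) -> None:
        missing = [c for c in CONTINUOUS_ORDER if c not in self.means or c not in self.sds]
        if missing:
            raise ValueError(f"means/sds missing for: {missing}")
        if any(self.sds[c] <= 0 for c in CONTINUOUS_ORDER):
            raise ValueError("all SDs must be strictly positive")
        for b in BINARY_ORDER:
            p = self.prevalences.get(b)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {b!r} must lie in [0, 1]")
        r = self.correlation.loc[list(LATENT_ORDER), list(LATENT_ORDER)].to_numpy(dtype=float)
        if not np.allclose(r, r.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        self._corr = r


def table1_male() -> CovariateSpec:
    """Packaged male parameter set (published baseline characteristics).

    ``bp_treated`` stands in for the published hypertension prevalence, since
    treatment prevalence itself is not reported.
    """
    return CovariateSpec(
        sex="male",
        means={"age": 42.5, "bmi": 23.7, "fasting_glucose": 92.4,
               "total_cholesterol": 193.1, "ldl": 115.2, "hdl": 51.9,
               "triglycerides": 149.0, "sbp": 123.4},
        sds={"age": 10.1, "bmi": 2.8, "fasting_glucose": 19.4,
             "total_cholesterol": 32.3, "ldl": 35.8, "hdl": 12.3,
             "triglycerides": 97.0, "sbp": 14.9},
        prevalences={"smoker": 0.448, "diabetes": 0.038,
                     "bp_treated": 0.062, "hypertension": 0.062},
    )


def table1_female() -> CovariateSpec:
    """Packaged female parameter set (published baseline characteristics)."""
    return CovariateSpec(
        sex="female",
        means={"age": 46.3, "bmi": 22.9, "fasting_glucose": 89.9,
               "total_cholesterol": 191.5, "ldl": 119.2, "hdl": 58.0,
               "triglycerides": 107.7, "sbp": 117.8},
        sds={"age": 9.9, "bmi": 2.9, "fasting_glucose": 17.2,
             "total_cholesterol": 34.0, "ldl": 34.7, "hdl": 13.0,
             "triglycerides": 64.4, "sbp": 16.6},
        prevalences={"smoker": 0.019, "diabetes": 0.030,
                     "bp_treated": 0.071, "hypertension": 0.071},
    )


#: published subtype incidence rates, events per 100,000 person-years
TABLE2_RATES: dict[str, dict[str, float]] = {
    "male": {"I63": 240.65, "I61": 24.73, "G45": 28.09, "I50": 14.63,
             "I48": 107.44, "I20": 117.42, "I21": 89.38, "I60": 12.26,
             "I46": 11.07, "I62": 9.88},
    "female": {"I63": 327.63, "I61": 23.94, "G45": 52.11, "I50": 23.93,
               "I48": 90.38, "I20": 118.73, "I21": 81.36, "I60": 20.04,
               "I46": 4.78, "I62": 4.78},
}


def table2_incidence_rates(sex: str) -> dict[str, float]:
    return dict(TABLE2_RATES[sex])


def table2_subtype_hazards(sex: str) -> dict[str, float]:
    """Constant per-person-year hazards calibrated to the published rates.

    Under competing constant hazards with administrative censoring, each
    subtype's events-per-person-year ratio equals its hazard exactly, so the
    calibration is simply rate / 100,000.
    """
    return {code: rate / 1e5 for code, rate in TABLE2_RATES[sex].items()}


@dataclass
class OutcomeSpec:
    """How 10-year outcomes are generated for a covariates-only cohort."""

    mode: Literal["engine_true_risk", "subtype_hazards"]
    engine_spec: Optional[RiskEngineSpec] = None
    subtype_hazards: Optional[Mapping[str, float]] = None
    subtype_shares: Optional[Mapping[str, float]] = None  # engine-mode code mix
    horizon: float = FOLLOWUP_HORIZON

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.mode == "engine_true_risk" and self.engine_spec is None:
            raise ValueError("engine_true_risk mode requires engine_spec")
        if self.mode == "subtype_hazards":
            if self.subtype_hazards is None:
                raise ValueError("subtype_hazards mode requires subtype_hazards")
            if any(h < 0 for h in self.subtype_hazards.values()):
                raise ValueError("hazards must be non-negative")


def generate_covariates(spec: CovariateSpec, n: int, seed: int) -> Cohort:
    """Draw a covariates-only cohort of size n from the Gaussian copula."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        np.zeros(len(LATENT_ORDER)), spec._corr, size=n, method="cholesky"
    )
    data: dict[str, object] = {}
    prefix = "M" if spec.sex == "male" else "F"
    data["id"] = [f"{prefix}{i:07d}" for i in range(n)]
    data["sex"] = spec.sex
    for j, c in enumerate(CONTINUOUS_ORDER):
        loc, scale = _clipped_normal_params(spec.means[c], spec.sds[c], POSITIVE_FLOOR)
        data[c] = np.maximum(loc + scale * z[:, j], POSITIVE_FLOOR)
    for j, b in enumerate(BINARY_ORDER, start=len(CONTINUOUS_ORDER)):
        data[b] = z[:, j] < stats.norm.ppf(spec.prevalences[b])
    data["prior_cvd"] = np.zeros(n, dtype=bool)
    df = pd.DataFrame(data)
    order = [c for c in COHORT_COLUMNS if c in df.columns]
    return Cohort(df[order], has_outcomes=False)


def simulate_outcomes(cohort: Cohort, spec: OutcomeSpec, seed: int) -> Cohort:
    """Attach event, event_code and followup_years to a covariates-only cohort."""
    if cohort.has_outcomes:
        raise ValueError("cohort already carries outcomes")
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    n = len(df)
    if spec.mode == "engine_true_risk":
        risk = score_cohort(df, spec.engine_spec)["risk"].to_numpy()
        event = rng.random(n) < risk
        time = np.full(n, spec.horizon)
        # uniform event timing: immaterial to the binary 10-year evaluation
        time[event] = spec.horizon * (1.0 - rng.random(int(event.sum())))
        shares = dict(_engine_mode_shares(spec, df))
        codes_pool = list(shares)
        p = np.array([shares[c] for c in codes_pool], dtype=float)
        p = p / p.sum()
        codes = np.full(n, "", dtype=object)
        codes[event] = rng.choice(codes_pool, size=int(event.sum()), p=p)
    else:
        hz = {c: h for c, h in spec.subtype_hazards.items()}
        codes_pool = list(hz)
        lam = np.array([hz[c] for c in codes_pool], dtype=float)
        times = np.full((n, len(codes_pool)), np.inf)
        pos = lam > 0
        if pos.any():
            times[:, pos] = rng.exponential(1.0 / lam[pos], size=(n, int(pos.sum())))
        first = times.min(axis=1)
        event = first < spec.horizon
        time = np.where(event, first, spec.horizon)
        codes = np.full(n, "", dtype=object)
        if event.any():
            winner = times[event].argmin(axis=1)
            codes[event] = np.array(codes_pool, dtype=object)[winner]
    df["event"] = event
    df["event_code"] = codes
    df["followup_years"] = time
    return Cohort(df, has_outcomes=True)


def _engine_mode_shares(spec: OutcomeSpec, df: pd.DataFrame) -> Mapping[str, float]:
    """Engine-mode subtype mix: explicit shares, else the sex's published event mix."""
    if spec.subtype_shares is not None:
        return spec.subtype_shares
    sex = str(df["sex"].iloc[0])
    return table2_incidence_rates(sex)


PLANT_KEYS = ("under_age", "prior_cvd", "tc_outlier", "hdl_outlier",
              "bmi_outlier", "ldl_outlier", "tg_outlier")


def generate_raw_cohort(
    spec: CovariateSpec,
    n: int,
    planted: Mapping[str, float],
    seed: int,
    rules: ExclusionRules | None = None,
) -> Cohort:
    """A pre-filter cohort with exact planted fractions of each exclusion class.

    The base draw is clamped inside all rule thresholds so that the planted
    counts are the only violations (this biases the clamped marginals, which
    is irrelevant here: the raw cohort exists to exercise the filter cascade,
    not the moment targets). Counts are ``round(fraction * n)``, the planted
    groups are disjoint, and the result is covariates-only — outcomes are
    simulated after the filters, as in the study design.
    """
    unknown = set(planted) - set(PLANT_KEYS)
    if unknown:
        raise ValueError(f"unknown planted classes: {sorted(unknown)}")
    counts = {k: int(round(planted.get(k, 0.0) * n)) for k in PLANT_KEYS}
    if any(v < 0 for v in counts.values()) or sum(counts.values()) > n:
        raise ValueError("planted fractions must be non-negative and sum to <= 1")
    rules = rules or ExclusionRules()
    rng = np.random.default_rng(seed)
    cohort = generate_covariates(spec, n, seed=int(rng.integers(2**31)))
    df = cohort.df
    # clamp the base inside every rule so violations are exactly the planted ones
    df["age"] = df["age"].clip(lower=rules.min_age)
    df["total_cholesterol"] = df["total_cholesterol"].clip(upper=rules.total_cholesterol_max)
    df["hdl"] = df["hdl"].clip(upper=rules.hdl_max)
    df["bmi"] = df["bmi"].clip(upper=rules.bmi_max)
    df["ldl"] = df["ldl"].clip(upper=rules.ldl_max)
    df["triglycerides"] = df["triglycerides"].clip(upper=rules.triglycerides_max)
    perm = rng.permutation(n)
    start = 0
    for key in PLANT_KEYS:
        idx = perm[start:start + counts[key]]
        start += counts[key]
        if key == "under_age":
            df.loc[idx, "age"] = rng.uniform(max(1.0, rules.min_age - 12), rules.min_age - 0.5, len(idx))
        elif key == "prior_cvd":
            df.loc[idx, "prior_cvd"] = True
        elif key == "tc_outlier":
            df.loc[idx, "total_cholesterol"] = rng.uniform(rules.total_cholesterol_max + 1, rules.total_cholesterol_max + 100, len(idx))
        elif key == "hdl_outlier":
            df.loc[idx, "hdl"] = rng.uniform(rules.hdl_max + 1, rules.hdl_max + 50, len(idx))
        elif key == "bmi_outlier":
            df.loc[idx, "bmi"] = rng.uniform(rules.bmi_max + 1, rules.bmi_max + 20, len(idx))
        elif key == "ldl_outlier":
            df.loc[idx, "ldl"] = rng.uniform(rules.ldl_max + 1, rules.ldl_max + 200, len(idx))
        elif key == "tg_outlier":
            df.loc[idx, "triglycerides"] = rng.uniform(rules.triglycerides_max + 1, rules.triglycerides_max + 500, len(idx))
    return Cohort(df, has_outcomes=False)
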