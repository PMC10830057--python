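"""Sex-specific 10-year CVD risk equations as data-driven coefficient tables.

Both engines share one functional form: a linear predictor
``L = sum_k beta_k * f_k(x) - mean_lp`` over transformed covariates, and
``risk = 1 - S0 ** exp(L)`` with S0 the 10-year baseline (mean-profile)
survival. The Framingham general-CVD equations use log-transformed
covariates and 0/1 indicators; the pooled cohort equations (ASCVD) add
age-squared and age-interaction terms. Coefficients are packaged as CSV
tables (see ``data/coefficients/README.md`` for provenance) so transcription
is auditable, and a ``transfer_spec`` relabeling supports scoring one sex's
cohort with the other sex's coefficients — the cross-sex transfer experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from io import StringIO
from typing import Literal

import numpy as np
import pandas as pd

from .cohort_model import Cohort, ParticipantRecord

__all__ = [
    "Term",
    "RiskEngineSpec",
    "RiskPrediction",
    "builtin_spec",
    "linear_predictor",
    "predict_risk",
    "score_cohort",
    "transfer_spec",
]

logger = logging.getLogger(__name__)

TRANSFORMS = ("ln", "identity", "ln_square", "product_of_lns", "ln_times_identity")
CONDITIONS = ("", "bp_treated", "not_bp_treated")

#: covariate ranges the engines were developed on; values outside are scored
#: as-is with a logged warning (no truncation rule is applied).
DEVELOPMENT_RANGES = {
    "age": (30.0, 79.0),
    "total_cholesterol": (100.0, 405.0),
    "hdl": (10.0, 100.0),
    "sbp": (80.0, 200.0),
}


@dataclass(frozen=True)
class Term:
    """One additive term of a risk equation's linear predictor.

    ``covariates`` holds one or two record field names depending on the
    transform; ``condition`` restricts the term to treated or untreated
    records so that exactly one of an SBP term pair fires per record.
    """

    name: str
    covariates: tuple[str, ...]
    transform: Literal["ln", "identity", "ln_square", "product_of_lns", "ln_times_identity"]
    beta: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        need = 2 if self.transform in ("product_of_lns", "ln_times_identity") else 1
        if len(self.covariates) != need:
            raise ValueError(
                f"term {self.name!r}: transform {self.transform} takes {need} covariate(s)"
            )
        if not np.isfinite(self.beta):
            raise ValueError(f"term {self.name!r}: beta must be finite")

    def values(self, df: pd.DataFrame) -> np.ndarray:
        """Evaluate beta * f(x) for every row (condition applied as 0/1 gate)."""
        f = self._feature(df)
        if self.condition == "bp_treated":
            f = f * df["bp_treated"].to_numpy(dtype=float)
        elif self.condition == "not_bp_treated":
            f = f * (1.0 - df["bp_treated"].to_numpy(dtype=float))
        return self.beta * f

    def _feature(self, df: pd.DataFrame) -> np.ndarray:
        cols = [df[c].to_numpy(dtype=float) for c in self.covariates]
        if self.transform in ("ln", "ln_square", "product_of_lns", "ln_times_identity"):
            x = cols[0]
            if np.any(x <= 0):
                raise ValueError(
                    f"term {self.name!r}: ln transform needs strictly positive "
                    f"{self.covariates[0]!r}"
                )
        if self.transform == "ln":
            return np.log(cols[0])
        if self.transform == "identity":
            return cols[0]
        if self.transform == "ln_square":
            return np.log(cols[0]) ** 2
        if self.transform == "product_of_lns":
            y = cols[1]
            if np.any(y <= 0):
                raise ValueError(
                    f"term {self.name!r}: ln transform needs strictly positive "
                    f"{self.covariates[1]!r}"
                )
            return np.log(cols[0]) * np.log(y)
        # ln_times_identity: ln(first) times a 0/1 indicator
        return np.log(cols[0]) * cols[1]


@dataclass(frozen=True)
class RiskEngineSpec:
    """A parameterized risk equation: terms, mean offset, baseline survival."""

    engine: str
    sex: Literal["male", "female"]
    terms: tuple[Term, ...]
    mean_lp: float
    baseline_survival: float

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("terms must be non-empty")
        if not (0.0 < self.baseline_survival < 1.0):
            raise ValueError("baseline_survival must lie in (0, 1)")
        if not np.isfinite(self.mean_lp):
            raise ValueError("mean_lp must be finite")

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    # -- serialization (same layout as the packaged CSV tables) -------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.name,
                "covariates": "|".join(t.covariates),
                "transform": t.transform,
                "condition": t.condition,
                "beta": t.beta,
            }
            for t in self.terms
        ]
        rows.append({"term": "mean_lp", "covariates": "", "transform": "meta",
                     "condition": "", "beta": self.mean_lp})
        rows.append({"term": "baseline_survival", "covariates": "", "transform": "meta",
                     "condition": "", "beta": self.baseline_survival})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # shortest-repr floats: bit-exact round-trip through read_csv
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, engine: str, sex: str) -> "RiskEngineSpec":
        df = df.fillna({"covariates": "", "condition": ""})
        meta = df[df["transform"] == "meta"].set_index("term")["beta"]
        terms = tuple(
            Term(
                name=r["term"],
                covariates=tuple(c for c in str(r["covariates"]).split("|") if c),
                transform=r["transform"],
                condition=str(r["condition"]),
                beta=float(r["beta"]),
            )
            for _, r in df[df["transform"] != "meta"].iterrows()
        )
        return cls(
            engine=engine,
            sex=sex,  # type: ignore[arg-type]
            terms=terms,
            mean_lp=float(meta["mean_lp"]),
            baseline_survival=float(meta["baseline_survival"]),
        )

    @classmethod
    def from_csv(cls, path, engine: str = "custom", sex: str = "male") -> "RiskEngineSpec":
        return cls.from_frame(pd.read_csv(path), engine, sex)


@dataclass(frozen=True)
class RiskPrediction:
    id: str
    linear_predictor: float
    risk: float


def builtin_spec(engine: Literal["framingham", "ascvd"], sex: Literal["male", "female"]) -> RiskEngineSpec:
    """Load the packaged coefficient table for an engine/sex pair."""
    if engine not in ("framingham", "ascvd") or sex not in ("male", "female"):
        raise ValueError(f"unknown engine/sex combination ({engine!r}, {sex!r})")
    ref = resources.files("cvdval").joinpath(f"data/coefficients/{engine}_{sex}.csv")
    df = pd.read_csv(StringIO(ref.read_text()))
    return RiskEngineSpec.from_frame(df, engine, sex)


def _as_frame(record_or_cohort) -> pd.DataFrame:
    if isinstance(record_or_cohort, Cohort):
        return record_or_cohort.df
    if isinstance(record_or_cohort, ParticipantRecord):
        return pd.DataFrame([record_or_cohort.model_dump()])
    if isinstance(record_or_cohort, pd.DataFrame):
        return record_or_cohort
    raise TypeError(f"expected ParticipantRecord, Cohort or DataFrame, got {type(record_or_cohort)}")


def _warn_out_of_range(df: pd.DataFrame) -> None:
    for cov, (lo, hi) in DEVELOPMENT_RANGES.items():
        if cov in df.columns:
            n = int(((df[cov] < lo) | (df[cov] > hi)).sum())
            if n:
                logger.warning(
                    "%d record(s) have %s outside the engines' development range "
                    "[%g, %g]; scored as-is", n, cov, lo, hi,
                )


def linear_predictor(record_or_cohort, spec: RiskEngineSpec) -> np.ndarray | float:
    """Mean-centered linear predictor L = sum(beta*f) - mean_lp.

    Scalar for a single record, ndarray for a cohort/DataFrame.
    """
    df = _as_frame(record_or_cohort)
    _warn_out_of_range(df)
    lp = np.zeros(len(df))
    for t in spec.terms:
        lp += t.values(df)
    lp -= spec.mean_lp
    if isinstance(record_or_cohort, ParticipantRecord):
        return float(lp[0])
    return lp


def _risk_from_lp(lp: np.ndarray, s0: float) -> np.ndarray:
    # clamp guards only against floating-point spill of the closed form
    return np.clip(1.0 - s0 ** np.exp(lp), 0.0, 1.0)


def predict_risk(record: ParticipantRecord, spec: RiskEngineSpec) -> RiskPrediction:
    """10-year risk = 1 - S0^exp(L) for a single participant."""
    lp = linear_predictor(record, spec)
    risk = float(_risk_from_lp(np.array([lp]), spec.baseline_survival)[0])
    return RiskPrediction(id=record.id, linear_predictor=lp, risk=risk)


def score_cohort(cohort: Cohort | pd.DataFrame, spec: RiskEngineSpec) -> pd.DataFrame:
    """Score every record; returns columns id, linear_predictor, risk."""
    df = _as_frame(cohort)
    lp = linear_predictor(df, spec)
    return pd.DataFrame(
        {
            "id": df["id"].to_numpy(),
            "linear_predictor": lp,
            "risk": _risk_from_lp(lp, spec.baseline_survival),
        }
    )


def transfer_spec(source: RiskEngineSpec, target_sex: Literal["male", "female"]) -> RiskEngineSpec:
    """Relabel a spec for the other sex, keeping terms, mean_lp and S0 unchanged.

    Scoring a female cohort with ``transfer_spec(male_spec, "female")`` is the
    coefficient-transfer experiment: numerically identical to scoring the same
    covariate values under the male equation.
    """
    if target_sex == source.sex:
        return source
    return replace(source, sex=target_sex)
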