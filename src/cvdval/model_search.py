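"""Data-driven Cox modelling: fits, exhaustive subset search, covariate importance.

The data-driven benchmark model is a Cox proportional-hazards fit over
log-transformed covariates (the engine covariates plus LDL, triglycerides,
fasting glucose and BMI), turned into a 10-year risk equation of the same
``1 - S0^exp(L - mean_lp)`` form as the packaged engines. Model selection
enumerates every non-empty covariate subset under seeded, event-stratified
5-fold cross-validation and keeps the subset with the highest cross-validated
AUC. Covariate importance is the leave-one-term-out share of linear-predictor
variance: ``100 * (Var(L) - Var(L minus term j)) / Var(L)``; under correlated
covariates shares can be negative and need not sum to 100, and are reported
as computed.

Partial-likelihood maximization and the Breslow baseline cumulative hazard
are delegated to ``statsmodels`` ``PHReg`` (Breslow ties by default, Efron by
option) behind this module's surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg

from .cohort_model import Cohort
from .evaluation import auc as _pooled_auc
from .risk_engines import RiskEngineSpec, Term

__all__ = [
    "CoxFit",
    "PoolEntry",
    "ModelSearchResult",
    "ImportanceTable",
    "default_candidate_pool",
    "fit_cox",
    "predict_risk_10y",
    "cv_subset_search",
    "variance_importance",
]

MAX_POOL = 20
HORIZON = 10.0


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox model packaged as a 10-year risk equation."""

    terms: tuple[Term, ...]          # design terms (beta field unused, kept 1.0)
    coefficients: np.ndarray         # fitted log-hazard ratios, aligned to terms
    standard_errors: np.ndarray
    baseline_survival_10y: float     # S(10) at the mean linear predictor
    mean_lp: float                   # mean of X @ coef over the fitting cohort
    convergence: Literal["converged", "max_iter"]
    log_partial_likelihood: float
    null_log_partial_likelihood: float
    ties: str = "breslow"

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def to_spec(self, sex: str = "male") -> RiskEngineSpec:
        """Repackage as a custom RiskEngineSpec usable by the scoring pipeline."""
        terms = tuple(
            replace(t, beta=float(c)) for t, c in zip(self.terms, self.coefficients)
        )
        return RiskEngineSpec(
            engine="custom",
            sex=sex,  # type: ignore[arg-type]
            terms=terms,
            mean_lp=self.mean_lp,
            baseline_survival=self.baseline_survival_10y,
        )


@dataclass(frozen=True)
class PoolEntry:
    """One selectable unit of the subset search.

    Usually a single term; the systolic-blood-pressure entry groups the
    treated/untreated conditional pair so both enter or leave together.
    """

    name: str
    terms: tuple[Term, ...]


def _t(name: str, covs: tuple[str, ...], transform: str, condition: str = "") -> Term:
    return Term(name=name, covariates=covs, transform=transform,  # type: ignore[arg-type]
                condition=condition, beta=1.0)


def default_candidate_pool() -> list[PoolEntry]:
    """The engine covariates plus LDL, triglycerides, glucose and BMI.

    All continuous covariates enter on the log scale, age also as
    log-age-squared, SBP as the treated/untreated conditional pair.
    """
    singles = [
        ("ln_age", ("age",), "ln"),
        ("ln_age_square", ("age",), "ln_square"),
        ("ln_total_cholesterol", ("total_cholesterol",), "ln"),
        ("ln_hdl", ("hdl",), "ln"),
        ("smoker", ("smoker",), "identity"),
        ("diabetes", ("diabetes",), "identity"),
        ("ln_bmi", ("bmi",), "ln"),
        ("ln_ldl", ("ldl",), "ln"),
        ("ln_triglycerides", ("triglycerides",), "ln"),
        ("ln_glucose", ("fasting_glucose",), "ln"),
    ]
    pool = [PoolEntry(n, (_t(n, c, tr),)) for n, c, tr in singles]
    pool.insert(
        4,
        PoolEntry(
            "ln_sbp",
            (
                _t("ln_sbp_treated", ("sbp",), "ln", "bp_treated"),
                _t("ln_sbp_untreated", ("sbp",), "ln", "not_bp_treated"),
            ),
        ),
    )
    return pool


def _design(df: pd.DataFrame, terms: Sequence[Term]) -> np.ndarray:
    cols = [replace(t, beta=1.0).values(df) for t in terms]
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def fit_cox(cohort: Cohort | pd.DataFrame, terms: Sequence[Term], ties: str = "breslow") -> CoxFit:
    """Fit a Cox proportional-hazards model on (followup_years, event).

    Zero-variance design columns carry no partial-likelihood information and
    are fixed at coefficient 0. The 10-year baseline survival is the Breslow
    estimate evaluated at the mean linear predictor.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    time = df["followup_years"].to_numpy(dtype=float)
    status = df["event"].to_numpy(dtype=float)
    if status.sum() == 0:
        raise ValueError("cannot fit a Cox model on a cohort with no events")
    X = _design(df, terms)
    keep = X.std(axis=0) > 0
    coef = np.zeros(X.shape[1])
    se = np.zeros(X.shape[1])
    if keep.any():
        model = PHReg(time, X[:, keep], status=status, ties=ties)
        res = model.fit(disp=False)
        coef[keep] = res.params
        se[keep] = res.bse
        gnorm = float(np.linalg.norm(model.score(res.params))) / len(df)
        convergence = "converged" if gnorm < 1e-6 else "max_iter"
        llf = float(model.loglike(res.params))
        null_llf = float(model.loglike(np.zeros(int(keep.sum()))))
        times, cumhaz, _ = res.baseline_cumulative_hazard[0]
        pos = np.searchsorted(times, HORIZON, side="right") - 1
        h0_10 = float(cumhaz[pos]) if pos >= 0 else 0.0
    else:
        # degenerate all-constant design: null model
        model = PHReg(time, np.zeros((len(df), 1)), status=status, ties=ties)
        null_llf = llf = float(model.loglike(np.zeros(1)))
        convergence = "converged"
        # Breslow-Nelson-Aalen baseline from the null model
        order = np.argsort(time)
        t_sorted, s_sorted = time[order], status[order]
        at_risk = len(time) - np.arange(len(time))
        h0_10 = float(np.sum(s_sorted[t_sorted <= HORIZON] / at_risk[t_sorted <= HORIZON]))
    mean_lp = float((X @ coef).mean())
    s0 = float(np.exp(-h0_10 * np.exp(mean_lp)))
    s0 = min(max(s0, 1e-12), 1.0 - 1e-12)
    return CoxFit(
        terms=tuple(terms),
        coefficients=coef,
        standard_errors=se,
        baseline_survival_10y=s0,
        mean_lp=mean_lp,
        convergence=convergence,
        log_partial_likelihood=llf,
        null_log_partial_likelihood=null_llf,
        ties=ties,
    )


def predict_risk_10y(fit: CoxFit, cohort: Cohort | pd.DataFrame) -> np.ndarray:
    """10-year risk 1 - S0^exp(L - mean_lp) from a fitted Cox model."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    lp = _design(df, fit.terms) @ fit.coefficients
    return np.clip(1.0 - fit.baseline_survival_10y ** np.exp(lp - fit.mean_lp), 0.0, 1.0)


def _stratified_folds(event: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded event-stratified fold ids: every fold sees events and non-events."""
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(event), dtype=int)
    for cls in (True, False):
        idx = np.nonzero(event == cls)[0]
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    return fold_id


@dataclass(frozen=True)
class ModelSearchResult:
    pool: tuple[str, ...]
    best_subset: tuple[str, ...]
    per_fold_auc: tuple[float, ...]
    mean_cv_auc: float                    # selection statistic of the winner
    final_fit: CoxFit
    n_subsets: int
    leaderboard: pd.DataFrame             # subset -> cv auc, all candidates
    selection: str = "pooled"


def cv_subset_search(
    cohort: Cohort | pd.DataFrame,
    pool: Sequence[PoolEntry] | None = None,
    folds: int = 5,
    seed: int = 0,
    selection: str = "pooled",
    force: bool = False,
    ties: str = "breslow",
) -> ModelSearchResult:
    """Exhaustive covariate-subset search maximizing cross-validated AUC.

    Every one of the ``2^|pool| - 1`` non-empty subsets is fit on each
    train split and scored on the held-out fold as a 10-year risk; the
    subset AUC pools all out-of-fold predictions (``selection="fold_mean"``
    averages per-fold AUCs instead). Ties prefer smaller subsets, then
    lexicographic order. The winner is refit on the full cohort.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    pool = list(default_candidate_pool() if pool is None else pool)
    if not pool:
        raise ValueError("candidate pool must be non-empty")
    if len(pool) > MAX_POOL and not force:
        raise ValueError(
            f"pool of {len(pool)} entries implies 2^{len(pool)}-1 subsets; "
            "pass force=True to proceed"
        )
    if selection not in ("pooled", "fold_mean"):
        raise ValueError(f"unknown selection rule {selection!r}")
    event = df["event"].to_numpy(dtype=bool)
    fold_id = _stratified_folds(event, folds, seed)
    if any(event[fold_id == k].sum() == 0 for k in range(folds)):
        raise ValueError("every fold must contain at least one event")

    # cache per-fold fits keyed by subset so each subset costs `folds` fits
    rows = []
    best = None
    for size in range(1, len(pool) + 1):
        for combo in itertools.combinations(range(len(pool)), size):
            names = tuple(pool[i].name for i in combo)
            terms = tuple(t for i in combo for t in pool[i].terms)
            preds = np.empty(len(df))
            fold_aucs = []
            for k in range(folds):
                test = fold_id == k
                fit = fit_cox(df[~test], terms, ties=ties)
                preds[test] = predict_risk_10y(fit, df[test])
                fold_aucs.append(_pooled_auc(preds[test], event[test]))
            cv_auc = _pooled_auc(preds, event) if selection == "pooled" else float(np.mean(fold_aucs))
            rows.append({"subset": names, "size": size, "cv_auc": cv_auc})
            key = (-cv_auc, size, names)  # max auc, then smaller, then lexicographic
            if best is None or key < best[0]:
                best = (key, names, terms, tuple(fold_aucs), cv_auc)
    _, names, terms, fold_aucs, cv_auc = best
    leaderboard = pd.DataFrame(rows).sort_values("cv_auc", ascending=False).reset_index(drop=True)
    return ModelSearchResult(
        pool=tuple(p.name for p in pool),
        best_subset=names,
        per_fold_auc=fold_aucs,
        mean_cv_auc=float(cv_auc),
        final_fit=fit_cox(df, terms, ties=ties),
        n_subsets=len(rows),
        leaderboard=leaderboard,
        selection=selection,
    )


@dataclass(frozen=True)
class ImportanceTable:
    model: str
    sex: str
    rows: pd.DataFrame  # columns: term, variance_share (percent)

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(0, "model", self.model)
        out.insert(1, "sex", self.sex)
        return out


def variance_importance(
    fit_or_spec: CoxFit | RiskEngineSpec,
    cohort: Cohort | pd.DataFrame,
    model_label: str | None = None,
) -> ImportanceTable:
    """Leave-one-term-out variance shares of the linear predictor.

    share(j) = 100 * (Var(L) - Var(L - contribution_j)) / Var(L), computed
    over the cohort with coefficients held fixed. Interaction terms and each
    conditional SBP term are scored as separate rows.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if len(df) == 0:
        raise ValueError("cohort must be non-empty")
    if isinstance(fit_or_spec, CoxFit):
        contrib = _design(df, fit_or_spec.terms) * fit_or_spec.coefficients
        names = fit_or_spec.term_names()
        label = model_label or "data_driven"
        sex = str(df["sex"].iloc[0]) if "sex" in df else "all"
    else:
        contrib = np.column_stack([t.values(df) for t in fit_or_spec.terms])
        names = fit_or_spec.term_names()
        label = model_label or fit_or_spec.engine
        sex = fit_or_spec.sex
    L = contrib.sum(axis=1)
    var_l = float(np.var(L))
    if var_l == 0:
        raise ValueError("degenerate model: linear predictor has zero variance")
    shares = [
        100.0 * (var_l - float(np.var(L - contrib[:, j]))) / var_l
        for j in range(contrib.shape[1])
    ]
    rows = pd.DataFrame({"term": names, "variance_share": shares})
    return ImportanceTable(model=label, sex=sex, rows=rows)
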