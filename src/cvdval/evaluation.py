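"""Discrimination and calibration statistics for 10-year binary outcomes.

AUC with the DeLong structural-component variance, the paired DeLong test for
two correlated AUCs on the same subjects, the Hosmer-Lemeshow decile
goodness-of-fit chi-square, and the Youden-optimal sensitivity/specificity
operating point. The outcome is treated as a plain binary label at the
10-year horizon (the study design administratively censors all non-events at
exactly 10 years, so no survival weighting is needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "DelongComparison",
    "CalibrationBin",
    "CalibrationReport",
    "auc",
    "roc_auc",
    "delong_test",
    "hosmer_lemeshow",
    "operating_point",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    sensitivity: float  # percent, at the Youden-optimal threshold
    specificity: float  # percent
    threshold: float


@dataclass(frozen=True)
class DelongComparison:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_value: float


@dataclass(frozen=True)
class CalibrationBin:
    n: int
    mean_predicted_risk: float
    expected_events: float
    observed_events: int


@dataclass(frozen=True)
class CalibrationReport:
    bins: tuple[CalibrationBin, ...]
    chi_square: float
    df: int
    p_value: float
    overall_predicted_pct: float
    overall_observed_pct: float
    variant: str = "hosmer-lemeshow"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "decile": np.arange(1, len(self.bins) + 1),
                "n": [b.n for b in self.bins],
                "mean_predicted_risk": [b.mean_predicted_risk for b in self.bins],
                "expected_events": [b.expected_events for b in self.bins],
                "observed_events": [b.observed_events for b in self.bins],
            }
        )


def _check_labels(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both event and non-event labels are required")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (per-positive) and V01 (per-negative) structural components.

    The midrank formulation: with m positives and n negatives,
    AUC = (sum of positive midranks - m(m+1)/2) / (mn); V10_i is the fraction
    of negatives each positive outranks (ties 1/2), V01_j the complement.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = all_r[:m], all_r[m:]
    auc = (pos_r.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (pos_r - _midrank(pos)) / n
    v01 = 1.0 - (neg_r - _midrank(neg)) / m
    return float(auc), v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Plain Mann-Whitney AUC (ties counted 1/2), without variance machinery."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_labels(y)
    r = _midrank(s)
    m = int(y.sum())
    n = len(y) - m
    return float((r[y].sum() - m * (m + 1) / 2) / (m * n))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """AUC (Mann-Whitney, ties 1/2) with DeLong SE and Wald 95% CI.

    Also reports the Youden-optimal operating point, percent scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    _check_labels(y)
    auc, v10, v01 = _delong_components(s, y)
    se = float(np.sqrt(_auc_variance(v10, v01)))
    z = stats.norm.ppf(0.975)
    sens, spec, thr = operating_point(s, y)
    return RocResult(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
    )


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> DelongComparison:
    """Paired DeLong test of two correlated AUCs computed on the same subjects."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    _check_labels(y)
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    var_a = _auc_variance(v10_a, v01_a)
    var_b = _auc_variance(v10_b, v01_b)
    cov = 0.0
    if m > 1:
        cov += np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    var_diff = var_a + var_b - 2 * cov
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            z = 0.0
        else:
            raise ValueError("degenerate DeLong comparison: zero variance with unequal AUCs")
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongComparison(
        auc_a=auc_a, auc_b=auc_b, var_a=float(var_a), var_b=float(var_b),
        cov_ab=float(cov), z=float(z), p_value=p,
    )


def _decile_bins(pred: np.ndarray, bins: int) -> np.ndarray:
    """Bin ids (0..bins-1) from rank cuts, tied predictions kept in the lower bin."""
    n = len(pred)
    order = np.argsort(pred, kind="mergesort")
    tentative = np.floor(np.arange(n) * bins / n).astype(int)
    sorted_pred = pred[order]
    # walk tie groups: every member takes the bin of the group's first element
    bin_sorted = tentative.copy()
    start = 0
    for i in range(1, n + 1):
        if i == n or sorted_pred[i] != sorted_pred[start]:
            bin_sorted[start:i] = tentative[start]
            start = i
    out = np.empty(n, dtype=int)
    out[order] = bin_sorted
    return out


def hosmer_lemeshow(
    predictions: Sequence[float],
    labels: Sequence[bool],
    bins: int = 10,
    variant: str = "hosmer-lemeshow",
) -> CalibrationReport:
    """Decile calibration table and goodness-of-fit chi-square.

    Records are sorted by predicted risk and cut into ``bins`` near-equal
    groups (ties kept together in the lower group). Per group g with n_g
    records, observed events O_g and expected events E_g = n_g * mean risk:

    - ``variant="hosmer-lemeshow"``: chi2 = sum (O-E)^2 / (E (1 - E/n_g))
    - ``variant="pearson"``:         chi2 = sum (O-E)^2 / E

    p-value from the chi-square distribution with ``bins - 2`` df.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if len(p) < bins:
        raise ValueError("cohort smaller than the number of bins")
    if variant not in ("hosmer-lemeshow", "pearson"):
        raise ValueError(f"unknown variant {variant!r}")
    bin_id = _decile_bins(p, bins)
    out_bins: list[CalibrationBin] = []
    chi2 = 0.0
    for g in range(bins):
        mask = bin_id == g
        n_g = int(mask.sum())
        if n_g == 0:
            out_bins.append(CalibrationBin(0, float("nan"), 0.0, 0))
            continue
        mean_risk = float(p[mask].mean())
        e = n_g * mean_risk
        o = int(y[mask].sum())
        out_bins.append(CalibrationBin(n_g, mean_risk, e, o))
        if variant == "hosmer-lemeshow":
            denom = e * (1.0 - e / n_g)
        else:
            denom = e
        if denom <= 0:
            if o != e:
                warnings.warn(
                    f"calibration bin {g + 1} has zero expected-event variance with "
                    f"O={o}; chi-square is infinite",
                    RuntimeWarning,
                )
                chi2 = float("inf")
            continue
        chi2 += (o - e) ** 2 / denom
    df = bins - 2
    if not np.isfinite(chi2):
        p_value = 0.0
    elif df < 1:  # two-bin toy case: the statistic has no free bins left
        p_value = 1.0 if chi2 == 0 else 0.0
    else:
        p_value = float(stats.chi2.sf(chi2, df))
    n = len(p)
    return CalibrationReport(
        bins=tuple(out_bins),
        chi_square=float(chi2),
        df=df,
        p_value=p_value,
        overall_predicted_pct=100.0 * float(p.mean()),
        overall_observed_pct=100.0 * float(y.mean()),
        variant=variant,
    )


def operating_point(scores: Sequence[float], labels: Sequence[bool]) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, threshold) maximizing Youden's J.

    Scans every observed score as a ">= threshold" classification rule plus
    the all-negative rule; ties on J are broken toward higher sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_labels(y)
    m = int(y.sum())
    n = len(y) - m
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # ">= threshold" rules: evaluate at the last index of each equal-score run
    run_end = np.nonzero(np.append(s_sorted[1:] != s_sorted[:-1], True))[0]
    sens = np.append(tp[run_end] / m, 0.0)
    spec = np.append(1.0 - fp[run_end] / n, 1.0)  # trailing all-negative rule
    thr = np.append(s_sorted[run_end], np.inf)
    j = sens + spec - 1.0
    best = np.lexsort((sens, j))[-1]  # max J, ties toward higher sensitivity
    return 100.0 * float(sens[best]), 100.0 * float(spec[best]), float(thr[best])
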