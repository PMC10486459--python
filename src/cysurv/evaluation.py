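"""ROC/AUC analysis, paired AUC comparison, cutoffs and Kaplan-Meier curves.

AUC is computed by the Mann-Whitney identity (ties credited 0.5) with the
Hanley-McNeil standard error; paired models are compared with the DeLong
covariance-based z-test; family-wise error over multiple comparisons is
controlled by Bonferroni adjustment. Patients are stratified into predicted
groups at the least-misclassification score cutoff, and group survival is
summarized with Kaplan-Meier product-limit curves and the two-sample
log-rank test (via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .datatypes import ContractError, EvaluationError

__all__ = [
    "ROCResult",
    "AUCComparison",
    "KMResult",
    "roc_auc",
    "compare_aucs",
    "bonferroni_adjust",
    "cutoff_least_misclassification",
    "km_logrank",
]


@dataclass
class ROCResult:
    auc: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class AUCComparison:
    label: str
    auc_a: float
    auc_b: float
    delta_auc: float
    p_value: float
    adjusted_alpha: float
    significant: bool


@dataclass
class KMResult:
    """Per-group product-limit curves and the two-sample log-rank test."""

    curves: dict[str, pd.DataFrame]  # time, at_risk, events, survival
    statistic: float
    p_value: float
    cutoff: float | None = None
    degenerate: bool = False
    group_sizes: dict[str, int] = field(default_factory=dict)


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("labels must contain both classes")
    if n_pos + n_neg != labels.size:
        raise EvaluationError("labels must be binary 0/1")
    return n_pos, n_neg


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = sps.rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores, labels) -> ROCResult:
    """AUC by the Mann-Whitney identity with Hanley-McNeil standard error.

    ROC points are reported at every distinct threshold; the trapezoidal
    integral of those points equals the Mann-Whitney AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ContractError("scores and labels must have equal length")
    n_pos, n_neg = _check_binary(labels)
    auc = _mann_whitney_auc(scores, labels)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        auc=float(auc), se=float(np.sqrt(max(var, 0.0))),
        fpr=fpr, tpr=tpr, thresholds=thr, n_pos=n_pos, n_neg=n_neg,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def compare_aucs(scores_a, scores_b, labels, label: str = "A vs B",
                 adjusted_alpha: float = 0.05) -> AUCComparison:
    """Paired nonparametric AUC-difference test (DeLong), two-sided.

    Both score vectors must refer to the same patients in the same order.
    A comparison of a model with itself yields delta 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if a.size != b.size or a.size != labels.size:
        raise ContractError("both models must score the same patients")
    _check_binary(labels)
    v10a, v01a = _delong_components(a, labels)
    v10b, v01b = _delong_components(b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 1e-16:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return AUCComparison(
        label=label, auc_a=auc_a, auc_b=auc_b, delta_auc=float(delta),
        p_value=p, adjusted_alpha=adjusted_alpha,
        significant=bool(p < adjusted_alpha),
    )


def bonferroni_adjust(alpha_family: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison alpha, reported at 3 decimals."""
    if m < 1:
        raise ContractError("number of comparisons must be >= 1")
    return round(alpha_family / m, 3)


def cutoff_least_misclassification(scores, labels) -> float:
    """Score threshold minimizing FP + FN (predict positive at >= cutoff).

    Candidate thresholds are the midpoints between consecutive distinct
    scores; ties in the misclassification count break towards the lower
    threshold. With a single distinct score, that score is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(labels)
    distinct = np.unique(scores)
    if distinct.size == 1:
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_thr, best_err = None, None
    for thr in candidates:  # ascending, so ties keep the lower threshold
        pred = scores >= thr
        err = int((pred & (labels == 0)).sum() + (~pred & (labels == 1)).sum())
        if best_err is None or err < best_err:
            best_thr, best_err = float(thr), err
    return best_thr


def _km_table(kmf: KaplanMeierFitter) -> pd.DataFrame:
    table = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )


def km_logrank(survival_months, event, group, cutoff: float | None = None) -> KMResult:
    """Kaplan-Meier curves per group with the two-sample log-rank test.

    ``group`` is a binary/str array naming each patient's predicted group.
    With no events in either group the log-rank statistic is undefined; a
    degenerate result (flagged, statistic NaN) is returned instead.
    """
    t = np.asarray(survival_months, dtype=float)
    e = np.asarray(event).astype(bool)
    g = np.asarray(group)
    names = [str(x) for x in pd.unique(g)]
    if len(names) != 2:
        raise EvaluationError(f"need exactly 2 groups, got {names}")
    if any((g == pd.unique(g)[i]).sum() == 0 for i in range(2)):
        raise EvaluationError("both groups must be nonempty")
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for name in pd.unique(g):
        sel = g == name
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], event_observed=e[sel])
        curves[str(name)] = _km_table(kmf)
        sizes[str(name)] = int(sel.sum())
    if not e.any():
        return KMResult(curves=curves, statistic=float("nan"),
                        p_value=float("nan"), cutoff=cutoff, degenerate=True,
                        group_sizes=sizes)
    sel = g == pd.unique(g)[0]
    res = logrank_test(t[sel], t[~sel], event_observed_A=e[sel],
                       event_observed_B=e[~sel])
    return KMResult(
        curves=curves, statistic=float(res.test_statistic),
        p_value=float(res.p_value), cutoff=cutoff, degenerate=False,
        group_sizes=sizes,
    )
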