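"""Mutual-information feature selection and Pearson redundancy analysis.

Relevance of a feature F for the binary survival class C is scored by the
mutual information I(F;C) = H(F) - H(F|C), estimated by equal-frequency
discretization of F into k = min(10, floor(sqrt(n))) bins followed by the
plug-in discrete estimator, in nats. Equal-frequency binning makes the score
exactly invariant under strictly increasing transforms of the feature.

Selection keeps features whose score reaches a threshold; when no threshold
is given, the threshold is placed so that the top ``k_features`` (default 12)
by descending score are kept. Redundancy among the selected features is then
summarized by a Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .datatypes import SelectionError

__all__ = [
    "estimate_mutual_information",
    "MutualInfoSelector",
    "MISelectionResult",
    "select_by_mi",
    "pearson_matrix",
    "CorrelationResult",
]


def _bin_feature(values: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Equal-frequency bin assignment (0-based); duplicate edges collapse.

    Bin edges are order statistics of the data themselves (quantiles with the
    ``lower`` method), which makes the partition exactly invariant under
    strictly increasing transforms of the feature.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n_bins is None:
        n_bins = min(10, int(np.floor(np.sqrt(n))))
    n_bins = max(1, n_bins)
    edges = np.unique(
        np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1], method="lower")
    )
    # strictly-less comparison: ties always share a bin, and the partition is
    # preserved exactly by any strictly increasing transform
    return np.searchsorted(edges, values, side="left")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def estimate_mutual_information(
    feature_values: np.ndarray,
    labels: np.ndarray,
    n_bins: int | None = None,
) -> float:
    """Plug-in MI estimate (nats) between a real feature and binary labels.

    Computed as H(F) - H(F|C) on the discretized feature, clamped at zero.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.size != y.size:
        raise SelectionError("feature and label vectors must have equal length")
    if x.size < 8:
        raise SelectionError(f"need at least 8 samples, got {x.size}")
    classes = np.unique(y)
    if classes.size < 2:
        raise SelectionError("labels must contain both classes")
    bins = _bin_feature(x, n_bins)
    n = x.size
    h_f = _entropy(np.bincount(bins))
    h_f_given_c = 0.0
    for c in classes:
        sel = y == c
        h_f_given_c += (sel.sum() / n) * _entropy(np.bincount(bins[sel]))
    return max(0.0, h_f - h_f_given_c)


@dataclass
class MISelectionResult:
    """Outcome of MI-threshold feature selection."""

    mi_score: pd.Series
    threshold: float
    selected_names: list[str]
    excluded_missing: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    """Pearson correlation matrix over selected features."""

    matrix: pd.DataFrame
    constant_features: list[str] = field(default_factory=list)


class MutualInfoSelector(SelectorMixin, BaseEstimator):
    """Select features by mutual information with the class label.

    Parameters
    ----------
    threshold:
        Keep features with ``MI >= threshold``. When ``None``, the threshold
        is set at the score of the ``k_features``-th ranked feature.
    k_features:
        Target selection cardinality used when ``threshold`` is ``None``.
    n_bins:
        Discretization bins; default ``min(10, floor(sqrt(n)))``.

    Columns containing missing values are excluded before scoring and listed
    in ``excluded_missing_``. Fit on the training split only.
    """

    def __init__(self, threshold: float | None = None, k_features: int = 12,
                 n_bins: int | None = None):
        self.threshold = threshold
        self.k_features = k_features
        self.n_bins = n_bins

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(values.shape[1])]
        y = np.asarray(y).astype(int)
        if self.threshold is not None and self.threshold < 0:
            raise SelectionError("threshold must be non-negative")

        ok = np.isfinite(values).all(axis=0)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.excluded_missing_ = [n for n, good in zip(names, ok) if not good]
        scores = np.full(len(names), np.nan)
        for j, good in enumerate(ok):
            if good:
                scores[j] = estimate_mutual_information(values[:, j], y, self.n_bins)
        self.scores_ = pd.Series(scores, index=names)

        valid = self.scores_.dropna()
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        elif len(valid) == 0:
            self.threshold_ = 0.0
        else:
            k = min(self.k_features, len(valid))
            self.threshold_ = float(np.sort(valid.to_numpy())[::-1][k - 1])
        # Descending score, name as the deterministic tie-break.
        ranked = sorted(valid.items(), key=lambda kv: (-kv[1], kv[0]))
        self.selected_names_ = [n for n, s in ranked if s >= self.threshold_]
        if self.threshold is None and len(self.selected_names_) > self.k_features:
            self.selected_names_ = self.selected_names_[: self.k_features]
        if not self.selected_names_:
            import warnings

            warnings.warn("MI selection is empty at the given threshold")
        self.n_features_in_ = len(names)
        self._support = np.isin(self.feature_names_in_, self.selected_names_)
        return self

    def _get_support_mask(self):
        return self._support

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_names_]
        return np.asarray(X)[:, self._support]

    def result_(self) -> MISelectionResult:
        return MISelectionResult(
            mi_score=self.scores_,
            threshold=self.threshold_,
            selected_names=list(self.selected_names_),
            excluded_missing=list(self.excluded_missing_),
        )


def select_by_mi(
    feature_matrix: pd.DataFrame,
    labels,
    threshold: float | None = None,
    k_features: int = 12,
    n_bins: int | None = None,
) -> MISelectionResult:
    """Functional wrapper around :class:`MutualInfoSelector`."""
    sel = MutualInfoSelector(threshold=threshold, k_features=k_features, n_bins=n_bins)
    sel.fit(feature_matrix, labels)
    return sel.result_()


def pearson_matrix(feature_matrix: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation among (selected) features.

    Constant columns have undefined correlation; their off-diagonal entries
    are reported as 0 and the columns are flagged.
    """
    if feature_matrix.shape[1] < 2:
        raise SelectionError("need at least 2 features for a correlation matrix")
    if feature_matrix.shape[0] < 3:
        raise SelectionError("need at least 3 samples for Pearson correlation")
    constant = [
        str(c) for c in feature_matrix.columns
        if float(feature_matrix[c].std(ddof=0)) == 0.0
    ]
    corr = feature_matrix.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationResult(matrix=corr, constant_features=constant)
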