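"""Descriptor fusion with a single-hidden-layer back-propagation network.

Three descriptor blocks can be fused per patient: C — the five clinical
nomogram point values; R — the MI-selected radiomics features; D — the
case-level CNN survival likelihood. Any of the combinations C, R, D, CR,
CD, CRD can be assembled into a fixed-column-order design matrix; models
trained on different combinations are therefore directly comparable.

The fusion classifier (BPNN) is a 13-hidden-node network with sigmoid
activations throughout, trained by full-batch gradient descent with
momentum on binary cross-entropy. Inputs are standardized with statistics
computed on the training split only; constant training columns are dropped
with a warning. When a validation set is given, the iteration with the best
validation AUC is restored after training; ``max_iter=0`` leaves the seeded
initialization untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import _nn
from .datatypes import AssemblyError, ConfigError, ContractError, TrainingError
from .nomogram import CLINICAL_INDICES

__all__ = [
    "COMBINATIONS",
    "DescriptorSet",
    "BPNNConfig",
    "BPNNClassifier",
    "assemble_descriptors",
    "train_bpnn",
    "predict_bpnn",
]

#: Valid descriptor combinations (C=clinical, R=radiomics, D=deep).
COMBINATIONS = ("C", "R", "D", "CR", "CD", "CRD")


@dataclass
class DescriptorSet:
    """Design matrix for one combination, with provenance."""

    combination: str
    X: pd.DataFrame  # one row per patient, frozen column order
    y: pd.Series  # 5-year survival labels aligned to X
    blocks: dict[str, list[str]]  # block name -> column names

    def __post_init__(self) -> None:
        if self.combination not in COMBINATIONS:
            raise AssemblyError(f"unknown combination {self.combination!r}")


@dataclass
class BPNNConfig:
    """Hyperparameters of the fusion network."""

    hidden_nodes: int = 13
    learning_rate: float = 0.5
    momentum: float = 0.9
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ConfigError("hidden_nodes must be >= 1")
        if self.max_iter < 0:
            raise ConfigError("max_iter must be >= 0")


def assemble_descriptors(
    combination: str,
    labels: pd.Series,
    clinical_points: pd.DataFrame | None = None,
    radiomics_selected: pd.DataFrame | None = None,
    dl_likelihood: pd.Series | None = None,
    patient_ids: list[str] | None = None,
) -> DescriptorSet:
    """Assemble the design matrix for ``combination`` over ``patient_ids``.

    ``clinical_points`` must carry the five ``points_*`` columns (extra
    columns such as totals are ignored); ``radiomics_selected`` the selected
    feature columns; ``dl_likelihood`` one score per patient. Raises
    :class:`AssemblyError` naming the patients missing from a required block.
    """
    combination = combination.upper()
    if combination not in COMBINATIONS:
        raise AssemblyError(f"unknown combination {combination!r}")
    ids = list(patient_ids) if patient_ids is not None else list(labels.index)
    blocks: dict[str, list[str]] = {}
    parts: list[pd.DataFrame] = []

    def require(block: str, frame: pd.DataFrame | None, what: str) -> pd.DataFrame:
        if frame is None:
            raise AssemblyError(f"combination {combination} requires the {what} block")
        missing = [p for p in ids if p not in frame.index]
        if missing:
            raise AssemblyError(
                f"{what} block missing patient(s): {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        return frame.loc[ids]

    if "C" in combination:
        cols = [f"points_{idx}" for idx in CLINICAL_INDICES]
        frame = require("C", clinical_points, "clinical points")
        absent = [c for c in cols if c not in frame.columns]
        if absent:
            raise AssemblyError(f"clinical points frame missing columns {absent}")
        parts.append(frame[cols])
        blocks["C"] = cols
    if "R" in combination:
        frame = require("R", radiomics_selected, "selected radiomics")
        parts.append(frame)
        blocks["R"] = [str(c) for c in frame.columns]
    if "D" in combination:
        frame = require(
            "D",
            dl_likelihood.to_frame("dl_likelihood") if dl_likelihood is not None else None,
            "deep likelihood",
        )
        parts.append(frame)
        blocks["D"] = ["dl_likelihood"]
    X = pd.concat(parts, axis=1)
    missing_labels = [p for p in ids if p not in labels.index]
    if missing_labels:
        raise AssemblyError(f"labels missing patient(s): {missing_labels[:10]}")
    return DescriptorSet(
        combination=combination, X=X, y=labels.loc[ids].astype(int), blocks=blocks
    )


class BPNNClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer sigmoid network trained by back-propagation.

    Missing feature values (e.g. a relative-difference radiomics feature
    undefined because its pre-treatment value was zero) are imputed at the
    training mean, i.e. zero after standardization.
    """

    def __init__(self, hidden_nodes: int = 13, learning_rate: float = 0.5,
                 momentum: float = 0.9, max_iter: int = 200, seed: int = 0):
        self.hidden_nodes = hidden_nodes
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_iter = max_iter
        self.seed = seed

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ContractError("X must be 2-dimensional")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        BPNNConfig(self.hidden_nodes, self.learning_rate, self.momentum,
                   self.max_iter, self.seed)  # parameter validation
        names = ([str(c) for c in X.columns] if isinstance(X, pd.DataFrame)
                 else None)
        X = self._validate(X)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise TrainingError("training labels must contain both classes")
        self.feature_names_in_ = (np.asarray(names, dtype=object) if names
                                  else np.asarray([f"x{i}" for i in range(X.shape[1])],
                                                  dtype=object))

        # Standardization statistics come from the training split only.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mean = np.nanmean(X, axis=0)
            sd = np.nanstd(X, axis=0, ddof=0)
        keep = np.isfinite(sd) & (sd > 0)
        if not keep.all():
            dropped = [str(n) for n, k in zip(self.feature_names_in_, keep) if not k]
            warnings.warn(f"dropping constant input column(s): {dropped}")
        if not keep.any():
            raise TrainingError("all input columns are constant")
        self.keep_mask_ = keep
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        Xs = self._standardize(X)

        rng = np.random.default_rng(self.seed)
        self.net_ = _nn.Sequential([
            _nn.Dense(Xs.shape[1], self.hidden_nodes, rng,
                      init_scale=1.0 / np.sqrt(Xs.shape[1])),
            _nn.Sigmoid(),
            _nn.Dense(self.hidden_nodes, 1, rng,
                      init_scale=1.0 / np.sqrt(self.hidden_nodes)),
        ])
        self.classes_ = np.array([0, 1])

        Xv = yv = None
        if X_val is not None and y_val is not None:
            Xv = self._standardize(self._validate(X_val))
            yv = np.asarray(y_val).astype(int)
        history = []
        best_auc, best_weights, best_iter = -np.inf, None, -1
        t = y[:, None].astype(float)
        for it in range(self.max_iter):
            logits = self.net_.forward(Xs)
            loss, grad = _nn.bce_with_logits(logits, t)
            self.net_.backward(grad)
            self.net_.step(self.learning_rate, self.momentum)
            row = {"iteration": it, "train_loss": loss, "val_auc": np.nan}
            if Xv is not None and np.unique(yv).size > 1:
                val_auc = roc_auc_score(yv, _nn.sigmoid(self.net_.forward(Xv).ravel()))
                row["val_auc"] = float(val_auc)
                if val_auc > best_auc:
                    best_auc, best_iter = val_auc, it
                    best_weights = self.net_.get_weights()
            history.append(row)
        if best_weights is not None:
            self.net_.set_weights(best_weights)
            self.best_iteration_ = best_iter
        else:
            self.best_iteration_ = self.max_iter - 1
        self.history_ = pd.DataFrame(
            history, columns=["iteration", "train_loss", "val_auc"]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Xs = (X[:, self.keep_mask_] - self.mean_) / self.sd_
        Xs[~np.isfinite(Xs)] = 0.0  # missing -> training mean
        return Xs

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ContractError(
                f"expected {self.n_features_in_} input columns, got {X.shape[1]}"
            )
        p1 = _nn.sigmoid(self.net_.forward(self._standardize(X)).ravel())
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_bpnn(
    train: DescriptorSet,
    val: DescriptorSet | None = None,
    config: BPNNConfig | None = None,
) -> BPNNClassifier:
    """Train the fusion network on a descriptor set (optionally validated)."""
    cfg = config or BPNNConfig()
    model = BPNNClassifier(
        hidden_nodes=cfg.hidden_nodes, learning_rate=cfg.learning_rate,
        momentum=cfg.momentum, max_iter=cfg.max_iter, seed=cfg.seed,
    )
    if val is not None and list(val.X.columns) != list(train.X.columns):
        raise ContractError("validation descriptor columns differ from training")
    model.fit(
        train.X, train.y,
        X_val=val.X if val is not None else None,
        y_val=val.y if val is not None else None,
    )
    return model


def predict_bpnn(model: BPNNClassifier, descriptors: DescriptorSet) -> pd.Series:
    """Survival scores in [0, 1], one per patient, aligned to the input."""
    scores = model.predict_proba(descriptors.X)[:, 1]
    return pd.Series(scores, index=descriptors.X.index, name="score")
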