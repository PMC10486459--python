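"""Patch CNN scoring hybrid ROIs, and per-patient likelihood aggregation.

The network maps one 32x32 hybrid ROI to a survival likelihood in [0, 1].
Its layout follows a compact AlexNet-style design: two convolution blocks
(convolution, cross-channel local response normalization, ReLU, overlapping
max-pool), two locally connected 3x3 layers, a small fully connected layer
(``fc_units`` = 10 by default) and a sigmoid output. Exact channel counts
and kernels are configurable; the defaults are a documented reconstruction.

Training minimizes binary cross-entropy on ROI-level labels with SGD and
momentum; when a validation set is supplied, the weights from the epoch with
the best validation ROI-level AUC are kept. All randomness (initialization,
shuffling) is driven by one integer seed.

Per patient, the likelihoods of all of that patient's hybrid ROIs are
combined (mean by default) into a single case-level survival likelihood,
the deep-learning descriptor handed to the fusion stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import _nn
from .datatypes import ConfigError, ContractError, EvaluationError, TrainingError
from .roi import HybridROI, ROI_SHAPE

__all__ = [
    "CNNConfig",
    "CaseScore",
    "PatchCNNClassifier",
    "build_cnn",
    "train_cnn",
    "score_case",
    "score_cohort",
]

_AGGREGATIONS = {"mean": np.mean, "median": np.median, "max": np.max}


@dataclass
class CNNConfig:
    """Hyperparameters of the hybrid-ROI CNN."""

    conv_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 5
    pool_size: int = 3
    pool_stride: int = 2
    lrn_size: int = 5
    lrn_k: float = 2.0
    lrn_alpha: float = 1e-4
    lrn_beta: float = 0.75
    local_channels: tuple[int, ...] = (32, 32)
    local_kernel: int = 3
    fc_units: int = 10
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.aggregation not in _AGGREGATIONS:
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if len(self.conv_channels) != 2:
            raise ConfigError("conv_channels must name the C1 and C2 channel counts")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class CaseScore:
    """Per-patient aggregate of ROI-level survival likelihoods."""

    patient_id: str
    roi_scores: list[float]
    case_likelihood: float

    def __post_init__(self) -> None:
        if not self.roi_scores:
            raise EvaluationError("a CaseScore requires at least one ROI score")
        lo, hi = min(self.roi_scores), max(self.roi_scores)
        if not (lo - 1e-12 <= self.case_likelihood <= hi + 1e-12):
            raise EvaluationError(
                "case likelihood must lie within the range of its ROI scores"
            )


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style wrapper around the hybrid-ROI CNN.

    Accepts patches as ``(n, 32, 32)`` or flattened ``(n, 1024)`` arrays.
    ``fit`` may be given a validation set (``X_val``, ``y_val``); the epoch
    with the best validation ROI AUC is restored at the end of training.
    With ``epochs=0`` the model keeps its seeded initialization.
    """

    def __init__(self, config: CNNConfig | None = None):
        self.config = config

    # -- construction ------------------------------------------------------
    def _cfg(self) -> CNNConfig:
        return self.config if self.config is not None else CNNConfig()

    def initialize(self) -> "PatchCNNClassifier":
        """Build the network with seeded initial weights, without training."""
        cfg = self._cfg()
        rng = np.random.default_rng(cfg.seed)
        c1, c2 = cfg.conv_channels
        pad = cfg.kernel_size // 2
        h = w = ROI_SHAPE[0]
        layers: list[_nn.Layer] = []

        def pooled(size: int) -> int:
            return (size - cfg.pool_size) // cfg.pool_stride + 1

        layers += [
            _nn.Conv2D(1, c1, cfg.kernel_size, 1, pad, rng),
            _nn.LRN(cfg.lrn_size, cfg.lrn_k, cfg.lrn_alpha, cfg.lrn_beta),
            _nn.ReLU(),
            _nn.MaxPool2D(cfg.pool_size, cfg.pool_stride),
        ]
        h, w = pooled(h), pooled(w)
        layers += [
            _nn.Conv2D(c1, c2, cfg.kernel_size, 1, pad, rng),
            _nn.LRN(cfg.lrn_size, cfg.lrn_k, cfg.lrn_alpha, cfg.lrn_beta),
            _nn.ReLU(),
            _nn.MaxPool2D(cfg.pool_size, cfg.pool_stride),
        ]
        h, w = pooled(h), pooled(w)
        ch = c2
        for lc in cfg.local_channels:
            if h < cfg.local_kernel or w < cfg.local_kernel:
                raise ConfigError(
                    f"feature map {h}x{w} too small for a {cfg.local_kernel}x"
                    f"{cfg.local_kernel} locally connected layer"
                )
            layers += [
                _nn.LocallyConnected2D(ch, lc, (h, w), cfg.local_kernel, 1, rng),
                _nn.ReLU(),
            ]
            h, w = h - cfg.local_kernel + 1, w - cfg.local_kernel + 1
            ch = lc
        layers += [
            _nn.Flatten(),
            _nn.Dense(ch * h * w, cfg.fc_units, rng),
            _nn.Sigmoid(),
            _nn.Dense(cfg.fc_units, 1, rng, init_scale=np.sqrt(1.0 / cfg.fc_units)),
        ]
        self.net_ = _nn.Sequential(layers)
        self.classes_ = np.array([0, 1])
        self._shuffle_rng = np.random.default_rng(cfg.seed + 1)
        return self

    # -- data handling -----------------------------------------------------
    @staticmethod
    def _as_patches(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] == ROI_SHAPE[0] * ROI_SHAPE[1]:
            X = X.reshape(-1, *ROI_SHAPE)
        if X.ndim != 3 or X.shape[1:] != ROI_SHAPE:
            raise ContractError(
                f"patches must be (n, {ROI_SHAPE[0]}, {ROI_SHAPE[1]}), got {X.shape}"
            )
        return X[:, None, :, :]

    # -- training ----------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        cfg = self._cfg()
        X = self._as_patches(X)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise TrainingError("training patches must contain both classes")
        self.initialize()
        history = []
        best_auc, best_weights, best_epoch = -np.inf, None, -1
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = self._shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self.net_.forward(X[idx])
                loss, grad = _nn.bce_with_logits(logits, y[idx][:, None])
                self.net_.backward(grad)
                self.net_.step(cfg.learning_rate, cfg.momentum)
                losses.append(loss)
            train_scores = self._scores(X)
            row = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_auc": roc_auc_score(y, train_scores),
                "val_auc": np.nan,
            }
            if (X_val is not None and y_val is not None
                    and np.unique(np.asarray(y_val)).size > 1):
                val_auc = roc_auc_score(
                    np.asarray(y_val).astype(int),
                    self._scores(self._as_patches(X_val)),
                )
                row["val_auc"] = float(val_auc)
                if val_auc > best_auc:
                    best_auc, best_epoch = val_auc, epoch
                    best_weights = self.net_.get_weights()
            history.append(row)
        if best_weights is not None:
            self.net_.set_weights(best_weights)
        self.best_epoch_ = best_epoch if best_weights is not None else (
            cfg.epochs - 1 if cfg.epochs else -1
        )
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "train_loss", "train_auc", "val_auc"]
        )
        return self

    def _scores(self, X4: np.ndarray, batch: int = 512) -> np.ndarray:
        out = [
            _nn.sigmoid(self.net_.forward(X4[i : i + batch]).ravel())
            for i in range(0, X4.shape[0], batch)
        ]
        return np.concatenate(out) if out else np.empty(0)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise ContractError("model is neither fitted nor initialized")
        p1 = self._scores(self._as_patches(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def build_cnn(config: CNNConfig | None = None) -> PatchCNNClassifier:
    """Construct the CNN with seeded initial weights (untrained)."""
    return PatchCNNClassifier(config=config).initialize()


def train_cnn(
    X_train, y_train, X_val=None, y_val=None, config: CNNConfig | None = None
) -> PatchCNNClassifier:
    """Train the hybrid-ROI CNN; returns the fitted model (see ``history_``)."""
    model = PatchCNNClassifier(config=config)
    model.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    return model


def score_case(
    model: PatchCNNClassifier,
    patches: np.ndarray,
    aggregation: str = "mean",
    patient_id: str = "",
) -> CaseScore:
    """Aggregate one patient's ROI likelihoods into a case likelihood."""
    if aggregation not in _AGGREGATIONS:
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    patches = np.asarray(patches)
    if patches.size == 0 or patches.shape[0] == 0:
        raise EvaluationError("cannot score a case with zero patches")
    scores = model.predict_proba(patches)[:, 1]
    return CaseScore(
        patient_id=patient_id,
        roi_scores=[float(s) for s in scores],
        case_likelihood=float(_AGGREGATIONS[aggregation](scores)),
    )


def score_cohort(
    model: PatchCNNClassifier, rois: list[HybridROI], aggregation: str = "mean"
) -> pd.Series:
    """Case likelihood per patient over a hybrid-ROI list."""
    by_case: dict[str, list[np.ndarray]] = {}
    for r in rois:
        by_case.setdefault(r.patient_id, []).append(r.patch)
    out = {
        pid: score_case(model, np.stack(patches), aggregation, pid).case_likelihood
        for pid, patches in by_case.items()
    }
    return pd.Series(out, name="dl_likelihood").sort_index()
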