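"""Preliminary per-point classification from the nine spectral features.

Three classifier families are supported with the configurations the
method was developed around:

* random forest with 8 trees (bootstrap-sampled binary decision trees,
  plurality vote across trees);
* RBF-kernel support vector machine with kernel coefficient gamma = 0.1
  and penalty C = 10;
* back-propagation neural network with one hidden layer of 5 logistic
  (sigmoid) units, 9 inputs and 4 outputs.

Labeled data are split 7:3 into training and validation sets.  Feature
standardization (fit on the training set only) is applied for the
scale-sensitive SVM and neural network and skipped for the forest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cloud import ComponentLabel
from .features import FEATURE_NAMES, FeatureTable

__all__ = ["ClassifierConfig", "TrainedModel", "split_dataset", "train", "predict"]

log = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    """Configuration of the preliminary classifier.

    ``scaling="standardize"`` is the default but is only applied for the
    SVM and the neural network; tree ensembles are scale-invariant and
    use raw features.
    """

    method: str = "rf"
    rf_n_trees: int = 8
    svm_kernel: str = "rbf"
    svm_gamma: float = 0.1
    svm_C: float = 10.0
    bpnn_layers: tuple[int, ...] = (9, 5, 4)
    bpnn_activation: str = "sigmoid"
    bpnn_max_iter: int = 500
    scaling: str = "standardize"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("rf", "svm", "bpnn"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.svm_kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if self.bpnn_activation != "sigmoid":
            raise ValueError("only sigmoid activation is supported")
        if self.scaling not in ("standardize", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        layers = tuple(self.bpnn_layers)
        if layers[0] != len(FEATURE_NAMES) or layers[-1] != len(ComponentLabel):
            raise ValueError(
                f"bpnn layers must run {len(FEATURE_NAMES)} inputs to "
                f"{len(ComponentLabel)} outputs, got {layers}"
            )
        self.bpnn_layers = layers


@dataclass
class TrainedModel:
    """Fitted predictor plus everything needed to apply it consistently."""

    estimator: object
    config: ClassifierConfig
    feature_names: tuple[str, ...]
    codebook: tuple[int, ...]
    scaler: StandardScaler | None = None
    train_class_counts: dict[int, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def split_dataset(
    features: FeatureTable,
    labels: np.ndarray,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation index split (default 7:3).

    Returns ``(train_idx, val_idx)``; their union is every index exactly
    once.  Reproducible for a fixed seed.  A warning is emitted when a
    class present in the data is absent from the training half.
    """
    labels = np.asarray(labels)
    n = len(features)
    if labels.shape != (n,):
        raise ValueError("labels length must match the feature table")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    missing = set(np.unique(labels)) - set(np.unique(labels[train_idx]))
    if missing:
        warnings.warn(
            f"classes {sorted(missing)} absent from the training split",
            stacklevel=2,
        )
    return train_idx, val_idx


def _build_estimator(config: ClassifierConfig):
    if config.method == "rf":
        return RandomForestClassifier(
            n_estimators=config.rf_n_trees, random_state=config.seed
        )
    if config.method == "svm":
        return SVC(kernel="rbf", gamma=config.svm_gamma, C=config.svm_C,
                   random_state=config.seed)
    # one hidden layer; logistic == sigmoid; Adam with a slightly raised
    # learning rate converges reliably with only five hidden units
    return MLPClassifier(
        hidden_layer_sizes=config.bpnn_layers[1:-1],
        activation="logistic",
        solver="adam",
        learning_rate_init=0.01,
        max_iter=config.bpnn_max_iter,
        random_state=config.seed,
    )


def train(
    features: FeatureTable, labels: np.ndarray, config: ClassifierConfig
) -> TrainedModel:
    """Fit the configured classifier on a labeled feature table."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (len(features),):
        raise ValueError("labels length must match the feature table")
    bad = features.missing_rows
    if bad.size:
        raise ValueError(
            f"feature table has missing values in rows {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training needs at least two classes present")

    X = features.values
    scaler = None
    if config.scaling == "standardize" and config.method in ("svm", "bpnn"):
        scaler = StandardScaler()
        # variance floor: constant features scale to 0 instead of dividing by 0
        scaler.fit(X)
        scaler.scale_ = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        X = scaler.transform(X)

    estimator = _build_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        estimator.fit(X, labels)
    class_counts = {int(c): int(k) for c, k in zip(classes, counts)}
    log.info("trained %s on %d points; class counts %s",
             config.method, len(features), class_counts)
    return TrainedModel(
        estimator=estimator,
        config=config,
        feature_names=tuple(features.names),
        codebook=tuple(int(c) for c in classes),
        scaler=scaler,
        train_class_counts=class_counts,
    )


def predict(model: TrainedModel, features: FeatureTable) -> np.ndarray:
    """Per-point component labels for a feature table matching training."""
    if tuple(features.names) != tuple(model.feature_names):
        raise ValueError(
            "feature names/order differ from those used in training: "
            f"{features.names} vs {model.feature_names}"
        )
    if len(features) == 0:
        return np.empty(0, dtype=np.int64)
    bad = features.missing_rows
    if bad.size:
        raise ValueError(f"missing feature values in rows {bad[:10].tolist()}")
    X = features.values
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return np.asarray(model.estimator.predict(X), dtype=np.int64)
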