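"""RBF-kernel SVM training, (c, gamma) grid search and prediction.

Feature scaling to [0, 1] is fitted on training data only and applied
before the kernel; inside cross-validated grid search the scaler is
re-fitted per fold so no held-out statistic leaks into training.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .balancing import FeatureMatrix
from .errors import ConfigError, InputError, ValidationError

#: The canonical libsvm coarse grid.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters and search grid.

    ``gamma=None`` means the libsvm default 1/n_features, resolved at
    training time.
    """

    c: float = 1.0
    gamma: float | None = None
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    scaling: str = "minmax"

    def __post_init__(self):
        if self.c <= 0:
            raise ConfigError("c must be > 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigError("gamma must be > 0")
        if not self.c_grid or not self.gamma_grid:
            raise ConfigError("grid lists must be non-empty")
        if self.scaling not in ("minmax", "none"):
            raise ConfigError("scaling must be 'minmax' or 'none'")


@dataclass
class TrainedModel:
    """A fitted SVM plus the scaling parameters and feature names it expects."""

    svc: SVC
    config: SVMConfig
    feature_names: tuple[str, ...]
    scaler: MinMaxScaler | None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValidationError(f"{path}: not a TrainedModel archive")
        return model


def _check_trainable(matrix: FeatureMatrix) -> None:
    if not np.all(np.isfinite(matrix.values)):
        raise InputError("feature matrix contains non-finite values")
    if len(matrix.class_counts()) < 2:
        raise InputError("training needs both classes present")
    if min(matrix.class_counts().values()) < 2:
        raise InputError("training needs >= 2 samples per class")


def train(matrix: FeatureMatrix, config: SVMConfig | None = None) -> TrainedModel:
    """Fit scaler (training data only) then an RBF SVC; deterministic."""
    config = config or SVMConfig()
    _check_trainable(matrix)
    X = matrix.values
    scaler = None
    if config.scaling == "minmax":
        scaler = MinMaxScaler().fit(X)
        X = scaler.transform(X)
    gamma = config.gamma if config.gamma is not None else 1.0 / matrix.n_features
    svc = SVC(C=config.c, gamma=gamma, kernel="rbf")
    svc.fit(X, matrix.labels)
    return TrainedModel(
        svc=svc,
        config=config,
        feature_names=matrix.feature_names,
        scaler=scaler,
    )


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Predict binary labels; rejects feature name/order mismatches."""
    if matrix.feature_names != model.feature_names:
        raise ValidationError(
            f"feature names do not match training: got {matrix.n_features} "
            f"features, model expects {len(model.feature_names)}"
        )
    if matrix.n_samples == 0:
        return np.empty(0, dtype=int)
    X = matrix.values
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return model.svc.predict(X).astype(int)


def _cv_accuracy(
    matrix: FeatureMatrix, config: SVMConfig, folds: int, seed: int
) -> float:
    """Mean stratified-CV accuracy (%) with per-fold scaler fitting."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(matrix.values, matrix.labels):
        model = train(matrix.subset_rows(train_idx), config)
        preds = predict(model, matrix.subset_rows(test_idx))
        correct += int((preds == matrix.labels[test_idx]).sum())
    return 100.0 * correct / matrix.n_samples


def grid_search(
    matrix: FeatureMatrix,
    config: SVMConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SVMConfig:
    """Pick the (c, gamma) pair maximizing mean CV accuracy over the grid.

    Ties break toward smaller c, then smaller gamma. Folds are stratified;
    classes smaller than ``folds`` raise an error.
    """
    config = config or SVMConfig()
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    _check_trainable(matrix)
    if min(matrix.class_counts().values()) < folds:
        raise InputError(
            f"cannot stratify {folds} folds: smallest class has "
            f"{min(matrix.class_counts().values())} samples"
        )
    best: tuple[float, float] | None = None
    best_acc = -1.0
    for c, gamma in itertools.product(
        sorted(config.c_grid), sorted(config.gamma_grid)
    ):
        acc = _cv_accuracy(matrix, replace(config, c=c, gamma=gamma), folds, seed)
        if acc > best_acc:
            best_acc, best = acc, (c, gamma)
    assert best is not None
    return replace(config, c=best[0], gamma=best[1])


def svm_trainer(config: SVMConfig | None = None):
    """A training callback (FeatureMatrix -> TrainedModel) for evaluators."""
    config = config or SVMConfig()

    def _fit(matrix: FeatureMatrix) -> TrainedModel:
        return train(matrix, config)

    return _fit
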