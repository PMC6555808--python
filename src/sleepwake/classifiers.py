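"""Learned sleep-wake classifiers.

Two input modalities are supported: a summary-statistic
:class:`~sleepwake.features.FeatureSchema` matrix for classical models
(logistic regression, linear SVM, perceptron, extremely randomized trees)
and fixed-width windows of raw counts for a small sequence model
(``window_mlp``, a multilayer perceptron over the window). Hyperparameters
are chosen by k-fold cross-validation maximizing accuracy, with folds cut
by subject by default to avoid within-subject leakage; the winning
configuration is refit on all training data. Everything is reproducible
from the training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.model_selection import GroupKFold, KFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import Hypnogram
from .errors import ConfigurationError, ValidationError


@dataclass
class WindowDataset:
    """Per-epoch fixed-width windows of raw counts, centered on the target."""

    width: int
    windows: np.ndarray  # shape (n_epochs, width)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 2 or self.windows.shape[1] != self.width:
            raise ValidationError(
                f"windows must have shape (n, {self.width}), got {self.windows.shape}"
            )

    def __len__(self) -> int:
        return len(self.windows)


def make_window_dataset(counts: Sequence | np.ndarray, width: int) -> WindowDataset:
    """Window for epoch ``t`` covers ``[t - width//2, t + ceil(width/2) - 1]``,
    zero-padded outside the series; missing counts enter as zeros."""
    if width < 1:
        raise ValidationError("window width must be >= 1")
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("counts must be a non-empty 1-d sequence")
    filled = np.nan_to_num(arr, nan=0.0)
    left = width // 2
    right = width - left - 1
    padded = np.concatenate([np.zeros(left), filled, np.zeros(right)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, width)[: len(filled)]
    return WindowDataset(width=width, windows=windows.copy())


ALGORITHMS = ("logistic_regression", "linear_svm", "perceptron", "extra_trees", "window_mlp")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0]},
    "linear_svm": {"C": [0.01, 0.1, 1.0]},
    "perceptron": {"alpha": [1e-4, 1e-2]},
    "extra_trees": {"n_estimators": [50], "max_depth": [None, 8]},
    "window_mlp": {"hidden_layer_sizes": [(32,)], "alpha": [1e-4]},
}


def _build_estimator(algorithm: str, params: Mapping, seed: int):
    if algorithm == "logistic_regression":
        est = LogisticRegression(max_iter=2000, random_state=seed, **params)
        return make_pipeline(StandardScaler(), est)
    if algorithm == "linear_svm":
        est = LinearSVC(random_state=seed, **params)
        return make_pipeline(StandardScaler(), est)
    if algorithm == "perceptron":
        est = Perceptron(random_state=seed, **params)
        return make_pipeline(StandardScaler(), est)
    if algorithm == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "window_mlp":
        est = MLPClassifier(max_iter=400, random_state=seed, **params)
        return make_pipeline(StandardScaler(), est)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}; known: {ALGORITHMS}")


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    hyperparameters: dict
    seed: int
    input_contract: tuple  # ("features", n_columns) or ("windows", width)
    cv_accuracy: float


def _design_matrix(inputs: pd.DataFrame | WindowDataset) -> tuple[np.ndarray, tuple]:
    if isinstance(inputs, WindowDataset):
        return inputs.windows, ("windows", inputs.width)
    if isinstance(inputs, pd.DataFrame):
        return inputs.to_numpy(dtype=float), ("features", inputs.shape[1])
    arr = np.asarray(inputs, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("inputs must be a FeatureMatrix DataFrame or a WindowDataset")
    return arr, ("features", arr.shape[1])


def train_classifier(
    inputs: pd.DataFrame | WindowDataset,
    labels: Hypnogram | Sequence,
    algorithm: str,
    search_space: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
    groups: Sequence | None = None,
) -> TrainedModel:
    """Grid-search hyperparameters by k-fold CV on accuracy, then refit.

    ``groups`` gives a subject id per epoch; when provided, folds are cut
    by subject (the default protocol). Without groups, contiguous epoch
    blocks are used so neighboring windows never straddle a fold boundary
    randomly. Missing-label epochs are excluded from training.
    """
    if algorithm not in ALGORITHMS:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}; known: {ALGORITHMS}")
    grid = dict(search_space) if search_space is not None else DEFAULT_GRIDS[algorithm]
    if search_space is not None and not grid:
        raise ConfigurationError("empty hyperparameter grid")
    X, contract = _design_matrix(inputs)
    y = labels.labels if isinstance(labels, Hypnogram) else np.asarray(labels, dtype=float)
    if len(y) != len(X):
        raise ValidationError(f"inputs/labels length mismatch: {len(X)} vs {len(y)}")
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    X, y = X[keep], y[keep].astype(int)
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    grp = np.asarray(groups)[keep] if groups is not None else None

    names = sorted(grid)
    combos = [dict(zip(names, vals)) for vals in product(*(grid[k] for k in names))]
    if grp is not None:
        n_splits = min(folds, np.unique(grp).size)
        splitter = GroupKFold(n_splits=n_splits)
        split_iter = list(splitter.split(X, y, groups=grp))
    else:
        n_splits = min(folds, len(X))
        splitter = KFold(n_splits=n_splits, shuffle=False)
        split_iter = list(splitter.split(X, y))

    best = None
    for params in combos:
        accs = []
        for tr, va in split_iter:
            if np.unique(y[tr]).size < 2:
                continue
            est = _build_estimator(algorithm, params, seed)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[va]) == y[va])))
        mean_acc = float(np.mean(accs)) if accs else -np.inf
        # ties resolved by grid order, so the search is deterministic
        if best is None or mean_acc > best[0]:
            best = (mean_acc, params)
    cv_acc, best_params = best
    final = _build_estimator(algorithm, best_params, seed)
    final.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=final,
        hyperparameters=best_params,
        seed=seed,
        input_contract=contract,
        cv_accuracy=cv_acc,
    )


def predict_epochs(model: TrainedModel, inputs: pd.DataFrame | WindowDataset) -> Hypnogram:
    """Predict aligned binary labels; rows with undefined inputs stay missing."""
    X, contract = _design_matrix(inputs)
    if contract != model.input_contract:
        raise ValidationError(
            f"input contract mismatch: model expects {model.input_contract}, got {contract}"
        )
    out = np.full(len(X), np.nan)
    ok = ~np.isnan(X).any(axis=1)
    if ok.any():
        out[ok] = model.estimator.predict(X[ok]).astype(float)
    return Hypnogram(out)
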