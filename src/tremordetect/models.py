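"""The four classifier families and their tuning procedures.

Classical models (KNN, SVM, RF) consume the flat normalized sample vector
of each window (50 or 510 values — no feature extraction) and are tuned by
exhaustive grid search with 10-fold cross-validation, selecting on mean CV
f1. The LSTM consumes the same window as a scalar-per-timestep sequence
and is tuned over hidden size and learning rate using a validation split.

Fixed choices follow the study protocol: KNN uses the ball-tree algorithm
with distance weighting; SVM uses the RBF kernel; RF uses the entropy
criterion with min_samples_leaf=2. The grids are small supersets of the
optima actually selected per modality (see OPTIMAL_HYPERPARAMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .lstm import LSTMClassifier

CLASSICAL_FAMILIES = ("knn", "svm", "rf")
FAMILIES = CLASSICAL_FAMILIES + ("lstm",)

#: default hyperparameter grids (sklearn param-grid form)
HYPER_GRIDS: dict[str, dict] = {
    "knn": {
        "n_neighbors": [2, 3, 6, 10],
        "leaf_size": [30],
        "metric": ["euclidean", "chebyshev"],
    },
    "svm": {
        "C": [1.0, 10.0],
        "gamma": [1.0, 0.1, 0.01],
    },
    "rf": {
        "n_estimators": [100, 110],
        "max_features": ["sqrt"],
    },
    "lstm": {
        "hidden_size": [20, 35, 50],
        "learning_rate": [0.005, 0.001, 0.0001],
    },
}

#: hyperparameters selected for the final assessment, per modality
OPTIMAL_HYPERPARAMS: dict[str, dict[str, dict]] = {
    "kinematic-angle": {
        "knn": {"n_neighbors": 6, "leaf_size": 30, "metric": "euclidean"},
        "svm": {"C": 10.0, "gamma": 1.0},
        "rf": {"n_estimators": 100, "max_features": "sqrt"},
        "lstm": {"hidden_size": 50, "learning_rate": 0.005},
    },
    "emg-envelope": {
        "knn": {"n_neighbors": 3, "leaf_size": 30, "metric": "euclidean"},
        "svm": {"C": 1.0, "gamma": 0.1},
        "rf": {"n_estimators": 100, "max_features": "sqrt"},
        "lstm": {"hidden_size": 35, "learning_rate": 0.005},
    },
    "emg-raw": {
        "knn": {"n_neighbors": 2, "leaf_size": 30, "metric": "chebyshev"},
        "svm": {"C": 10.0, "gamma": 0.01},
        "rf": {"n_estimators": 110, "max_features": "sqrt"},
        "lstm": {"hidden_size": 50, "learning_rate": 0.005},
    },
}


def make_classical(family: str, seed: int = 0, **params):
    """Instantiate a classical estimator with the protocol's fixed settings."""
    if family == "knn":
        return KNeighborsClassifier(algorithm="ball_tree", weights="distance",
                                    **params)
    if family == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "rf":
        return RandomForestClassifier(criterion="entropy", min_samples_leaf=2,
                                      random_state=seed, **params)
    raise ValueError(f"unknown classical family {family!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus its provenance.

    ``estimator`` is an sklearn estimator or an :class:`LSTMClassifier`;
    ``cv_table`` holds the grid-search results (classical) and
    ``training_log`` the per-epoch losses (LSTM).
    """

    family: str
    modality: str
    hyperparams: dict
    estimator: object
    selection_metric: str = "f1"
    norm_stats: Optional[tuple] = None
    cv_table: Optional[pd.DataFrame] = None
    training_log: Optional[dict] = None
    seed: int = 0

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return predict(self, windows)


def tune_classical(family: str, X: np.ndarray, y: np.ndarray,
                   space: Optional[dict] = None, k: int = 10,
                   seed: int = 0, modality: str = "",
                   n_jobs: int = 1) -> TrainedModel:
    """Exhaustive grid search with stratified k-fold CV, selecting on mean f1.

    The winning configuration is refit on the full training partition; the
    complete CV table is retained on the returned model.
    """
    if family not in CLASSICAL_FAMILIES:
        raise ValueError(f"{family!r} is not a classical family")
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(
            f"k={k} folds exceed the smallest class count {counts.min()}")
    space = HYPER_GRIDS[family] if space is None else space
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    gs = GridSearchCV(make_classical(family, seed=seed), space, scoring="f1",
                      cv=cv, refit=True, n_jobs=n_jobs)
    gs.fit(X, y)
    table = pd.DataFrame(gs.cv_results_)
    return TrainedModel(family=family, modality=modality,
                        hyperparams=dict(gs.best_params_),
                        estimator=gs.best_estimator_,
                        cv_table=table, seed=seed)


def train_classical(family: str, X: np.ndarray, y: np.ndarray,
                    params: Optional[dict] = None, seed: int = 0,
                    modality: str = "") -> TrainedModel:
    """Fit one classical configuration directly (no grid search)."""
    if params is None:
        params = OPTIMAL_HYPERPARAMS[modality][family]
    est = make_classical(family, seed=seed, **params)
    est.fit(X, np.asarray(y))
    return TrainedModel(family=family, modality=modality,
                        hyperparams=dict(params), estimator=est, seed=seed)


def train_lstm(X: np.ndarray, y: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray,
               hidden_size: int = 35, learning_rate: float = 0.005,
               max_epochs: int = 150, batch_size: int = 64,
               patience: Optional[int] = None, seed: int = 0,
               modality: str = "") -> TrainedModel:
    """Train the two-layer LSTM with validation checkpointing.

    Returns the best-validation-loss checkpoint together with the full
    train/validation loss trajectory.
    """
    net = LSTMClassifier(hidden_size=hidden_size, learning_rate=learning_rate,
                         max_epochs=max_epochs, batch_size=batch_size,
                         patience=patience, seed=seed)
    net.fit(X, y, X_val, y_val)
    return TrainedModel(
        family="lstm", modality=modality,
        hyperparams={"hidden_size": hidden_size, "learning_rate": learning_rate,
                     "max_epochs": max_epochs, "batch_size": batch_size},
        estimator=net,
        training_log={"train_loss": list(net.history["train_loss"]),
                      "val_loss": list(net.history["val_loss"]),
                      "best_val_loss": net.best_val_loss_},
        seed=seed)


def tune_lstm(X, y, X_val, y_val, space: Optional[dict] = None,
              max_epochs: int = 150, batch_size: int = 64,
              patience: Optional[int] = None, seed: int = 0,
              modality: str = "") -> TrainedModel:
    """Grid search over hidden size and learning rate by validation loss."""
    space = HYPER_GRIDS["lstm"] if space is None else space
    best: Optional[TrainedModel] = None
    for hs in space["hidden_size"]:
        for lr in space["learning_rate"]:
            tm = train_lstm(X, y, X_val, y_val, hidden_size=hs,
                            learning_rate=lr, max_epochs=max_epochs,
                            batch_size=batch_size, patience=patience,
                            seed=seed, modality=modality)
            if best is None or (tm.training_log["best_val_loss"]
                                < best.training_log["best_val_loss"]):
                best = tm
    return best


def predict(model: TrainedModel, windows: np.ndarray) -> np.ndarray:
    """Hard Tremor/No Tremor labels for a stack of windows.

    LSTM scores are cut at 0.5; classical estimators use their native
    decision rule. The window length must match the model's input length.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    est = model.estimator
    if isinstance(est, LSTMClassifier):
        expected = getattr(est, "n_timesteps_", None)
        if expected is not None and windows.shape[1] != expected:
            raise ValueError(
                f"window length {windows.shape[1]} does not match the model "
                f"input length {expected}")
        return est.predict(windows)
    expected = getattr(est, "n_features_in_", None)
    if expected is not None and windows.shape[1] != expected:
        raise ValueError(
            f"window length {windows.shape[1]} does not match the model "
            f"input length {expected}")
    return np.asarray(est.predict(windows), dtype=int)
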