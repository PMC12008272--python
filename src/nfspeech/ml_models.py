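"""Approach 2 — classical ML on reduced text embeddings.

Classifiers (Gaussian naive Bayes, SVM, random forest) predict the
medication state; regressors (random forest, ridge, SVM, light/extreme
gradient boosting) predict the 0-60 state score, with out-of-range
predictions clipped to the scale.  Hyperparameters are chosen by grid
search with an inner 3-fold cross-validation on the training rows only
(stratified for classification), seeded for reproducibility.  Grids are
deliberately small and config-exposed.

A bagging ensemble utility uniformly averages aligned score predictions
from two or more base regressors (typically the two best models applied
to different embeddings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC, SVR

from .corpus_io import MedState, SCORE_MAX, SCORE_MIN
from .embed import EmbeddingMatrix
from .errors import FitError

CLASSIFIER_FAMILIES = ("random_forest", "svm", "gaussian_nb")
REGRESSOR_FAMILIES = (
    "random_forest",
    "ridge",
    "svm",
    "gradient_boosting",
    "extreme_boosting",
)

DEFAULT_GRIDS: dict[tuple[str, str], dict[str, list[Any]]] = {
    ("classify", "random_forest"): {
        "n_estimators": [100],
        "max_depth": [None, 5],
        "max_features": ["sqrt", 0.5],
    },
    ("classify", "svm"): {
        "estimator__C": [0.1, 1.0, 10.0],
        "estimator__kernel": ["linear", "rbf"],
    },
    ("classify", "gaussian_nb"): {"var_smoothing": [1e-9, 1e-6, 1e-3]},
    ("regress", "random_forest"): {
        "n_estimators": [100],
        "max_depth": [None, 5],
        "max_features": ["sqrt", 0.5],
    },
    ("regress", "ridge"): {"alpha": [0.1, 1.0, 10.0, 100.0]},
    ("regress", "svm"): {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    ("regress", "gradient_boosting"): {"n_estimators": [100], "num_leaves": [7, 31]},
    ("regress", "extreme_boosting"): {"n_estimators": [100], "max_depth": [2, 4]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One model family with its task, hyperparameter grid and seed."""

    task: str  # "classify" | "regress"
    family: str
    grid: dict[str, list[Any]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classify", "regress"):
            raise ValueError(f"unknown task {self.task!r}")
        allowed = CLASSIFIER_FAMILIES if self.task == "classify" else REGRESSOR_FAMILIES
        if self.family not in allowed:
            raise ValueError(
                f"family {self.family!r} not valid for task {self.task!r} "
                f"(allowed: {allowed})"
            )

    @property
    def effective_grid(self) -> dict[str, list[Any]]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[(self.task, self.family)]


def _make_estimator(spec: ModelSpec):
    seed = spec.seed
    key = (spec.task, spec.family)
    if key == ("classify", "random_forest"):
        return RandomForestClassifier(random_state=seed)
    if key == ("classify", "svm"):
        # probability output via Platt scaling on inner folds
        return CalibratedClassifierCV(SVC(random_state=seed), cv=3)
    if key == ("classify", "gaussian_nb"):
        return GaussianNB()
    if key == ("regress", "random_forest"):
        return RandomForestRegressor(random_state=seed)
    if key == ("regress", "ridge"):
        return Ridge(random_state=seed)
    if key == ("regress", "svm"):
        return SVR()
    if key == ("regress", "gradient_boosting"):
        from lightgbm import LGBMRegressor

        return LGBMRegressor(random_state=seed, verbose=-1, min_child_samples=2)
    if key == ("regress", "extreme_boosting"):
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, verbosity=0)
    raise AssertionError(key)


@dataclass
class FittedModel:
    """A grid-searched estimator plus the fit's bookkeeping."""

    spec: ModelSpec
    chosen_hyperparameters: dict[str, Any]
    training_ids: tuple[str, ...]
    _estimator: Any = None
    _classes: tuple[str, ...] = ()


def fit(spec: ModelSpec, train: EmbeddingMatrix, targets: Sequence) -> FittedModel:
    """Grid-search fit on training rows only.

    Model selection uses accuracy (classification) or RMSE (regression)
    under an inner 3-fold CV; the best setting is refitted on all
    training rows.
    """
    X = np.asarray(
        train.vectors.toarray() if hasattr(train.vectors, "toarray") else train.vectors,
        dtype=float,
    )
    if X.shape[0] < 5:
        raise FitError(f"need >= 5 training rows, got {X.shape[0]}")
    if len(targets) != X.shape[0]:
        raise ValueError("targets do not align with training rows")
    if spec.task == "classify":
        y = np.array([t.value if isinstance(t, MedState) else str(t) for t in targets])
        if len(np.unique(y)) < 2:
            raise FitError("single-class training set")
        counts = np.bincount(np.unique(y, return_inverse=True)[1])
        n_splits = int(min(3, counts.min()))
        if n_splits < 2:
            raise FitError("a class has fewer than 2 training rows")
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
        scoring = "accuracy"
    else:
        y = np.asarray(targets, dtype=float)
        cv = KFold(n_splits=3, shuffle=True, random_state=spec.seed)
        scoring = "neg_root_mean_squared_error"
    search = GridSearchCV(
        _make_estimator(spec), spec.effective_grid, scoring=scoring, cv=cv, refit=True
    )
    search.fit(X, y)
    est = search.best_estimator_
    classes = tuple(est.classes_) if spec.task == "classify" else ()
    return FittedModel(
        spec=spec,
        chosen_hyperparameters=dict(search.best_params_),
        training_ids=tuple(train.doc_ids),
        _estimator=est,
        _classes=classes,
    )


def predict_class(
    model: FittedModel, rows: EmbeddingMatrix
) -> tuple[list[MedState], np.ndarray]:
    """Predict labels and probability-of-ON per row.

    The label is ON exactly when P(ON) > 0.5; ties break toward OFF.
    """
    if model.spec.task != "classify":
        raise ValueError("predict_class requires a classification model")
    X = np.asarray(
        rows.vectors.toarray() if hasattr(rows.vectors, "toarray") else rows.vectors,
        dtype=float,
    )
    proba = model._estimator.predict_proba(X)
    on_col = list(model._classes).index(MedState.ON.value)
    p_on = proba[:, on_col]
    labels = [MedState.ON if p > 0.5 else MedState.OFF for p in p_on]
    return labels, p_on


def predict_score(model: FittedModel, rows: EmbeddingMatrix) -> np.ndarray:
    """Predict state scores, clipped to the scale range [0, 60]."""
    if model.spec.task != "regress":
        raise ValueError("predict_score requires a regression model")
    X = np.asarray(
        rows.vectors.toarray() if hasattr(rows.vectors, "toarray") else rows.vectors,
        dtype=float,
    )
    raw = np.asarray(model._estimator.predict(X), dtype=float)
    return np.clip(raw, SCORE_MIN, SCORE_MAX)


def bagging_ensemble(*predictions: Sequence[float]) -> np.ndarray:
    """Uniform average of two or more aligned score vectors, clipped."""
    if len(predictions) < 2:
        raise ValueError("bagging needs at least two prediction vectors")
    arrays = [np.asarray(p, dtype=float) for p in predictions]
    n = arrays[0].shape[0]
    if any(a.shape != (n,) for a in arrays):
        raise ValueError("prediction vectors have mismatched lengths")
    return np.clip(np.mean(arrays, axis=0), SCORE_MIN, SCORE_MAX)
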