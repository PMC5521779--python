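"""Classifier training, cross-validation, prediction and feature ranking.

Six model families (SVM-RBF, random forest, Gaussian naive Bayes, KNN,
single-hidden-layer ANN, PLS discriminant analysis) share one protocol:
center/scale preprocessing fitted inside each training fold, stratified
k-fold cross-validation, grid search scored by mean held-out accuracy
(ties broken by grid order), and probability outputs for ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .descriptors import FEATURE_COLUMNS

__all__ = [
    "ALGORITHMS",
    "DEFAULT_SEED",
    "ModelConfig",
    "TrainedModel",
    "PredictionResult",
    "FeatureRanking",
    "CenterScaler",
    "fit_preprocessing",
    "default_grid",
    "cross_validate",
    "train",
    "predict",
    "rfe_rank",
    "save_model",
    "load_model",
]

DEFAULT_SEED = 20170721

ALGORITHMS = ("SVM_RBF", "RANDOM_FOREST", "NAIVE_BAYES", "KNN", "ANN", "PLS_DA")


class CenterScaler(BaseEstimator, TransformerMixin):
    """Center and scale each feature by training mean and sample sd.

    Zero-variance features are transformed to 0 with a warning.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = self.scale_ == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} constant feature(s) scaled to 0")
            self.scale_ = np.where(zero, 1.0, self.scale_)
        self.zero_variance_ = zero
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = (X - self.mean_) / self.scale_
        out[:, self.zero_variance_] = 0.0
        return out


def fit_preprocessing(features: pd.DataFrame | np.ndarray) -> CenterScaler:
    """Fit center/scale statistics on a training feature table."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit preprocessing")
    if np.issubdtype(X.dtype, np.number) is False or not np.all(np.isfinite(X)):
        raise TypeError("features must be finite numeric values")
    return CenterScaler().fit(X)


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS regression turned into a classifier.

    The latent PLS score of the binary response is mapped to a
    probability by a one-dimensional logistic link fitted on the
    training scores, so the probability is a monotone function of the
    latent score.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_comp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=n_comp, scale=False)
        self.pls_.fit(X, y.astype(float))
        scores = self.pls_.predict(X).ravel()
        self.link_ = LogisticRegression(C=1e3)
        self.link_.fit(scores.reshape(-1, 1), y)
        return self

    def decision_function(self, X):
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()

    def predict_proba(self, X):
        scores = self.decision_function(X).reshape(-1, 1)
        return self.link_.predict_proba(scores)

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise squared distance of scaled data."""
    from scipy.spatial.distance import pdist

    d2 = pdist(X, "sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def default_grid(algorithm: str, X_scaled: np.ndarray | None = None) -> list[dict]:
    """Hyperparameter grid per family, in declared (tie-break) order."""
    if algorithm == "SVM_RBF":
        if X_scaled is not None:
            g0 = _median_heuristic_gamma(np.asarray(X_scaled, dtype=float))
        else:
            g0 = 1.0 / 13
        return [
            {"C": c, "gamma": g}
            for c in (0.25, 0.5, 1.0, 2.0, 4.0)
            for g in (g0 / 2, g0, g0 * 2)
        ]
    if algorithm == "RANDOM_FOREST":
        return [{"n_estimators": 500, "max_features": m} for m in (2, 3, 4, 6)]
    if algorithm == "NAIVE_BAYES":
        return [{}]
    if algorithm == "KNN":
        return [{"n_neighbors": k} for k in (3, 5, 7, 9, 11)]
    if algorithm == "ANN":
        return [
            {"hidden_layer_sizes": (h,), "alpha": a}
            for h in (3, 5, 7)
            for a in (0.0, 0.01, 0.1)
        ]
    if algorithm == "PLS_DA":
        return [{"n_components": c} for c in (1, 2, 3)]
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _build_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "SVM_RBF":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if algorithm == "RANDOM_FOREST":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "NAIVE_BAYES":
        return GaussianNB(**params)
    if algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if algorithm == "ANN":
        return MLPClassifier(max_iter=2000, random_state=seed, **params)
    if algorithm == "PLS_DA":
        return PLSDAClassifier(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ModelConfig:
    algorithm: str = "RANDOM_FOREST"
    grid: list[dict] | None = None  # None -> default_grid at fit time
    cv_folds: int = 10
    seed: int = DEFAULT_SEED
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.grid is not None and len(self.grid) == 0:
            raise ValueError("grid must be non-empty")


@dataclass
class TrainedModel:
    config: ModelConfig
    pipeline: Pipeline  # CenterScaler + fitted estimator
    chosen_params: dict
    feature_names: list[str]
    n_train: int
    class_counts: dict

    @property
    def preprocessing(self) -> CenterScaler:
        return self.pipeline.named_steps["scale"]


@dataclass
class PredictionResult:
    index: object
    probability: float
    label: int

    def __post_init__(self):
        assert self.label == int(self.probability >= self._threshold)

    _threshold: float = field(default=0.5, repr=False)


@dataclass
class FeatureRanking:
    """Features ordered best-first with weights rescaled so max = 100.

    ``elimination_order`` records the recursive-elimination survival
    order (last survivor first); the headline ranking is sorted by the
    rescaled full-model weight, elimination order breaking ties, so the
    weight column is non-increasing.
    """

    features: list[str]
    weights: list[float]
    elimination_order: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features, "weight": self.weights})


def _check_xy(features, labels):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the labels")
    return X, y, names, dict(zip(classes.tolist(), counts.tolist()))


def _make_pipeline(algorithm: str, params: dict, seed: int) -> Pipeline:
    return Pipeline([
        ("scale", CenterScaler()),
        ("est", _build_estimator(algorithm, params, seed)),
    ])


def cross_validate(features, labels, config: ModelConfig) -> dict:
    """Grid search by stratified k-fold CV; returns the tuning report.

    Preprocessing is fitted inside each training fold (no leakage).  If
    the minority class has fewer members than ``cv_folds``, the fold
    count is reduced with a warning so every fold sees both classes.
    """
    X, y, names, class_counts = _check_xy(features, labels)
    n_min = min(class_counts.values())
    if n_min < 2:
        raise ValueError("minority class needs at least 2 members for CV")
    folds = config.cv_folds
    if n_min < folds:
        warnings.warn(
            f"minority class has {n_min} members; reducing folds "
            f"{folds} -> {n_min} to keep folds stratified"
        )
        folds = n_min
    if len(y) < folds:
        raise ValueError("fewer rows than folds")

    grid = config.grid
    if grid is None:
        scaled = CenterScaler().fit_transform(X)
        grid = default_grid(config.algorithm, scaled)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(X, y))
    fold_assignments = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = k

    grid_accuracies = []
    per_fold_best = None
    best_idx, best_acc = 0, -1.0
    for gi, params in enumerate(grid):
        fold_accs = []
        for train_idx, test_idx in splits:
            pipe = _make_pipeline(config.algorithm, params, config.seed)
            pipe.fit(X[train_idx], y[train_idx])
            fold_accs.append(float(np.mean(pipe.predict(X[test_idx]) == y[test_idx])))
        mean_acc = float(np.mean(fold_accs))
        grid_accuracies.append(mean_acc)
        if mean_acc > best_acc:  # strict: ties keep the earlier grid point
            best_acc, best_idx, per_fold_best = mean_acc, gi, fold_accs

    return {
        "algorithm": config.algorithm,
        "cv_folds": folds,
        "seed": config.seed,
        "grid": grid,
        "grid_accuracies": grid_accuracies,
        "best_params": grid[best_idx],
        "best_accuracy": best_acc,
        "per_fold_accuracies": per_fold_best,
        "fold_assignments": fold_assignments.tolist(),
        "class_counts": class_counts,
    }


def train(features, labels, config: ModelConfig,
          cv_report: dict | None = None) -> TrainedModel:
    """Fit the configured family on all rows at the CV-chosen grid point."""
    X, y, names, class_counts = _check_xy(features, labels)
    if cv_report is None:
        cv_report = cross_validate(features, labels, config)
    params = cv_report["best_params"]
    pipe = _make_pipeline(config.algorithm, params, config.seed)
    pipe.fit(X, y)
    return TrainedModel(
        config=config,
        pipeline=pipe,
        chosen_params=params,
        feature_names=names,
        n_train=len(y),
        class_counts=class_counts,
    )


def predict(model: TrainedModel, features) -> list[PredictionResult]:
    """Probability + thresholded label per row, in input row order."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing from input: {missing}")
        index = list(features.index)
        X = features[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} feature columns, "
                f"got {X.shape[1]}"
            )
        index = list(range(len(X)))
    if not np.all(np.isfinite(X)):
        raise ValueError("feature rows contain missing/non-finite values")
    proba = model.pipeline.predict_proba(X)[:, 1]
    thr = model.config.decision_threshold
    return [
        PredictionResult(i, float(p), int(p >= thr), _threshold=thr)
        for i, p in zip(index, proba)
    ]


def prediction_frame(results: list[PredictionResult]) -> pd.DataFrame:
    """Ranked report: rows sorted by descending deamidation probability."""
    frame = pd.DataFrame(
        {
            "index": [r.index for r in results],
            "probability": [r.probability for r in results],
            "label": [r.label for r in results],
        }
    )
    return frame.sort_values("probability", ascending=False, kind="mergesort")


def rfe_rank(features, labels, config: ModelConfig | None = None) -> FeatureRanking:
    """Recursive feature elimination with a random-forest ranker.

    Repeatedly fits an RF on the surviving features (preprocessed) and
    drops the least important one.  The final order is the elimination
    order, last survivor first; reported weights are the full-model
    importances rescaled so the top feature scores exactly 100.
    """
    if config is None:
        config = ModelConfig(algorithm="RANDOM_FOREST")
    X, y, names, _ = _check_xy(features, labels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")

    def rf_importances(cols: list[int]) -> np.ndarray:
        pipe = _make_pipeline(
            "RANDOM_FOREST", {"n_estimators": 500}, config.seed
        )
        pipe.fit(X[:, cols], y)
        return pipe.named_steps["est"].feature_importances_

    full_importance = dict(zip(names, rf_importances(list(range(X.shape[1])))))

    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        imp = rf_importances(surviving)
        drop_pos = int(np.argmin(imp))
        eliminated.append(surviving.pop(drop_pos))
    elim_order = surviving + eliminated[::-1]  # last survivor first
    elim_names = [names[i] for i in elim_order]

    top = max(full_importance.values())

    def weight(name: str) -> float:
        # divide before scaling so the top feature scores exactly 100.0
        return max(0.0, (full_importance[name] / top) * 100.0) if top > 0 else 0.0

    # headline order: rescaled full-model weight, elimination order on ties
    ordered = sorted(elim_names, key=lambda n: (-weight(n), elim_names.index(n)))
    return FeatureRanking(ordered, [weight(n) for n in ordered], elim_names)


def save_model(model: TrainedModel, path) -> None:
    """Persist as a joblib archive with a JSON-serializable config block."""
    payload = {
        "format_version": 1,
        "config": {
            "algorithm": model.config.algorithm,
            "cv_folds": model.config.cv_folds,
            "seed": model.config.seed,
            "decision_threshold": model.config.decision_threshold,
        },
        "chosen_params": model.chosen_params,
        "feature_names": model.feature_names,
        "n_train": model.n_train,
        "class_counts": model.class_counts,
        "pipeline": model.pipeline,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model archive version")
    cfg = ModelConfig(
        algorithm=payload["config"]["algorithm"],
        cv_folds=payload["config"]["cv_folds"],
        seed=payload["config"]["seed"],
        decision_threshold=payload["config"]["decision_threshold"],
    )
    return TrainedModel(
        config=cfg,
        pipeline=payload["pipeline"],
        chosen_params=payload["chosen_params"],
        feature_names=payload["feature_names"],
        n_train=payload["n_train"],
        class_counts=payload["class_counts"],
    )
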