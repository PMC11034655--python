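"""Slide-level classifiers over heatmap feature vectors.

Two fit paths mirror the two feature schemes: gradient-boosted trees
(XGBoost, 60 estimators of depth 3, class weights tuned for malignant
sensitivity) and a random forest tuned by randomized hyperparameter search
with K-fold cross-validation.

The boosted fit runs several independently seeded restarts and keeps the
model with the best (malignant sensitivity, accuracy) on a validation
split — the selection objective of a triage tool where missing a
malignancy is the costly error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterSampler, cross_val_score
from xgboost import XGBClassifier

from .categories import CATEGORIES, Category

__all__ = [
    "BoostConfig",
    "ForestSearchSpace",
    "SlideModel",
    "fit_boosted",
    "fit_forest_with_search",
    "predict_slides",
]

DEFAULT_CLASS_WEIGHTS = {
    Category.MALIGNANT: 1.0,
    Category.HIGH_GRADE: 0.1,
    Category.LOW_GRADE: 0.1,
    Category.NORMAL: 0.1,
}


@dataclass(frozen=True)
class BoostConfig:
    n_estimators: int = 60
    max_depth: int = 3
    class_weights: dict[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    n_restarts: int = 20
    subsample: float = 0.8  # row subsampling makes restarts distinct
    # min_child_weight is an absolute-hessian regularizer that does not
    # scale with cohort size: with 0.1 class weights a down-weighted class
    # of a desk-scale cohort cannot form a leaf at the xgboost default of
    # 1, so it is disabled by default
    min_child_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")


@dataclass(frozen=True)
class ForestSearchSpace:
    """Randomized-search ranges for the random-forest classifier."""

    n_estimators: tuple[int, ...] = tuple(range(100, 1501, 10))
    min_samples_split: tuple[int, ...] = (2, 5, 10)
    min_samples_leaf: tuple[int, ...] = (1, 2, 4)
    max_features: tuple[str, ...] = ("auto", "sqrt", "log2")
    max_depth: tuple[int, ...] = tuple(range(10, 111, 10))
    criterion: tuple[str, ...] = ("gini", "entropy")
    bootstrap: tuple[bool, ...] = (True, False)
    n_samples: int = 300
    cv_folds: int = 3

    def grid(self) -> dict:
        return {
            "n_estimators": list(self.n_estimators),
            "min_samples_split": list(self.min_samples_split),
            "min_samples_leaf": list(self.min_samples_leaf),
            "max_features": list(self.max_features),
            "max_depth": list(self.max_depth),
            "criterion": list(self.criterion),
            "bootstrap": list(self.bootstrap),
        }


@dataclass
class SlideModel:
    """Fitted slide classifier plus its feature scheme tag."""

    estimator: object
    scheme: str
    feature_length: int

    def predict(self, features: np.ndarray) -> list[Category]:
        return predict_slides(self, features)


def _encode(labels) -> np.ndarray:
    return np.asarray([Category.parse(str(getattr(l, "value", l))).severity_rank for l in labels])


def class_weight_vector(labels, weights: dict[Category, float]) -> np.ndarray:
    """Per-sample weight vector from per-class weights."""
    return np.asarray(
        [weights[CATEGORIES[r]] for r in _encode(labels)], dtype=float
    )


def _malignant_sensitivity(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    mal = Category.MALIGNANT.severity_rank
    mask = y_true == mal
    if not mask.any():
        return 0.0
    return float((y_pred[mask] == mal).mean())


def fit_boosted(
    features: np.ndarray,
    labels,
    cfg: BoostConfig = BoostConfig(),
    valid_features: np.ndarray | None = None,
    valid_labels=None,
    scheme: str = "forest90",
) -> SlideModel:
    """Fit weighted gradient-boosted trees with restart-based selection.

    Runs ``n_restarts`` independently seeded fits and keeps the one with
    the lexicographically best (malignant sensitivity, accuracy) on the
    validation split (training split if no validation data is given).
    Deterministic given ``cfg.seed``.
    """
    X = np.asarray(features, dtype=float)
    y = _encode(labels)
    if set(np.unique(y)) != {c.severity_rank for c in CATEGORIES}:
        missing = [
            CATEGORIES[r].value
            for r in ({c.severity_rank for c in CATEGORIES} - set(np.unique(y)))
        ]
        raise ValueError(f"training labels missing categories: {missing}")
    w = class_weight_vector(labels, cfg.class_weights)

    if valid_features is None:
        Xv, yv = X, y
    else:
        Xv = np.asarray(valid_features, dtype=float)
        yv = _encode(valid_labels)

    best = None
    for r in range(cfg.n_restarts):
        est = XGBClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            subsample=cfg.subsample,
            min_child_weight=cfg.min_child_weight,
            random_state=cfg.seed * 10_000 + r,
            n_jobs=1,
            verbosity=0,
        )
        est.fit(X, y, sample_weight=w)
        pred = est.predict(Xv)
        score = (_malignant_sensitivity(yv, pred), float((pred == yv).mean()))
        if best is None or score > best[0]:
            best = (score, est)
    return SlideModel(estimator=best[1], scheme=scheme, feature_length=X.shape[1])


def fit_forest_with_search(
    features: np.ndarray,
    labels,
    space: ForestSearchSpace = ForestSearchSpace(),
    seed: int = 0,
    scheme: str = "forest90",
) -> tuple[SlideModel, dict]:
    """Random-forest fit with randomized hyperparameter search.

    Samples ``space.n_samples`` parameter settings, scores each by
    ``cv_folds``-fold cross-validated accuracy, refits the best setting on
    all training data, and returns the model plus the chosen parameters.
    """
    X = np.asarray(features, dtype=float)
    y = _encode(labels)
    if len(X) < space.cv_folds:
        raise ValueError("fewer samples than cross-validation folds")
    grid = space.grid()
    total = int(np.prod([len(v) for v in grid.values()]))
    n_iter = min(space.n_samples, total)
    best_params, best_score = None, -np.inf
    for params in ParameterSampler(grid, n_iter=n_iter, random_state=seed):
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **_translate(params))
        score = cross_val_score(est, X, y, cv=space.cv_folds).mean()
        if score > best_score:
            best_score, best_params = score, params
    est = RandomForestClassifier(random_state=seed, n_jobs=1, **_translate(best_params))
    est.fit(X, y)
    model = SlideModel(estimator=est, scheme=scheme, feature_length=X.shape[1])
    return model, dict(best_params)


def _translate(params: dict) -> dict:
    """Map legacy parameter spellings to the current scikit-learn API.

    ``max_features='auto'`` historically meant sqrt for classification.
    """
    out = dict(params)
    if out.get("max_features") == "auto":
        out["max_features"] = "sqrt"
    return out


def predict_slides(model: SlideModel, features: np.ndarray) -> list[Category]:
    """Predict one category per slide from scheme-matched feature vectors."""
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return []
    if X.ndim != 2 or X.shape[1] != model.feature_length:
        raise ValueError(
            f"expected feature length {model.feature_length}, got {X.shape}"
        )
    return [CATEGORIES[int(r)] for r in model.estimator.predict(X)]
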