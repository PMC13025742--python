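"""Grid-searched training and benchmarking of the seven screening classifiers.

The harness compares Random Forest, Gradient Boosting, SVM, k-NN, MLP,
Logistic Regression and Gaussian Naive Bayes on the binary screening task,
each tuned by exhaustive grid search with stratified 5-fold cross-validated
accuracy on the training side only, then refit and scored once on the
untouched test side.  Benchmarks cross two axes: the feature condition
(raw vs preprocessed vectors) and the acquisition condition (all 3-7 samples
per training participant vs a single seeded sample each).

The Random Forest grid contains the reference optimum (n_estimators = 200,
max_depth = 20, min_samples_split = 5, criterion = 'gini'); the other six
grids are deliberately small so the full 7-model benchmark runs in minutes
on one CPU.  Distance- and gradient-based models (SVM, k-NN, MLP, logistic
regression) are wrapped in a standardization pipeline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import SampleTable, Split
from .evaluate import binomial_ci
from .exceptions import ConfigError

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "FittedModel",
    "Benchmark",
    "default_model_specs",
    "build_estimator",
    "tune_and_train",
    "predict",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "random_forest",
    "gradient_boosting",
    "svm",
    "knn",
    "mlp",
    "logistic_regression",
    "naive_bayes",
)

_SCALED = {"svm", "knn", "mlp", "logistic_regression"}


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier plus its hyperparameter grid."""

    name: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model {self.name!r}")
        if not self.grid:
            raise ConfigError("hyperparameter grid must be non-empty")

    @property
    def n_candidates(self) -> int:
        n = 1
        for v in self.grid.values():
            n *= len(v)
        return n


def default_model_specs(names=MODEL_NAMES) -> dict:
    """The benchmark's standard grids, keyed by model name."""
    grids = {
        "random_forest": {
            "n_estimators": [100, 200],
            "max_depth": [10, 20],
            "min_samples_split": [2, 5],
            "criterion": ["gini"],
        },
        "gradient_boosting": {
            "n_estimators": [100],
            "learning_rate": [0.05, 0.1],
            "max_depth": [2, 3],
        },
        "svm": {"clf__C": [0.5, 1.0, 5.0], "clf__kernel": ["rbf"]},
        "knn": {"clf__n_neighbors": [3, 5, 9]},
        "mlp": {"clf__hidden_layer_sizes": [(32,), (64,)], "clf__alpha": [1e-4]},
        "logistic_regression": {"clf__C": [0.5, 1.0, 5.0]},
        "naive_bayes": {"var_smoothing": [1e-9, 1e-6]},
    }
    return {name: ModelSpec(name, grids[name]) for name in names}


def build_estimator(name: str, seed: int = 0):
    """Instantiate the (optionally standardized) estimator for ``name``."""
    if name == "random_forest":
        est = RandomForestClassifier(random_state=seed)
    elif name == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed)
    elif name == "svm":
        est = SVC(random_state=seed)
    elif name == "knn":
        est = KNeighborsClassifier()
    elif name == "mlp":
        est = MLPClassifier(max_iter=600, random_state=seed)
    elif name == "logistic_regression":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif name == "naive_bayes":
        est = GaussianNB()
    else:
        raise ConfigError(f"unknown model {name!r}")
    if name in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass(frozen=True)
class FittedModel:
    """A tuned, refit classifier with its selection diagnostics."""

    name: str
    estimator: object = field(repr=False)
    best_params: dict
    cv_accuracy: float
    n_features: int


def tune_and_train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Exhaustive grid search with stratified k-fold CV accuracy; refit on all.

    Deterministic given the seed (fold shuffling and estimator randomness
    both derive from it).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigError("training labels contain a single class")
    if counts.min() < folds:
        raise ConfigError(
            f"need at least {folds} samples per class for {folds}-fold CV, "
            f"got {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        build_estimator(spec.name, seed),
        spec.grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny grids
        search.fit(X, y)
    return FittedModel(
        name=spec.name,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_accuracy=float(search.best_score_),
        n_features=X.shape[1],
    )


def predict(model: FittedModel, X: np.ndarray):
    """Predict binary labels (plus class-probability scores when available)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigError("feature matrix must be 2-D and non-empty")
    if X.shape[1] != model.n_features:
        raise ConfigError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.n_features}"
        )
    labels = np.asarray(model.estimator.predict(X), dtype=int)
    scores = None
    if hasattr(model.estimator, "predict_proba"):
        scores = np.asarray(model.estimator.predict_proba(X), dtype=float)
    return labels, scores


@dataclass(frozen=True)
class Benchmark:
    """Results of a model x feature-condition x acquisition-condition sweep.

    ``table`` has one row per cell with CV and test accuracies in percent;
    ``models`` and ``predictions`` are keyed by (model, features, acquisition).
    """

    table: pd.DataFrame = field(repr=False)
    models: dict = field(repr=False)
    predictions: dict = field(repr=False)
    test_sample_ids: tuple
    seed: int

    def cell(self, model: str, features: str = "preprocessed",
             acquisition: str = "multi") -> pd.Series:
        t = self.table
        m = (t["model"] == model) & (t["features"] == features) & (
            t["acquisition"] == acquisition)
        if not m.any():
            raise KeyError((model, features, acquisition))
        return t[m].iloc[0]


def _single_sample_ids(meta: pd.DataFrame, rng: np.random.Generator) -> set:
    """One seeded sample id per participant (first after a seeded shuffle)."""
    chosen = set()
    for pid, group in meta.groupby("participant_id", sort=True):
        ids = group["sample_id"].to_numpy()
        chosen.add(ids[rng.permutation(len(ids))[0]])
    return chosen


def run_benchmark(
    table: SampleTable,
    split: Split,
    specs: dict | None = None,
    feature_sets: tuple = ("raw", "preprocessed"),
    acquisitions: tuple = ("multi",),
    folds: int = 5,
    seed: int = 0,
    ci_level: float = 0.95,
) -> Benchmark:
    """Tune, train and test every model under every requested condition.

    All cells share the same participant-level split; the single-sample
    acquisition condition thins only the *training* side to one seeded
    sample per participant, the test side is never touched by tuning.
    """
    if specs is None:
        specs = default_model_specs()
    for fs in feature_sets:
        if fs not in table.features:
            raise ConfigError(f"feature set {fs!r} not present in table")

    train_tab = table.select_samples(split.train_sample_ids)
    test_tab = table.select_samples(split.test_sample_ids)
    if len(train_tab) == 0 or len(test_tab) == 0:
        raise ConfigError("split leaves an empty train or test side")
    y_test = test_tab.labels

    rng = np.random.default_rng(seed)
    single_ids = _single_sample_ids(train_tab.meta, rng)

    rows, models, predictions = [], {}, {}
    for features in feature_sets:
        for acq in acquisitions:
            if acq == "multi":
                tr = train_tab
            elif acq == "single":
                tr = train_tab.select_samples(single_ids)
            else:
                raise ConfigError(f"unknown acquisition condition {acq!r}")
            X_train, y_train = tr.features[features], tr.labels
            X_test = test_tab.features[features]
            for name, spec in specs.items():
                fitted = tune_and_train(spec, X_train, y_train, folds, seed)
                y_pred, _ = predict(fitted, X_test)
                correct = int((y_pred == y_test).sum())
                acc = correct / len(y_test)
                lo, hi = binomial_ci(correct, len(y_test), level=ci_level)
                key = (name, features, acq)
                models[key] = fitted
                predictions[key] = y_pred
                rows.append(
                    {
                        "model": name,
                        "features": features,
                        "acquisition": acq,
                        "cv_accuracy_pct": 100 * fitted.cv_accuracy,
                        "test_accuracy_pct": 100 * acc,
                        "ci_low_pct": 100 * lo,
                        "ci_high_pct": 100 * hi,
                        "n_test": len(y_test),
                        "best_params": json.dumps(fitted.best_params, sort_keys=True),
                    }
                )
                logger.info(
                    "benchmark %s/%s/%s: CV %.1f%%, test %.1f%%",
                    name, features, acq,
                    100 * fitted.cv_accuracy, 100 * acc,
                )
    return Benchmark(
        table=pd.DataFrame(rows),
        models=models,
        predictions=predictions,
        test_sample_ids=tuple(split.test_sample_ids),
        seed=seed,
    )
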