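"""Uniform registry of the nine classification algorithms.

Each algorithm is wrapped in :class:`StageClassifier`, a scikit-learn
compatible estimator exposing the same three contracts everywhere:
``fit`` (deterministic given data and seed), ``predict_score`` (a
continuous, higher-is-more-AD-like score — class probability where the
learner provides one, signed distance to the decision boundary for the
perceptron and the SVM), and ``predict`` (hard 0/1 labels, ties at the
decision threshold resolved to 1). Scale-sensitive learners (logistic,
perceptron, KNN, SVM) standardize features internally using training
statistics only; the scaler is part of the frozen model, so no
information leaks from validation folds or test cohorts.

Hyperparameters are a fixed, overridable reference configuration; no
tuning is performed anywhere in the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import FeatureMatrix
from .exceptions import DegenerateTrainingError, FeatureMismatchError

#: Canonical algorithm names, in the registry's fixed order.
ALGORITHM_NAMES = (
    "logistic",
    "perceptron",
    "decision_tree",
    "boosted_tree",
    "gradient_boosting",
    "naive_bayes",
    "random_forest",
    "knn",
    "svm",
)

#: Human-readable labels used in reports.
ALGORITHM_LABELS = {
    "logistic": "Logistic",
    "perceptron": "Perceptron",
    "decision_tree": "Decision Tree",
    "boosted_tree": "Boosted Decision Tree",
    "gradient_boosting": "Gradient Boosting",
    "naive_bayes": "Naive Bayes",
    "random_forest": "Random Forests",
    "knn": "K-Nearest Neighbor",
    "svm": "Support Vector Machine",
}

# Learners whose geometry depends on feature scale get an internal
# standardizer fit on training data only.
_SCALED = frozenset({"logistic", "perceptron", "knn", "svm"})

# Learners scored by signed distance to the decision boundary rather
# than a class probability (threshold 0 instead of 0.5).
_DECISION_FUNCTION = frozenset({"perceptron", "svm"})

#: Reference hyperparameter configuration (fixed, versioned with the
#: package; any entry can be overridden per run).
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "logistic": {"max_iter": 2000},
    "perceptron": {"max_iter": 1000},
    "decision_tree": {},
    "boosted_tree": {"n_estimators": 100},
    "gradient_boosting": {"n_estimators": 100},
    "naive_bayes": {},
    "random_forest": {"n_estimators": 500},
    "knn": {"n_neighbors": 5},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}


#: Lighter ensemble sizes for calibration/power studies that need many
#: thousands of fits (repeated-replicate null runs). The empirical
#: p-value of the Gini distribution is calibrated for any fitted
#: classifier, so ensemble size does not affect null behaviour; the
#: reference configuration above remains the default for analysis runs.
REDUCED_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {"n_estimators": 50},
    "boosted_tree": {"n_estimators": 25},
    "gradient_boosting": {"n_estimators": 25},
}


def _build_base_estimator(name: str, params: dict, random_state: int):
    if name == "logistic":
        return LogisticRegression(random_state=random_state, **params)
    if name == "perceptron":
        return Perceptron(random_state=random_state, **params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=random_state, **params)
    if name == "boosted_tree":
        params = dict(params)
        depth = params.pop("max_depth", 1)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth),
            random_state=random_state,
            **params,
        )
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=random_state, **params)
    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=random_state, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "svm":
        return SVC(random_state=random_state, **params)
    raise ValueError(
        f"unknown algorithm {name!r}; valid names: {', '.join(ALGORITHM_NAMES)}"
    )


def _as_array(X, feature_names=None):
    """Accept a FeatureMatrix or an ndarray; return (array, names)."""
    if isinstance(X, FeatureMatrix):
        return X.values, tuple(X.feature_names)
    return np.asarray(X, dtype=float), (None if feature_names is None else tuple(feature_names))


class StageClassifier(BaseEstimator, ClassifierMixin):
    """One of the nine registry algorithms under a uniform contract.

    Parameters
    ----------
    algorithm:
        One of :data:`ALGORITHM_NAMES`.
    hyperparams:
        Overrides merged on top of :data:`DEFAULT_HYPERPARAMETERS`.
    random_state:
        Seed for every stochastic component of the learner.

    Attributes (after :meth:`fit`)
    ------------------------------
    pipeline_ : fitted sklearn Pipeline (scaler where applicable + learner)
    feature_names_ : column names captured at fit time, or None
    classes_ : the two class labels, ascending
    threshold_ : decision threshold on the continuous score
    """

    def __init__(self, algorithm: str = "svm", hyperparams: dict | None = None,
                 random_state: int = 0):
        self.algorithm = algorithm
        self.hyperparams = hyperparams
        self.random_state = random_state

    def _resolved_params(self) -> dict:
        if self.algorithm not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid names: "
                f"{', '.join(ALGORITHM_NAMES)}"
            )
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(self.hyperparams or {})
        return params

    def fit(self, X, y=None, feature_names=None):
        if isinstance(X, FeatureMatrix) and y is None:
            y = X.labels
        values, names = _as_array(X, feature_names)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateTrainingError(
                f"{self.algorithm}: training labels contain a single class "
                f"({classes.tolist()})"
            )
        if classes.size > 2:
            raise ValueError("StageClassifier is strictly binary")
        base = _build_base_estimator(
            self.algorithm, self._resolved_params(), int(self.random_state) % (2**31)
        )
        steps = []
        if self.algorithm in _SCALED:
            steps.append(("scale", StandardScaler()))
        steps.append(("learner", base))
        self.pipeline_ = Pipeline(steps)
        self.pipeline_.fit(values, y)
        self.feature_names_ = names
        self.classes_ = classes
        self.threshold_ = 0.0 if self.algorithm in _DECISION_FUNCTION else 0.5
        return self

    def _check_features(self, X, feature_names):
        values, names = _as_array(X, feature_names)
        if names is not None and self.feature_names_ is not None:
            if names != self.feature_names_:
                raise FeatureMismatchError(
                    f"model was fit on features {list(self.feature_names_)}, "
                    f"got {list(names)}"
                )
        if self.feature_names_ is not None and values.shape[1] != len(self.feature_names_):
            raise FeatureMismatchError(
                f"model expects {len(self.feature_names_)} features, "
                f"got {values.shape[1]}"
            )
        return values

    def predict_score(self, X, feature_names=None) -> np.ndarray:
        """Continuous score per row; higher = more AD-like (class 1)."""
        values = self._check_features(X, feature_names)
        if self.algorithm in _DECISION_FUNCTION:
            return np.asarray(self.pipeline_.decision_function(values), dtype=float)
        proba = self.pipeline_.predict_proba(values)
        return np.asarray(proba[:, 1], dtype=float)

    def predict(self, X, feature_names=None) -> np.ndarray:
        """Hard labels; score exactly at the threshold maps to class 1."""
        score = self.predict_score(X, feature_names)
        hi, lo = self.classes_[1], self.classes_[0]
        return np.where(score >= self.threshold_, hi, lo)

    def score(self, X, y=None):
        """Accuracy, for sklearn model-selection compatibility."""
        if isinstance(X, FeatureMatrix) and y is None:
            y = X.labels
        values = self._check_features(X, None)
        return float(np.mean(self.predict(values) == np.asarray(y)))


def make_classifier(algorithm: str, hyperparams: dict | None = None,
                    random_state: int = 0) -> StageClassifier:
    """Thin functional constructor over :class:`StageClassifier`."""
    return StageClassifier(algorithm=algorithm, hyperparams=hyperparams,
                           random_state=random_state)


def save_model(model: StageClassifier, path: str | Path) -> None:
    """Serialize a fitted model so validation can run in a later invocation."""
    joblib.dump({"format": "xmittn-frozen-model", "version": 1, "model": model}, path)


def load_model(path: str | Path) -> StageClassifier:
    payload = joblib.load(path)
    if not (isinstance(payload, dict) and payload.get("format") == "xmittn-frozen-model"):
        raise ValueError(f"{path}: not a frozen-model artifact")
    return payload["model"]


__all__ = [
    "ALGORITHM_NAMES",
    "ALGORITHM_LABELS",
    "DEFAULT_HYPERPARAMETERS",
    "StageClassifier",
    "make_classifier",
    "save_model",
    "load_model",
    "clone",
]
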