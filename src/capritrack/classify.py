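"""Frame-wise classifier comparators: random forest, RBF-SVM, neural net.

These classifiers see each frame's observation vector z_k = (x, y, L) in
isolation — no temporal structure — which is exactly what makes them the
benchmark against the HMM's smoothed decoding.  Hyperparameters follow the
reference analysis: the forest considers a single feature per split
(mtry = 1, 500 trees); the SVM uses an RBF kernel with kernel width and cost
grid-searched under k-fold cross-validation where k comes from Sturges'
formula; the network has a single hidden layer of 10 units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ObservationSequence

METHODS = ("rf", "svm", "nn")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "rf": {"max_features": 1, "n_trees": 500},
    # Grid bounds are configurable; the selected pair is recorded on the
    # trained handle rather than hard-coded.
    "svm": {
        "gamma_grid": tuple(10.0**e for e in range(-2, 6)),
        "cost_grid": tuple(10.0**e for e in range(-1, 4)),
        "folds": None,  # None -> Sturges' formula from the sample size
    },
    "nn": {"hidden_units": 10, "max_iter": 500},
}


@dataclass
class ClassifierSpec:
    """Recipe for one frame-wise comparator."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.method])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


@dataclass
class TrainedClassifier:
    """Fitted comparator plus the hyperparameters actually used."""

    spec: ClassifierSpec
    estimator: object
    selected: dict = field(default_factory=dict)

    def predict(self, Z) -> np.ndarray:
        return predict_frames(self, Z)


def sturges_folds(n: int) -> int:
    """Cross-validation fold count k = ⌊1 + log2(n)⌋ (Sturges' formula)."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    return int(math.floor(1 + math.log2(n)))


def train_frame_classifier(
    spec: ClassifierSpec, features: np.ndarray, labels: np.ndarray
) -> TrainedClassifier:
    """Fit the comparator described by ``spec`` on stacked (n, 3) features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features and labels must be aligned 2-D/1-D arrays")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("single-class training set")
    if (X.std(axis=0) == 0).any():
        warnings.warn("constant feature column in training data")
    hp = spec.hyperparameters
    selected: dict = {}

    if spec.method == "rf":
        est = RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_features=hp["max_features"],
            random_state=spec.seed,
        )
        est.fit(X, y)
    elif spec.method == "svm":
        folds = hp["folds"] if hp["folds"] is not None else sturges_folds(len(X))
        min_class = int(min(np.unique(y, return_counts=True)[1]))
        if folds > min_class:
            warnings.warn(
                f"reducing CV folds from {folds} to {min_class} (smallest class size)"
            )
            folds = max(2, min_class)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        base = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        grid = GridSearchCV(
            base,
            {"svc__gamma": list(hp["gamma_grid"]), "svc__C": list(hp["cost_grid"])},
            cv=cv,
            n_jobs=None,
        )
        grid.fit(X, y)
        est = grid.best_estimator_
        selected = {
            "gamma": grid.best_params_["svc__gamma"],
            "cost": grid.best_params_["svc__C"],
            "folds": folds,
        }
    else:  # nn
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(hp["hidden_units"],),
                        max_iter=hp["max_iter"],
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            est.fit(X, y)
    return TrainedClassifier(spec=spec, estimator=est, selected=selected)


def predict_frames(clf: TrainedClassifier, Z) -> np.ndarray:
    """Predict one state per frame, independently across frames."""
    z = Z.z if isinstance(Z, ObservationSequence) else np.asarray(Z, dtype=float)
    if len(z) == 0:
        return np.array([], dtype=int)
    z = np.atleast_2d(z)
    if z.shape[1] != 3:
        raise ValueError(f"expected 3 features per frame, got {z.shape[1]}")
    return np.asarray(clf.estimator.predict(z), dtype=int)
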