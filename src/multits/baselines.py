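"""Non-convolutional baselines behind one fit/predict contract.

Three classifiers with fixed hyperparameters: k-nearest neighbours (k=21),
random forest (100 trees) and a fully connected network (two hidden layers
of 100 logistic-sigmoid units trained with Adam, 200 epochs, batch 100).
They consume the band-power features from :mod:`multits.spectral`; features
are z-scored with statistics fitted on the training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import ConfigError, DegenerateDataError, ShapeError

__all__ = ["BaselineSpec", "fit_baseline", "predict_baseline",
           "FittedBaseline"]

_KINDS = ("knn", "rf", "fcn")


@dataclass(frozen=True)
class BaselineSpec:
    """Declarative baseline description; hyperparameters are fixed."""

    kind: str
    seed: int = 0
    standardize: bool = True
    n_neighbors: int = 21          # knn
    n_trees: int = 100             # rf
    hidden: tuple = (100, 100)     # fcn
    epochs: int = 200              # fcn (0 -> majority-class dummy)
    batch: int = 100               # fcn

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown baseline kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "seed": self.seed,
                "standardize": self.standardize}


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    pipeline: Pipeline
    n_features: int
    classes_: np.ndarray


def _make_estimator(spec: BaselineSpec, n_train: int):
    if spec.kind == "knn":
        k = spec.n_neighbors
        if n_train < k:
            warnings.warn(
                f"only {n_train} training rows; clamping k from {k}",
                stacklevel=3)
            k = n_train
        return KNeighborsClassifier(n_neighbors=k)
    if spec.kind == "rf":
        return RandomForestClassifier(n_estimators=spec.n_trees,
                                      random_state=spec.seed)
    if spec.epochs == 0:
        return DummyClassifier(strategy="most_frequent")
    return MLPClassifier(hidden_layer_sizes=spec.hidden,
                         activation="logistic", solver="adam",
                         max_iter=spec.epochs,
                         batch_size=min(spec.batch, max(1, n_train)),
                         random_state=spec.seed)


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y) -> FittedBaseline:
    """Fit one baseline; deterministic for a fixed spec seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ShapeError("X must be 2-D with one label per row")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training labels contain a single class")
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _make_estimator(spec, len(X))))
    pipe = Pipeline(steps)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", category=UserWarning,
                                module="sklearn")
        pipe.fit(X, y)
    return FittedBaseline(spec=spec, pipeline=pipe, n_features=X.shape[1],
                          classes_=pipe.named_steps["clf"].classes_)


def predict_baseline(model: FittedBaseline, X: np.ndarray) -> np.ndarray:
    """One label per row, drawn from the training label set."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ShapeError(
            f"expected {model.n_features} feature columns, got "
            f"{X.shape[1] if X.ndim == 2 else X.shape}")
    if len(X) == 0:
        return np.array([], dtype=model.classes_.dtype)
    return model.pipeline.predict(X)
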