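"""The four spectral classifier families behind one fit/predict contract.

* k-nearest neighbors in Euclidean spectral space (default k=3),
* the representative-spectrum (nearest class-mean) classifier,
* a random forest with a grid-search tuner over the standard spans, and
* a fully connected network: three ReLU hidden layers and a 3-way
  softmax output trained with Adam on cross-entropy.

All estimators follow the scikit-learn protocol (``fit``/``predict``,
fitted attributes with trailing underscores) and operate on normalized
``(n_samples, n_bins)`` matrices with string class labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KNNSpec:
    k: int = 3

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ModelError("k must be a positive odd integer")


@dataclass(frozen=True)
class RFSpec:
    """Random-forest hyperparameters; defaults are the tuned operating point
    (200 trees, sqrt feature rule, unlimited depth, bootstrap on)."""

    n_estimators: int = 200
    max_features: str = "sqrt"
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    bootstrap: bool = True


#: The published search spans for the random-forest grid search.
RF_DEFAULT_GRID: dict[str, list] = {
    "n_estimators": list(range(200, 1801, 200)),
    "max_features": ["sqrt", "log2"],
    "max_depth": list(range(10, 101, 10)) + [None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "bootstrap": [True, False],
}


@dataclass(frozen=True)
class MLPSpec:
    """Fully connected network: three ReLU hidden layers, 3-way softmax.

    The architecture items (three hidden layers, softmax output, Adam,
    cross-entropy loss) are fixed; widths, learning rate and schedule are
    configurable.  The default learning rate 1e-5 suits corpora of ~1e5
    spectra; small training sets need a proportionally larger rate (see
    docs/methods.md).
    """

    hidden_sizes: tuple[int, int, int] = (1024, 256, 64)
    learning_rate: float = 1e-5
    epochs: int = 200
    batch_size: int = 64
    early_stopping: bool = True
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_sizes) != 3:
            raise ModelError("exactly three hidden layers are required")
        if any(h < 1 for h in self.hidden_sizes):
            raise ModelError("hidden layer widths must be positive")


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _validate_X(X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.any(~np.isfinite(X)):
        raise ModelError("spectra contain non-finite values")
    return X


class KNNSpectrumClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbor vote in Euclidean spectral space.

    Vote ties are broken by the nearest single neighbor among the tied
    classes, then lexicographic class order — never by training-sample
    insertion order.
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X, y):
        X = _validate_X(X)
        y = np.asarray(y, dtype=object)
        if len(y) != X.shape[0]:
            raise ModelError("X and y length mismatch")
        if self.k < 1 or self.k > X.shape[0]:
            raise ModelError(f"k={self.k} infeasible for {X.shape[0]} samples")
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        self._nn = NearestNeighbors(n_neighbors=self.k, metric="euclidean").fit(X)
        self._y = y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = _validate_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ModelError(f"expected {self.n_features_in_} bins, got {X.shape[1]}")
        dist, idx = self._nn.kneighbors(X)
        out = np.empty(X.shape[0], dtype=object)
        for i in range(X.shape[0]):
            neigh_labels = self._y[idx[i]]
            votes: dict[str, int] = {}
            for lab in neigh_labels:
                votes[lab] = votes.get(lab, 0) + 1
            top = max(votes.values())
            tied = sorted(c for c, v in votes.items() if v == top)
            if len(tied) == 1:
                out[i] = tied[0]
            else:
                # neighbors are distance-sorted: first tied-class hit wins
                for lab in neigh_labels:
                    if lab in tied:
                        out[i] = lab
                        break
        return out


class RepresentativeSpectrumClassifier(ClassifierMixin, BaseEstimator):
    """Nearest class-mean ("representative spectrum") classifier.

    Each class is summarized by the arithmetic mean of its training
    spectra; a query takes the label of the Euclidean-nearest mean.
    Distance ties resolve to the lexicographically smaller class.
    """

    def fit(self, X, y):
        X = _validate_X(X)
        y = np.asarray(y, dtype=object)
        if X.shape[0] == 0:
            raise ModelError("cannot fit on an empty dataset")
        if len(y) != X.shape[0]:
            raise ModelError("X and y length mismatch")
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        self.centroids_ = np.stack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        X = _validate_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ModelError(f"expected {self.n_features_in_} bins, got {X.shape[1]}")
        # squared Euclidean distances to every centroid
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2 * X @ self.centroids_.T
            + np.sum(self.centroids_**2, axis=1)[None, :]
        )
        # classes_ is sorted, argmin takes the first minimum: lexicographic ties
        return self.classes_[np.argmin(d2, axis=1)]


class RandomForestSpectrumClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over binned spectra; thin wrapper fixing the spec surface."""

    def __init__(self, spec: RFSpec | None = None, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def _make(self) -> RandomForestClassifier:
        spec = self.spec if self.spec is not None else RFSpec()
        return RandomForestClassifier(
            n_estimators=spec.n_estimators,
            max_features=spec.max_features,
            max_depth=spec.max_depth,
            min_samples_split=spec.min_samples_split,
            min_samples_leaf=spec.min_samples_leaf,
            bootstrap=spec.bootstrap,
            random_state=self.seed,
            n_jobs=1,
        )

    def fit(self, X, y):
        X = _validate_X(X)
        self._rf = self._make().fit(X, np.asarray(y, dtype=object))
        self.classes_ = self._rf.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._rf.predict(_validate_X(X))

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return self._rf.predict_proba(_validate_X(X))


class MLPSpectrumClassifier(ClassifierMixin, BaseEstimator):
    """Three-hidden-layer ReLU network with a softmax output.

    Requires normalized input (values in [0, 1]): on the raw 1e5-1e7
    intensity scale the activations saturate and training stalls.
    """

    def __init__(self, spec: MLPSpec | None = None):
        self.spec = spec

    def fit(self, X, y):
        spec = self.spec if self.spec is not None else MLPSpec()
        X = _validate_X(X)
        if np.any(X < 0) or np.any(X > 1):
            raise ModelError(
                "MLP requires normalized spectra in [0, 1]; apply "
                "LogMinMaxNormalizer first"
            )
        self._mlp = MLPClassifier(
            hidden_layer_sizes=spec.hidden_sizes,
            activation="relu",
            solver="adam",
            learning_rate_init=spec.learning_rate,
            batch_size=min(spec.batch_size, X.shape[0]),
            max_iter=spec.epochs,
            shuffle=True,
            early_stopping=spec.early_stopping,
            validation_fraction=0.1,
            n_iter_no_change=spec.patience,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._mlp.fit(X, np.asarray(y, dtype=object))
        self.classes_ = self._mlp.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._mlp.predict(_validate_X(X))

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return self._mlp.predict_proba(_validate_X(X))


def make_classifier(family: str, seed: int = 0, **kwargs) -> BaseEstimator:
    """Instantiate one of the four model families by name."""
    family = family.lower()
    if family == "knn":
        return KNNSpectrumClassifier(k=kwargs.get("k", 3))
    if family == "centroid":
        return RepresentativeSpectrumClassifier()
    if family == "rf":
        return RandomForestSpectrumClassifier(spec=kwargs.get("spec"), seed=seed)
    if family == "mlp":
        spec = kwargs.get("spec")
        if spec is None:
            spec = MLPSpec(seed=seed)
        return MLPSpectrumClassifier(spec=spec)
    raise ModelError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Cross-validated tuning
# ---------------------------------------------------------------------------

def _cv_macro_f1(
    estimator: BaseEstimator,
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    iterations: int,
    seed: int,
) -> float:
    """Mean macro-F1 over `iterations` random re-shufflings of `folds`-fold CV."""
    scores = []
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        for train_idx, val_idx in skf.split(X, y):
            est = clone(estimator)
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[val_idx])
            scores.append(
                f1_score(y[val_idx].astype(str), pred.astype(str), average="macro")
            )
    return float(np.mean(scores))


def tune_k(
    X,
    y,
    candidate_ks: Sequence[int] = (1, 3, 5, 7, 9),
    folds: int = 3,
    iterations: int = 10,
    seed: int = 0,
) -> KNNSpec:
    """Pick k by repeated stratified 3-fold CV on macro-F1; ties favor smaller k."""
    X = _validate_X(X)
    y = np.asarray(y, dtype=object)
    best: tuple[float, int] | None = None
    for k in sorted(candidate_ks):
        if k % 2 == 0 or k < 1:
            raise ModelError(f"candidate k={k} must be a positive odd integer")
        max_train = (folds - 1) * X.shape[0] // folds
        if k > max_train:
            continue
        score = _cv_macro_f1(KNNSpectrumClassifier(k=k), X, y, folds, iterations, seed)
        if best is None or score > best[0]:
            best = (score, k)
    if best is None:
        raise ModelError("no feasible candidate k")
    return KNNSpec(k=best[1])


def grid_search_rf(
    X,
    y,
    grid: dict[str, list] | None = None,
    folds: int = 3,
    iterations: int = 10,
    seed: int = 0,
) -> RFSpec:
    """Exhaustive grid search for the random forest, scored by repeated-CV macro-F1.

    Ties are broken toward the simpler model: fewer trees, then shallower
    depth (a concrete limit beats "no limit").
    """
    X = _validate_X(X)
    y = np.asarray(y, dtype=object)
    grid = grid if grid is not None else RF_DEFAULT_GRID
    keys = list(grid)
    best: tuple[float, tuple, RFSpec] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        spec = RFSpec(**params)
        est = RandomForestSpectrumClassifier(spec=spec, seed=seed)
        score = _cv_macro_f1(est, X, y, folds, iterations, seed)
        depth_rank = np.inf if spec.max_depth is None else spec.max_depth
        sort_key = (-score, spec.n_estimators, depth_rank)
        if best is None or sort_key < best[1]:
            best = (score, sort_key, spec)
    if best is None:
        raise ModelError("empty grid")
    return best[2]
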