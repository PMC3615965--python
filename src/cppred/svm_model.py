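"""RBF-kernel SVM training with exhaustive grid search over (g, c, j).

The classifier is a soft-margin SVM with a radial basis function kernel.
Three hyper-parameters are tuned by exhaustive grid search with k-fold
cross-validated accuracy as the selection criterion:

* ``g`` — RBF width (gamma), log-spaced over [1e-4, 10];
* ``c`` — error cost, integers 1..15;
* ``j`` — cost-factor weighting errors on the positive class, 1..5
  (mapped to a per-class weight on the positive class).

Ties are broken deterministically toward the smaller ``c``, then smaller
``g``, then smaller ``j``.  The winner is refit on all the data.  Models
persist to disk and reload bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import (
    DegenerateFeatureError,
    ModelFileError,
    SchemeMismatchError,
    SingleClassError,
)
from .features import FeatureVector

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridSpec:
    """Hyper-parameter grid for the RBF-SVM search."""

    gamma: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
    cost: tuple[float, ...] = tuple(float(c) for c in range(1, 16))
    weight: tuple[float, ...] = tuple(float(j) for j in range(1, 6))

    def __post_init__(self):
        for vals, name in ((self.gamma, "gamma"), (self.cost, "cost"),
                           (self.weight, "weight")):
            if not vals:
                raise ValueError(f"{name} grid is empty")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} grid must be positive")

    def combinations(self):
        """All (g, c, j) triples in deterministic tie-break order
        (ascending c, then g, then j; first max wins the search)."""
        return [(g, c, j) for c, g, j in
                product(sorted(self.cost), sorted(self.gamma), sorted(self.weight))]


@dataclass
class TrainedModel:
    """A fitted RBF-SVM bound to the feature scheme it was trained with."""

    scheme: str
    gamma: float
    cost: float
    weight: float
    estimator: SVC
    threshold: float = 0.0
    metadata: dict = field(default_factory=dict)

    def _check_scheme(self, scheme: str):
        if scheme != self.scheme:
            raise SchemeMismatchError(
                f"model expects {self.scheme!r} features, got {scheme!r}")


def _fit_svc(X, y, g, c, j) -> SVC:
    return SVC(kernel="rbf", gamma=g, C=c, class_weight={1: j}).fit(X, y)


def grid_search(X: np.ndarray, y: np.ndarray, grid: GridSpec, k: int,
                seed: int) -> tuple[tuple[float, float, float], float]:
    """Exhaustive (g, c, j) search by mean k-fold CV accuracy.

    Returns the winning triple and its CV accuracy.  Fold assignment is
    stratified and derived from ``seed`` only, so the search is a pure
    function of its arguments.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training data must contain both classes")
    if np.all(X == X[0]):
        raise DegenerateFeatureError("feature matrix has zero variance")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best, best_acc = None, -1.0
    for g, c, j in GridSpec.combinations(grid):
        accs = []
        for tr, te in folds:
            clf = _fit_svc(X[tr], y[tr], g, c, j)
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: earlier (smaller c, g, j) wins ties
            best, best_acc = (g, c, j), acc
    return best, best_acc


def train(X, y, grid: GridSpec | None = None, k: int = 5, seed: int = 0,
          scheme: str = "composition") -> TrainedModel:
    """Grid-search hyper-parameters and refit the winner on all data."""
    grid = grid or GridSpec()
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    (g, c, j), cv_acc = grid_search(Xa, ya, grid, k, seed)
    est = _fit_svc(Xa, ya, g, c, j)
    meta = {"n": len(ya), "seed": seed, "cv_folds": k,
            "cv_accuracy": cv_acc, "format_version": _MODEL_FORMAT_VERSION}
    return TrainedModel(scheme=scheme, gamma=g, cost=c, weight=j,
                        estimator=est, metadata=meta)


def decision_score(m: TrainedModel, x: FeatureVector | np.ndarray) -> float:
    """Signed distance from the decision boundary; larger = more CPP-like."""
    if isinstance(x, FeatureVector):
        m._check_scheme(x.scheme)
        x = x.values
    return float(m.estimator.decision_function(np.asarray(x, float).reshape(1, -1))[0])


def decision_scores(m: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decision_score` over a feature matrix."""
    return np.asarray(m.estimator.decision_function(np.asarray(X, dtype=float)))


def classify(m: TrainedModel, x: FeatureVector | np.ndarray,
             threshold: float | None = None) -> str:
    """``CPP`` iff the decision score is >= the threshold (default 0)."""
    thr = m.threshold if threshold is None else threshold
    return "CPP" if decision_score(m, x) >= thr else "non-CPP"


def save_model(m: TrainedModel, path: str | Path) -> Path:
    """Persist a model; :func:`load_model` restores bit-exact scoring."""
    path = Path(path)
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "scheme": m.scheme, "gamma": m.gamma, "cost": m.cost,
        "weight": m.weight, "threshold": m.threshold,
        "metadata": m.metadata, "estimator": m.estimator,
    }
    joblib.dump(payload, path)
    return path


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as e:
        raise ModelFileError(f"cannot read model file {path}: {e}") from e
    if not isinstance(payload, dict) or \
            payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ModelFileError(f"incompatible or corrupt model file {path}")
    return TrainedModel(scheme=payload["scheme"], gamma=payload["gamma"],
                        cost=payload["cost"], weight=payload["weight"],
                        estimator=payload["estimator"],
                        threshold=payload["threshold"],
                        metadata=payload["metadata"])
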