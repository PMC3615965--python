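"""Cross-validation machinery and classifier performance measures.

Threshold-dependent measures come from the confusion matrix on the
0-100 percent scale:

    Sn  = TP / (TP + FN) * 100
    Sp  = TN / (TN + FP) * 100
    Ac  = (TP + TN) / (TP + FP + TN + FN) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The threshold-independent measure is the area under the ROC curve,
computed as the Mann-Whitney rank statistic (ties averaged).

``cross_validate`` runs the full protocol: stratified outer folds, the
hyper-parameter grid search nested inside each training fold (so model
selection never sees the test fold), per-fold metrics, fold-averaged
summary.  In hybrid mode the motif bonus is applied to test-fold scores
only, from a motif set supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import SingleClassError, TooFewExamplesError, UndefinedMetricError
from .features import encode_dataset
from .motif_scan import Motif, has_motif_hit
from .peptide_core import PeptideDataset
from .svm_model import GridSpec, decision_scores, train

HYBRID_BONUS = 5.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion matrix is empty")


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)), tn=int(np.sum(~y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)), fn=int(np.sum(y_true & ~y_pred)))


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive examples")
    return c.tp / (c.tp + c.fn) * 100.0


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative examples")
    return c.tn / (c.tn + c.fp) * 100.0


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / (c.tp + c.fp + c.tn + c.fn) * 100.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (by convention) when any
    marginal sum is zero."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(denom))


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC via the Mann-Whitney rank statistic, plus ROC curve points.

    Ranks are midranks (ties averaged).  The curve is (1 - Sp, Sn) as
    fractions, one point per distinct score threshold plus the (0,0) and
    (1,1) anchors; its trapezoidal integral equals the rank AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("ROC needs both classes")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    # keep the last point of each tied-score run
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return float(auc), curve


def kfold_split(d: PeptideDataset, k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold test-index assignment, deterministic in seed."""
    labels = np.array([1 if p.label == "positive" else 0 for p in d])
    counts = np.bincount(labels, minlength=2)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise TooFewExamplesError(
            f"each class needs >= {k} members, have {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(d)), labels)]


def loocv_split(d: PeptideDataset) -> list[np.ndarray]:
    """Leave-one-out folds: n singleton test sets."""
    if len(d) < 2:
        raise TooFewExamplesError("leave-one-out needs n >= 2")
    return [np.array([i]) for i in range(len(d))]


@dataclass
class EvalReport:
    """Per-fold and averaged performance of one cross-validated model."""

    scheme: str
    mode: str
    k: int
    seed: int
    folds: pd.DataFrame           # one row per fold: Sn, Sp, Ac, MCC, AUC
    mean: pd.Series               # fold-averaged metrics
    pooled: pd.Series             # metrics on pooled test predictions
    selected_params: list = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        """Table in the conventional column order (Sn, Sp, Ac, MCC, AUC)."""
        t = self.folds.copy()
        t.loc["mean"] = self.mean
        return t[["sensitivity", "specificity", "accuracy", "mcc", "auc"]]


def _fold_metrics(y_true, scores, threshold) -> dict[str, float]:
    c = confusion(y_true, scores >= threshold)
    auc, _ = roc_auc(scores, y_true)
    return {"sensitivity": sensitivity(c), "specificity": specificity(c),
            "accuracy": accuracy(c), "mcc": mcc(c), "auc": auc}


def cross_validate(d: PeptideDataset, scheme: str = "composition",
                   grid: GridSpec | None = None, k: int = 5, seed: int = 0,
                   mode: str = "svm", motifs: list[Motif] | None = None,
                   e_threshold: float = 10.0, threshold: float = 0.0,
                   inner_k: int = 5) -> EvalReport:
    """Full cross-validated evaluation of the SVM or hybrid classifier.

    For each outer fold the grid search (its own ``inner_k``-fold CV) is
    run on the training portion only; the winning model is refit on the
    training portion and scored on the held-out fold.  In hybrid mode
    every test peptide with a motif hit at ``e_threshold`` gets the
    fixed +5 score bonus before thresholding.  Metrics are computed per
    fold and averaged; pooled-test-set metrics are reported alongside.
    """
    grid = grid or GridSpec()
    if mode not in ("svm", "hybrid"):
        raise ValueError("mode must be 'svm' or 'hybrid'")
    if mode == "hybrid" and not motifs:
        raise ValueError("hybrid mode requires motifs")
    X, y = encode_dataset(d, scheme)
    Xv = X.to_numpy()
    folds = kfold_split(d, k, seed)
    all_idx = np.arange(len(d))
    rows, params = [], []
    pooled_scores = np.empty(len(d))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = train(Xv[train_idx], y[train_idx], grid=grid, k=inner_k,
                      seed=seed, scheme=scheme)
        params.append((model.gamma, model.cost, model.weight))
        scores = decision_scores(model, Xv[test_idx])
        if mode == "hybrid":
            bonus = np.array([HYBRID_BONUS if has_motif_hit(d[i], motifs,
                                                            e_threshold) else 0.0
                              for i in test_idx])
            scores = scores + bonus
        pooled_scores[test_idx] = scores
        rows.append(_fold_metrics(y[test_idx], scores, threshold))
    folds_df = pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(k)])
    mean = folds_df.mean()
    pooled = pd.Series(_fold_metrics(y, pooled_scores, threshold))
    return EvalReport(scheme=scheme, mode=mode, k=k, seed=seed,
                      folds=folds_df, mean=mean, pooled=pooled,
                      selected_params=params)
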