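"""RBF-kernel classification of responder status and model-refinement sweeps.

Signature-gene panels discovered in one ancestry (EA tails) are evaluated
as classifier features in the other (AA tails): a radial-basis SVM is
trained and tested on repeated random stratified 90/10 splits, the test-
fold decision scores pooled over repeats, and the pooled scores summarized
as an ROC curve and its AUC.  Two refinement sweeps mirror the study
design: over the number of PCs corrected, and over the panel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .preprocess import DeltaExpression
from .signature import compute_signature, top_k_genes

__all__ = [
    "ClassifierEval",
    "RBFResponderClassifier",
    "train_rbf_classifier",
    "repeated_split_eval",
    "roc_curve",
    "auc",
    "evaluate_panel",
    "pc_sweep_eval",
    "gene_count_sweep",
]


@dataclass
class ClassifierEval:
    """Pooled evaluation of one (n_pcs, n_genes) configuration."""

    n_pcs: int
    n_genes: int
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    roc_points: np.ndarray  # (m, 2) array of (fpr, tpr)
    auc: float
    n_repeats: int
    seed: int | None


class RBFResponderClassifier(BaseEstimator, ClassifierMixin):
    """Radial-basis-kernel maximum-margin classifier.

    A thin, convention-fixing wrapper around :class:`sklearn.svm.SVC`:
    cost ``C`` defaults to 1 and the kernel width defaults to the median
    heuristic, ``gamma = 1 / median(squared pairwise training distances)``,
    so decision scores are real-valued with higher meaning more
    'high-responder'.  Deterministic given inputs and hyperparameters.
    """

    def __init__(self, C: float = 1.0, gamma: float | str = "median",
                 pos_label=None):
        self.C = C
        self.gamma = gamma
        self.pos_label = pos_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or not np.isfinite(X).all():
            raise ValueError("features must be a finite 2-D matrix")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        if len(classes) > 2:
            raise ValueError("binary classification only")
        if np.any(X.std(axis=0) == 0):
            warnings.warn("zero-variance feature(s) in the training set")
        pos = self.pos_label
        if pos is None:
            pos = "high" if "high" in classes else classes[1]
        self.classes_ = np.array([c for c in classes if c != pos] + [pos],
                                 dtype=classes.dtype)
        if self.gamma == "median":
            d2 = pdist(X, metric="sqeuclidean")
            d2 = d2[d2 > 0]
            self.gamma_ = 1.0 / np.median(d2) if d2.size else 1.0
        else:
            self.gamma_ = float(self.gamma)
        y_bin = (y == pos).astype(int)
        self.svc_ = SVC(C=self.C, kernel="rbf", gamma=self.gamma_)
        self.svc_.fit(X, y_bin)
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        return np.where(self.decision_function(X) > 0,
                        self.classes_[1], self.classes_[0])


def train_rbf_classifier(features, labels, **hyperparams) -> RBFResponderClassifier:
    """Fit an RBF classifier on (samples x genes) features."""
    return RBFResponderClassifier(**hyperparams).fit(features, labels)


def _stratified_partition(y: np.ndarray, n_folds: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Fold assignment 0..n_folds-1 with per-class balance."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(idx)) % n_folds
    return folds


def repeated_split_eval(features, labels, n_repeats: int = 5000,
                        n_folds: int = 10, seed: int | None = None,
                        **clf_params) -> tuple[np.ndarray, np.ndarray]:
    """Pool test-fold decision scores over repeated stratified splits.

    Each repeat draws one fresh class-stratified random partition into
    ``n_folds``; one fold is held out as the test set, the others train
    the classifier, and the test scores and labels join the pool.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < n_folds).any():
        warnings.warn("a class has fewer members than folds; "
                      "stratification is relaxed to >= 1 per fold")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    clf = RBFResponderClassifier(**clf_params)
    scores, lab = [], []
    done = 0
    while done < n_repeats:  # exactly n_repeats test folds enter the pool
        folds = _stratified_partition(y, n_folds, rng)
        test = folds == 0
        if len(np.unique(y[~test])) < 2:  # degenerate draw: redraw folds
            continue
        clf.fit(X[~test], y[~test])
        scores.append(clf.decision_function(X[test]))
        lab.append(y[test])
        done += 1
    return np.concatenate(scores), np.concatenate(lab)


def roc_curve(scores, labels, pos_label=None) -> np.ndarray:
    """ROC points by descending score threshold, tied scores advancing jointly.

    Returns an (m, 2) array of (false-positive-rate, true-positive-rate)
    from (0, 0) to (1, 1).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if pos_label is None:
        pos_label = "high" if "high" in classes else classes[1]
    fpr, tpr, _ = _sk_roc_curve(y == pos_label, np.asarray(scores, float),
                                drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(scores, labels, pos_label=None) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Computed from the rank statistic; equals the trapezoidal area under
    :func:`roc_curve`.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if pos_label is None:
        pos_label = "high" if "high" in classes else classes[1]
    pos = y == pos_label
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)  # average ranks handle ties as 1/2
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_panel(features, labels, *, n_pcs: int, n_genes: int,
                   n_repeats: int = 5000, n_folds: int = 10,
                   seed: int | None = None, **clf_params) -> ClassifierEval:
    """Repeated-split evaluation bundled into a ClassifierEval."""
    scores, lab = repeated_split_eval(features, labels, n_repeats=n_repeats,
                                      n_folds=n_folds, seed=seed, **clf_params)
    return ClassifierEval(
        n_pcs=n_pcs, n_genes=n_genes,
        pooled_scores=scores, pooled_labels=lab,
        roc_points=roc_curve(scores, lab),
        auc=auc(scores, lab),
        n_repeats=n_repeats, seed=seed,
    )


def _labeled_features(dataset: DeltaExpression, labels: pd.Series
                      ) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    labels = labels.reindex(dataset.sample_ids)
    keep = labels.isin(["high", "low"]).to_numpy()
    X = dataset.values.to_numpy(dtype=float).T[keep]
    return X, labels.to_numpy()[keep], dataset.sample_ids[keep]


def pc_sweep_eval(corrected_datasets, discovery_labels: pd.Series,
                  validation_labels: pd.Series, n_top_genes: int = 100,
                  B: int = 0, n_repeats: int = 5000,
                  seed: int | None = None, s0_method: str = "cv_min",
                  train_on_discovery: bool = False,
                  **clf_params) -> list[ClassifierEval]:
    """Cross-ancestry panel evaluation for each PC-corrected dataset.

    For every dataset: discover the signature on the discovery-ancestry
    tails, take the top ``n_top_genes``, restrict the validation-ancestry
    samples to those genes, and evaluate by repeated stratified splits
    (or, with ``train_on_discovery``, by training on the discovery tails
    and scoring all validation samples once).
    """
    evals = []
    for ds in corrected_datasets:
        sig = compute_signature(ds, discovery_labels, s0_method=s0_method,
                                B=B, seed=seed)
        panel = top_k_genes(sig, n_top_genes)
        sub = DeltaExpression(values=ds.values.loc[panel],
                              quantile_normalized=ds.quantile_normalized,
                              batch_adjusted=ds.batch_adjusted,
                              n_pcs_removed=ds.n_pcs_removed)
        Xv, yv, _ = _labeled_features(sub, validation_labels)
        if train_on_discovery:
            Xd, yd, _ = _labeled_features(sub, discovery_labels)
            clf = RBFResponderClassifier(**clf_params).fit(Xd, yd)
            scores = clf.decision_function(Xv)
            evals.append(ClassifierEval(
                n_pcs=ds.n_pcs_removed, n_genes=n_top_genes,
                pooled_scores=scores, pooled_labels=yv,
                roc_points=roc_curve(scores, yv), auc=auc(scores, yv),
                n_repeats=1, seed=seed))
        else:
            evals.append(evaluate_panel(
                Xv, yv, n_pcs=ds.n_pcs_removed, n_genes=n_top_genes,
                n_repeats=n_repeats, seed=seed, **clf_params))
    return evals


def gene_count_sweep(dataset: DeltaExpression, discovery_labels: pd.Series,
                     validation_labels: pd.Series, n_grid,
                     B: int = 0, n_repeats: int = 5000,
                     seed: int | None = None, s0_method: str = "cv_min",
                     **clf_params) -> tuple[list[ClassifierEval], int]:
    """Evaluate nested panels of varying size; return evals and the arg-max n.

    The signature is computed once; panels are nested by rank.  Ties in
    AUC go to the smallest panel.
    """
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("empty panel-size grid")
    sig = compute_signature(dataset, discovery_labels, s0_method=s0_method,
                            seed=seed)
    evals = []
    for n in n_grid:
        panel = top_k_genes(sig, n)
        sub = DeltaExpression(values=dataset.values.loc[panel],
                              quantile_normalized=dataset.quantile_normalized,
                              batch_adjusted=dataset.batch_adjusted,
                              n_pcs_removed=dataset.n_pcs_removed)
        Xv, yv, _ = _labeled_features(sub, validation_labels)
        evals.append(evaluate_panel(
            Xv, yv, n_pcs=dataset.n_pcs_removed, n_genes=n,
            n_repeats=n_repeats, seed=seed, **clf_params))
    aucs = np.array([e.auc for e in evals])
    order = np.lexsort((n_grid, -aucs))
    best_n = int(np.array(n_grid)[order[0]])
    return evals, best_n
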