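"""Linear multiclass classification with confidence scores.

One-vs-rest linear support vector machines (scikit-learn ``LinearSVC``,
primal solver for determinism) realize the multiclass contract: scoring an
example returns one finite decision value per class. The regularization
parameter C is selected on a development set, the final model is retrained
on the combined training and development data, and a recall-adjustment
multiplier applied to the negative-class score trades precision for recall
against a downstream metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.svm import LinearSVC

from eventex.features import FeatureIndex, SparseExample

NEGATIVE = "neg"

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-8, 7))
DEFAULT_BETA_GRID: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(8))


@dataclass
class ModelBundle:
    classes: list[str]                    # NEGATIVE first when present
    clf: Optional[LinearSVC]
    feature_index: FeatureIndex
    C: float
    single_class: Optional[str] = None    # degenerate one-class training

    def decision_scores(self, X: csr_matrix) -> np.ndarray:
        """(n_examples, n_classes) decision values aligned with .classes."""
        n = X.shape[0]
        if self.single_class is not None:
            scores = np.full((n, len(self.classes)), -1.0)
            scores[:, self.classes.index(self.single_class)] = 1.0
            return scores
        raw = self.clf.decision_function(X)
        if raw.ndim == 1:   # binary: score of clf.classes_[1]
            raw = np.column_stack([-raw, raw])
        order = [list(self.clf.classes_).index(c) for c in self.classes]
        return raw[:, order]

    def predict(self, X: csr_matrix, beta: float = 1.0) -> list[str]:
        return adjust_scores(self.decision_scores(X), self.classes, beta)


def _sorted_matrix(examples: Sequence[SparseExample], index: FeatureIndex
                   ) -> tuple[csr_matrix, list[str]]:
    ordered = sorted(examples, key=lambda e: e.example_id)
    X = index.transform(ordered)
    y = [e.label for e in ordered]
    return X, y


def train(examples: Sequence[SparseExample], C: float,
          feature_index: FeatureIndex) -> ModelBundle:
    """Fit a one-vs-rest linear SVM; deterministic given the (sorted)
    example order. Single-class data yields a degenerate constant model."""
    if not examples:
        raise ValueError("cannot train on an empty example set")
    X, y = _sorted_matrix(examples, feature_index)
    labels = sorted(set(y))
    if len(labels) == 1:
        warnings.warn(f"single-class training data ({labels[0]}); "
                      "model will always predict that class")
        return ModelBundle(classes=labels, clf=None,
                           feature_index=feature_index, C=C,
                           single_class=labels[0])
    clf = LinearSVC(C=C, dual=False, max_iter=5000, tol=1e-4)
    clf.fit(X, y)
    classes = sorted(clf.classes_, key=lambda c: (c != NEGATIVE, c))
    return ModelBundle(classes=list(classes), clf=clf,
                       feature_index=feature_index, C=C)


def classification_f1(gold: Sequence[str], predicted: Sequence[str]) -> float:
    """Micro-averaged F over the positive (non-negative) classes, the
    stage-level selection criterion for C."""
    tp = fp = fn = 0
    for g, p in zip(gold, predicted):
        if p != NEGATIVE:
            if g == p:
                tp += 1
            else:
                fp += 1
                if g != NEGATIVE:
                    fn += 1
        elif g != NEGATIVE:
            fn += 1
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def optimize_C(train_examples: Sequence[SparseExample],
               devel_examples: Sequence[SparseExample],
               grid: Sequence[float] = DEFAULT_C_GRID,
               feature_index: FeatureIndex | None = None,
               scorer: Callable[[Sequence[str], Sequence[str]], float]
               = classification_f1) -> tuple[float, float]:
    """Pick the C maximizing devel F for this classification task in
    isolation; ties resolve to the smaller C. Returns (best_C, best_F)."""
    if not list(grid):
        raise ValueError("empty C grid")
    if feature_index is None:
        feature_index = FeatureIndex()
        for ex in train_examples:
            for name in ex.features:
                feature_index.get(name)
    best_c, best_f = None, -1.0
    Xd, yd = _sorted_matrix(devel_examples, feature_index)
    for c in sorted(grid):
        bundle = train(train_examples, c, feature_index)
        pred = bundle.predict(Xd)
        f = scorer(yd, pred)
        if f > best_f:
            best_c, best_f = c, f
    return best_c, best_f


def retrain_combined(train_examples: Sequence[SparseExample],
                     devel_examples: Sequence[SparseExample],
                     best_C: float,
                     feature_index: FeatureIndex) -> ModelBundle:
    """Refit on the union of training and development data at the chosen C,
    for use on held-out test data."""
    return train(list(train_examples) + list(devel_examples), best_C,
                 feature_index)


def adjust_with_recall(scores: dict[str, float], beta: float) -> str:
    """Recall adjustment of a single decision.

    The negative-class confidence is multiplied by ``beta``; if the product
    falls below the score of another class, that class becomes the new
    classification. Decisions that were already positive never change."""
    if NEGATIVE not in scores:
        raise ValueError("scores must contain the negative class")
    argmax = max(scores, key=lambda c: (scores[c], c == NEGATIVE, c))
    if argmax != NEGATIVE:
        return argmax
    adjusted = dict(scores)
    adjusted[NEGATIVE] = beta * scores[NEGATIVE]
    return max(adjusted, key=lambda c: (adjusted[c], c == NEGATIVE, c))


def adjust_scores(score_matrix: np.ndarray, classes: Sequence[str],
                  beta: float) -> list[str]:
    """Vectorized recall adjustment over a score matrix."""
    classes = list(classes)
    out: list[str] = []
    if NEGATIVE not in classes:
        idx = np.argmax(score_matrix, axis=1)
        return [classes[i] for i in idx]
    neg_col = classes.index(NEGATIVE)
    for row in score_matrix:
        out.append(adjust_with_recall(dict(zip(classes, row)), beta))
    return out


def optimize_recall_multiplier(pipeline_fn: Callable[[float], float],
                               grid: Sequence[float] = DEFAULT_BETA_GRID
                               ) -> tuple[float, float]:
    """Pick the negative-class multiplier maximizing the configured
    downstream metric (event-level F, or edge F when no events exist);
    ties resolve to the beta closest to 1, then the smaller one.
    Returns (best_beta, best_metric)."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty beta grid")
    results = [(pipeline_fn(b), b) for b in grid]
    best_f = max(f for f, _ in results)
    candidates = [b for f, b in results if f == best_f]
    best_beta = min(candidates, key=lambda b: (abs(b - 1.0), b))
    return best_beta, best_f
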