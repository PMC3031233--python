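"""Stratified k-fold cross-validation and ROC AUC.

AUC is computed once on the predictions pooled over all test folds, via the
rank-sum (Mann-Whitney) formulation with midrank tie correction: it equals
the probability that a random positive outranks a random negative, ties
counting one half.  The positive class is "ageing".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from agerepair.data import CLASS_POSITIVE, Dataset

logger = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    """Pooled out-of-fold predictions: each instance tested exactly once."""

    instance_ids: list
    y_true: np.ndarray  # class labels
    y_score: np.ndarray  # positive-class probability
    fold: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.instance_ids)
        self.y_true = np.asarray(self.y_true, dtype=object)
        self.y_score = np.asarray(self.y_score, dtype=float)
        self.fold = np.asarray(self.fold, dtype=int)
        if not (len(self.y_true) == len(self.y_score) == len(self.fold) == n):
            raise ValueError("prediction arrays must align")
        if ((self.y_score < 0) | (self.y_score > 1)).any():
            raise ValueError("scores must be probabilities in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instance_id": self.instance_ids,
                "true_class": self.y_true,
                "positive_probability": self.y_score,
                "fold": self.fold,
            }
        )


def stratified_folds(data: Dataset, k: int, seed: int) -> np.ndarray:
    """Deterministic per-instance fold assignment, stratified by class.

    Within each class, instances are shuffled with the seeded generator and
    dealt round-robin, carrying the deal position across classes so overall
    fold sizes differ by at most one and per-class counts by at most one.
    """
    n = data.n_instances
    if k < 2:
        raise ValueError("fold count k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available instances")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for label in sorted(set(data.classes)):
        idx = np.flatnonzero((data.classes == label).to_numpy())
        if idx.size < k:
            logger.warning(
                "class %r has %d instances for %d folds; stratification is "
                "best-effort",
                label,
                idx.size,
                k,
            )
        rng.shuffle(idx)
        for i, instance in enumerate(idx):
            assignment[instance] = (offset + i) % k
        offset = (offset + idx.size) % k
    return assignment


def cross_validate(data: Dataset, learner, k: int = 10, seed: int = 0) -> PredictionSet:
    """Train on k-1 folds, score the held-out fold, pool over folds.

    ``learner`` exposes ``fit(dataset) -> model`` and
    ``score(model, dataset) -> array of positive-class probabilities``.
    """
    folds = stratified_folds(data, k, seed)
    scores = np.empty(data.n_instances, dtype=float)
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        model = learner.fit(data.subset(train_idx))
        scores[test_idx] = learner.score(model, data.subset(test_idx))
    return PredictionSet(
        instance_ids=list(data.instance_ids),
        y_true=data.classes.to_numpy(dtype=object),
        y_score=scores,
        fold=folds,
    )


def auc(predictions: PredictionSet) -> float:
    """Pooled AUC by the rank-sum formulation with midrank tie correction."""
    pos = predictions.y_true == CLASS_POSITIVE
    return auc_scores(pos, predictions.y_score)


def auc_scores(positive_mask: np.ndarray, scores: np.ndarray) -> float:
    """AUC of ``scores`` against a boolean positive-class mask."""
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n_pos = int(positive_mask.sum())
    n_neg = int((~positive_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class present")
    ranks = rankdata(np.asarray(scores, dtype=float), method="average")
    rank_sum = ranks[positive_mask].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


class MajorityLearner:
    """Baseline scorer: every instance gets the training positive frequency."""

    name = "majority"

    def fit(self, data: Dataset) -> float:
        return data.class_frequency(CLASS_POSITIVE)

    def score(self, model: float, data: Dataset) -> np.ndarray:
        return np.full(data.n_instances, model)


def evaluation_report(rows, path=None) -> pd.DataFrame:
    """Tabular CV report (variant, t, learner, seed, AUC, root attribute)."""
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
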