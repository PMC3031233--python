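"""Interpretable classifiers: C4.5-style decision tree and Naive Bayes.

Both tolerate missing values and mixed binary/nominal/numeric attributes,
train deterministically, and serialize to JSON.  The thin learner adapters
(:class:`TreeLearner`, :class:`NaiveBayesLearner`) give both models the
fit/score surface the cross-validation driver expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from agerepair.data import CLASS_POSITIVE, Dataset
from agerepair.classifiers.naive_bayes import (
    NaiveBayesModel,
    predict_naive_bayes,
    train_naive_bayes,
)
from agerepair.classifiers.tree import (
    DecisionTree,
    TreeNode,
    predict_tree,
    root_attribute,
    train_tree,
)

__all__ = [
    "DecisionTree",
    "NaiveBayesLearner",
    "NaiveBayesModel",
    "TreeLearner",
    "TreeNode",
    "predict_naive_bayes",
    "predict_tree",
    "root_attribute",
    "train_naive_bayes",
    "train_tree",
]


@dataclass
class NaiveBayesLearner:
    """Adapter: train Naive Bayes and score positive-class posteriors."""

    smoothing: float = 1.0
    name: str = "naive_bayes"

    def fit(self, data: Dataset) -> NaiveBayesModel:
        return train_naive_bayes(data, smoothing=self.smoothing)

    def score(self, model: NaiveBayesModel, data: Dataset) -> np.ndarray:
        return np.array(
            [
                predict_naive_bayes(model, data.row(i))[CLASS_POSITIVE]
                for i in range(data.n_instances)
            ]
        )


@dataclass
class TreeLearner:
    """Adapter: train the decision tree and score Laplace leaf probabilities."""

    min_leaf: int = 2
    prune_confidence: float = 0.25
    use_pruning: bool = True
    name: str = "tree"

    def fit(self, data: Dataset) -> DecisionTree:
        return train_tree(
            data,
            min_leaf=self.min_leaf,
            prune_confidence=self.prune_confidence,
            use_pruning=self.use_pruning,
        )

    def score(self, model: DecisionTree, data: Dataset) -> np.ndarray:
        return np.array(
            [predict_tree(model, data.row(i))[1] for i in range(data.n_instances)]
        )


LEARNERS = {"naive_bayes": NaiveBayesLearner, "tree": TreeLearner}
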