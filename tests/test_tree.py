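"""Decision tree induction: splits, routing, pruning, serialization."""

import math

import numpy as np
import pytest

from agerepair.data import CLASS_NEGATIVE, CLASS_POSITIVE
from agerepair.classifiers.tree import (
    GT,
    LE,
    DecisionTree,
    TreeNode,
    _Trainer,
    estimated_error,
    predict_tree,
    root_attribute,
    train_tree,
)
from conftest import random_mixed_dataset, toy_dataset


class TestStoppingAndBasicSplits:
    def test_pure_input_is_single_leaf(self):
        data = toy_dataset(
            [{"a": "yes"}, {"a": "no"}], {"a": "binary"},
            [CLASS_POSITIVE, CLASS_POSITIVE],
        )
        tree = train_tree(data)
        assert tree.root.is_leaf
        assert tree.root.prediction == CLASS_POSITIVE
        assert root_attribute(tree) is None

    def test_perfect_binary_splitter_is_depth_one(self):
        rows = [{"a": "yes", "b": "no"}] * 4 + [{"a": "no", "b": "no"}] * 4
        classes = [CLASS_POSITIVE] * 4 + [CLASS_NEGATIVE] * 4
        data = toy_dataset(rows, {"a": "binary", "b": "binary"}, classes)
        tree = train_tree(data, use_pruning=False)
        assert root_attribute(tree) == "a"
        assert all(c.is_leaf for c in tree.root.children.values())

    def test_numeric_threshold_at_midpoint_of_adjacent_values(self):
        rows = [{"x": v} for v in (1.0, 2.0, 8.0, 9.0)]
        classes = [CLASS_POSITIVE, CLASS_POSITIVE, CLASS_NEGATIVE, CLASS_NEGATIVE]
        data = toy_dataset(rows, {"x": "numeric"}, classes)
        tree = train_tree(data, min_leaf=1, use_pruning=False)
        assert tree.root.attribute == "x"
        assert tree.root.threshold == pytest.approx(5.0)  # midpoint of 2 and 8

    def test_two_attribute_noiseless_function_zero_resubstitution_error(self):
        # label = (b = yes AND x > 5), three replicated copies per cell
        rows, classes = [], []
        for b in ("yes", "no"):
            for x in (2.0, 8.0):
                for _ in range(3):
                    rows.append({"b": b, "x": x})
                    classes.append(
                        CLASS_POSITIVE if (b == "yes" and x > 5) else CLASS_NEGATIVE
                    )
        data = toy_dataset(rows, {"b": "binary", "x": "numeric"}, classes)
        tree = train_tree(data, use_pruning=False)
        for i in range(data.n_instances):
            pred, _ = predict_tree(tree, data.row(i))
            assert pred == classes[i]


class TestPrediction:
    def leaf(self, pos, neg):
        return TreeNode(
            counts={CLASS_POSITIVE: pos, CLASS_NEGATIVE: neg},
            prediction=CLASS_POSITIVE if pos >= neg else CLASS_NEGATIVE,
        )

    def stub_tree(self, root):
        return DecisionTree(root=root, classes=(CLASS_POSITIVE, CLASS_NEGATIVE),
                            attributes=[], params={})

    def test_single_leaf_tree_predicts_its_class(self):
        tree = self.stub_tree(self.leaf(3, 1))
        assert predict_tree(tree, {})[0] == CLASS_POSITIVE

    def test_partner_count_sixteen_takes_greater_branch(self):
        root = self.leaf(5, 5)
        root.attribute = "#partners"
        root.kind = "numeric"
        root.threshold = 15.0
        root.children = {LE: self.leaf(1, 5), GT: self.leaf(4, 0)}
        tree = self.stub_tree(root)
        pred, prob = predict_tree(tree, {"#partners": 16.0})
        assert pred == CLASS_POSITIVE
        assert prob > 0.5

    def test_laplace_corrected_leaf_probability(self):
        tree = self.stub_tree(self.leaf(5, 0))
        _, prob = predict_tree(tree, {})
        assert prob == pytest.approx(6 / 7)

    def test_missing_value_routes_to_heavier_child(self):
        root = self.leaf(5, 6)
        root.attribute = "x"
        root.kind = "numeric"
        root.threshold = 0.0
        root.children = {LE: self.leaf(1, 1), GT: self.leaf(4, 5)}
        tree = self.stub_tree(root)
        pred, prob = predict_tree(tree, {"x": None})
        assert prob == pytest.approx((4 + 1) / (9 + 2))


def oracle_choose_split(data, min_leaf=2):
    """Independent exhaustive enumeration of all attributes and cut points.

    Returns (attribute, threshold-or-None) for the split the gain-ratio rule
    should select, or None.  Plain-python loops; no shared code with the
    trainer's vectorized scan.
    """
    def entropy(labels):
        h = 0.0
        for c in set(labels):
            p = labels.count(c) / len(labels)
            h -= p * math.log2(p)
        return h

    candidates = []
    for col_order, a in enumerate(data.attributes):
        pairs = []
        for i in range(data.n_instances):
            v = data.values[a.name].iloc[i]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            pairs.append((v, data.classes.iloc[i]))
        if len(pairs) < 2 * min_leaf:
            continue
        labels = [c for _, c in pairs]
        parent_h = entropy(labels)
        if a.kind == "numeric":
            values = sorted(set(v for v, _ in pairs))
            best = None
            for lo, hi in zip(values, values[1:]):
                thr = (lo + hi) / 2
                left = [c for v, c in pairs if v <= thr]
                right = [c for v, c in pairs if v > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                gain = parent_h - (
                    len(left) / len(pairs) * entropy(left)
                    + len(right) / len(pairs) * entropy(right)
                )
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, thr, [len(left), len(right)])
            if best is None or best[0] <= 1e-10:
                continue
            gain, thr, sizes = best
            split_info = entropy(
                [0] * sizes[0] + [1] * sizes[1]
            )  # entropy of branch-size distribution
            candidates.append((col_order, a.name, thr, gain, split_info))
        else:
            groups = {}
            for v, c in pairs:
                groups.setdefault(v, []).append(c)
            if len(groups) < 2:
                continue
            if sum(1 for g in groups.values() if len(g) >= min_leaf) < 2:
                continue
            gain = parent_h - sum(
                len(g) / len(pairs) * entropy(g) for g in groups.values()
            )
            if gain <= 1e-10:
                continue
            sizes = []
            for g in groups.values():
                sizes.extend([len(sizes)] * len(g))
            split_info = entropy(sizes)
            candidates.append((col_order, a.name, None, gain, split_info))
    if not candidates:
        return None
    mean_gain = sum(c[3] for c in candidates) / len(candidates)
    eligible = [c for c in candidates if c[3] >= mean_gain - 1e-10]
    best = max(eligible, key=lambda c: (c[4] > 1e-10 and c[3] / c[4], -c[0]))
    return best[1], best[2]


def test_gain_ratio_choice_matches_enumeration_oracle():
    """Trainer's split agrees with brute-force enumeration on small data."""
    rng = np.random.default_rng(11)
    checked = 0
    for trial in range(25):
        n = int(rng.integers(10, 50))
        data = random_mixed_dataset(rng, n=n, n_binary=3, n_numeric=2,
                                    missing_rate=0.05)
        trainer = _Trainer(data, min_leaf=2)
        split = trainer.choose_split(
            np.arange(n), list(range(len(data.attributes)))
        )
        want = oracle_choose_split(data, min_leaf=2)
        if want is None:
            assert split is None
            continue
        assert split is not None
        assert (split.attribute, split.threshold) == (
            want[0],
            pytest.approx(want[1]) if want[1] is not None else None,
        )
        checked += 1
    assert checked >= 10


class TestPruning:
    def test_pruning_never_increases_estimated_error(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            data = random_mixed_dataset(rng, n=40, n_binary=4, n_numeric=2)
            full = train_tree(data, use_pruning=False)
            pruned = train_tree(data, use_pruning=True)
            assert estimated_error(pruned) <= estimated_error(full) + 1e-9

    def test_pruning_collapses_chance_structure(self):
        # labels independent of the attributes: the tree should shrink
        rng = np.random.default_rng(9)
        data = random_mixed_dataset(rng, n=60, n_binary=5, n_numeric=0)

        def n_leaves(node):
            if node.is_leaf:
                return 1
            return sum(n_leaves(c) for c in node.children.values())

        full = train_tree(data, use_pruning=False)
        pruned = train_tree(data, use_pruning=True)
        assert n_leaves(pruned.root) <= n_leaves(full.root)


class TestPathConsistency:
    def test_numeric_conditions_never_contradict_on_a_path(self, d5_dataset):
        tree = train_tree(d5_dataset, use_pruning=False)

        def walk(node, bounds):
            if node.is_leaf:
                return
            for key, child in node.children.items():
                if node.kind == "numeric":
                    lo, hi = bounds.get(node.attribute, (-math.inf, math.inf))
                    new = dict(bounds)
                    if key == LE:
                        new[node.attribute] = (lo, min(hi, node.threshold))
                    else:
                        new[node.attribute] = (max(lo, node.threshold), hi)
                    lo2, hi2 = new[node.attribute]
                    assert lo2 < hi2  # the interval stays non-empty
                    walk(child, new)
                else:
                    walk(child, bounds)

        walk(tree.root, {})

    def test_leaf_counts_sum_to_training_size(self, d5_dataset):
        tree = train_tree(d5_dataset, use_pruning=False)

        def total(node):
            if node.is_leaf:
                return node.n
            return sum(total(c) for c in node.children.values())

        assert total(tree.root) == d5_dataset.n_instances

    def test_internal_nodes_have_at_least_two_children(self, d5_dataset):
        tree = train_tree(d5_dataset)

        def walk(node):
            if not node.is_leaf:
                assert len(node.children) >= 2
                for c in node.children.values():
                    walk(c)

        walk(tree.root)


def test_json_round_trip_predicts_identically(d5_dataset):
    tree = train_tree(d5_dataset)
    clone = DecisionTree.from_json(tree.to_json())
    for i in range(0, d5_dataset.n_instances, 7):
        row = d5_dataset.row(i)
        assert predict_tree(tree, row) == predict_tree(clone, row)


def test_render_mentions_root_attribute(d5_dataset):
    tree = train_tree(d5_dataset)
    text = tree.render()
    assert root_attribute(tree) in text
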