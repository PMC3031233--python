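"""C4.5-style decision tree: gain-ratio splits, pessimistic pruning.

The induction is recursive top-down.  At each node every attribute proposes
its best split (multiway over observed values for nominal/binary columns, a
binary cut at the gain-maximizing midpoint between consecutive distinct
observed values for numeric columns).  Among proposals whose information
gain reaches the mean gain of the positive-gain proposals, the one with the
largest gain ratio wins; ties fall to attribute column order, then to the
smaller threshold.  Instances missing the tested value are routed whole to
the heaviest branch (no fractional weighting).  Optional pruning replaces a
subtree by a leaf whenever the leaf's pessimistic error estimate does not
exceed the subtree's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.stats import norm

from agerepair.data import AttributeDescriptor, Dataset, is_missing

_EPS = 1e-10

# branch keys for numeric splits
LE, GT = "le", "gt"


@dataclass
class TreeNode:
    counts: Dict[str, int]
    prediction: str
    attribute: Optional[str] = None
    kind: Optional[str] = None  # "nominal" | "numeric" (None for leaves)
    threshold: Optional[float] = None
    children: Dict[str, "TreeNode"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def heaviest_child(self) -> "TreeNode":
        return max(self.children.values(), key=lambda c: c.n)

    def to_dict(self) -> dict:
        d = {"counts": self.counts, "prediction": self.prediction}
        if not self.is_leaf:
            d.update(
                attribute=self.attribute,
                kind=self.kind,
                threshold=self.threshold,
                children={k: c.to_dict() for k, c in self.children.items()},
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            counts={k: int(v) for k, v in d["counts"].items()},
            prediction=d["prediction"],
        )
        if "children" in d:
            node.attribute = d["attribute"]
            node.kind = d["kind"]
            node.threshold = d["threshold"]
            node.children = {
                k: cls.from_dict(c) for k, c in d["children"].items()
            }
        return node


@dataclass
class DecisionTree:
    root: TreeNode
    classes: tuple
    attributes: list
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "decision_tree",
                "classes": list(self.classes),
                "params": self.params,
                "attributes": [
                    {"name": a.name, "kind": a.kind, "domain": a.domain}
                    for a in self.attributes
                ],
                "root": self.root.to_dict(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        doc = json.loads(text)
        if doc.get("model") != "decision_tree":
            raise ValueError("not a serialized decision tree")
        attrs = [
            AttributeDescriptor(
                a["name"], a["kind"], tuple(a["domain"]) if a["domain"] else None
            )
            for a in doc["attributes"]
        ]
        return cls(
            root=TreeNode.from_dict(doc["root"]),
            classes=tuple(doc["classes"]),
            attributes=attrs,
            params=doc.get("params", {}),
        )

    def render(self) -> str:
        """Indented IF-THEN style text rendering."""
        lines: List[str] = []

        def walk(node: TreeNode, depth: int) -> None:
            pad = "|   " * depth
            if node.is_leaf:
                lines.append(f"{pad}=> class = {node.prediction} {node.counts}")
                return
            for key, child in node.children.items():
                if node.kind == "numeric":
                    op = "<=" if key == LE else ">"
                    cond = f"{node.attribute} {op} {node.threshold:g}"
                else:
                    cond = f"{node.attribute} = {key}"
                lines.append(f"{pad}{cond}")
                walk(child, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# training


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass
class _Split:
    attribute: str
    col_index: int
    kind: str
    gain: float
    split_info: float
    threshold: Optional[float] = None
    branch_values: Optional[list] = None  # observed nominal values, domain order

    @property
    def gain_ratio(self) -> float:
        return self.gain / self.split_info if self.split_info > _EPS else 0.0


class _Trainer:
    def __init__(self, data: Dataset, min_leaf: int):
        self.min_leaf = min_leaf
        self.classes = tuple(sorted(set(data.classes)))
        self.class_index = {c: i for i, c in enumerate(self.classes)}
        self.y = data.classes.map(self.class_index).to_numpy(dtype=np.int64)
        self.attributes = list(data.attributes)
        self.columns: List[np.ndarray] = []
        self.missing: List[np.ndarray] = []
        self.domains: List[Optional[list]] = []
        for a in self.attributes:
            col = data.values[a.name]
            if a.kind == "numeric":
                arr = col.to_numpy(dtype=float)
                self.columns.append(arr)
                self.missing.append(~np.isfinite(arr))
                self.domains.append(None)
            else:
                domain = list(a.domain)
                code = {v: i for i, v in enumerate(domain)}
                arr = np.array(
                    [-1 if is_missing(v) else code[v] for v in col],
                    dtype=np.int64,
                )
                self.columns.append(arr)
                self.missing.append(arr < 0)
                self.domains.append(domain)

    # -- split search --------------------------------------------------------

    def candidate(self, j: int, idx: np.ndarray) -> Optional[_Split]:
        a = self.attributes[j]
        nm = idx[~self.missing[j][idx]]
        if nm.size < 2 * self.min_leaf:
            return None
        parent_counts = np.bincount(self.y[nm], minlength=len(self.classes))
        parent_h = _entropy(parent_counts)
        if a.kind == "numeric":
            return self._numeric_candidate(j, nm, parent_h)
        return self._nominal_candidate(j, nm, parent_h)

    def _nominal_candidate(
        self, j: int, nm: np.ndarray, parent_h: float
    ) -> Optional[_Split]:
        codes = self.columns[j][nm]
        domain = self.domains[j]
        table = np.zeros((len(domain), len(self.classes)))
        np.add.at(table, (codes, self.y[nm]), 1)
        sizes = table.sum(axis=1)
        present = sizes > 0
        if present.sum() < 2 or (sizes >= self.min_leaf).sum() < 2:
            return None
        n = nm.size
        child_h = sum(
            sizes[v] / n * _entropy(table[v]) for v in np.where(present)[0]
        )
        gain = parent_h - child_h
        if gain <= _EPS:
            return None
        split_info = _entropy(sizes[present])
        return _Split(
            attribute=self.attributes[j].name,
            col_index=j,
            kind="nominal",
            gain=gain,
            split_info=split_info,
            branch_values=[domain[v] for v in np.where(present)[0]],
        )

    def _numeric_candidate(
        self, j: int, nm: np.ndarray, parent_h: float
    ) -> Optional[_Split]:
        vals = self.columns[j][nm]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sy = self.y[nm][order]
        n = nm.size
        # cumulative class counts below each cut position
        onehot = np.zeros((n, len(self.classes)))
        onehot[np.arange(n), sy] = 1.0
        cum = onehot.cumsum(axis=0)
        total = cum[-1]
        # cut after position i (0-based) is valid when the value changes
        change = np.nonzero(np.diff(sv) > 0)[0]
        valid = change[
            (change + 1 >= self.min_leaf) & (n - change - 1 >= self.min_leaf)
        ]
        if valid.size == 0:
            return None
        left = cum[valid]
        right = total - left
        nl = left.sum(axis=1)
        nr = right.sum(axis=1)

        def h(mat: np.ndarray, sizes: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = mat / sizes[:, None]
                logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
            return -(p * logp).sum(axis=1)

        child_h = (nl / n) * h(left, nl) + (nr / n) * h(right, nr)
        gains = parent_h - child_h
        best = int(np.argmax(gains))  # argmax keeps the first (smaller cut)
        if gains[best] <= _EPS:
            return None
        cut = valid[best]
        thr = float((sv[cut] + sv[cut + 1]) / 2.0)
        sizes = np.array([nl[best], nr[best]])
        return _Split(
            attribute=self.attributes[j].name,
            col_index=j,
            kind="numeric",
            gain=float(gains[best]),
            split_info=_entropy(sizes),
            threshold=thr,
        )

    def choose_split(
        self, idx: np.ndarray, available: List[int]
    ) -> Optional[_Split]:
        candidates = [
            s for j in available if (s := self.candidate(j, idx)) is not None
        ]
        if not candidates:
            return None
        mean_gain = sum(s.gain for s in candidates) / len(candidates)
        eligible = [s for s in candidates if s.gain >= mean_gain - _EPS]
        # max gain ratio; ties -> attribute column order (candidates are
        # already in column order, and max keeps the first maximum)
        return max(eligible, key=lambda s: s.gain_ratio)

    # -- recursion -----------------------------------------------------------

    def leaf(self, idx: np.ndarray, fallback: str) -> TreeNode:
        counts = np.bincount(self.y[idx], minlength=len(self.classes))
        if counts.sum() == 0:
            return TreeNode(
                counts={c: 0 for c in self.classes}, prediction=fallback
            )
        pred = self.classes[int(np.argmax(counts))]
        return TreeNode(
            counts={c: int(k) for c, k in zip(self.classes, counts)},
            prediction=pred,
        )

    def build(
        self, idx: np.ndarray, available: List[int], fallback: str
    ) -> TreeNode:
        counts = np.bincount(self.y[idx], minlength=len(self.classes))
        pure = (counts > 0).sum() <= 1
        if pure or idx.size < 2 * self.min_leaf or not available:
            return self.leaf(idx, fallback)
        split = self.choose_split(idx, available)
        if split is None:
            return self.leaf(idx, fallback)

        j = split.col_index
        miss_mask = self.missing[j][idx]
        nm = idx[~miss_mask]
        missing_idx = idx[miss_mask]
        if split.kind == "numeric":
            le_mask = self.columns[j][nm] <= split.threshold
            groups = {LE: nm[le_mask], GT: nm[~le_mask]}
            child_available = available
        else:
            code = {v: i for i, v in enumerate(self.domains[j])}
            groups = {
                v: nm[self.columns[j][nm] == code[v]]
                for v in split.branch_values
            }
            child_available = [k for k in available if k != j]
        if missing_idx.size:
            heavy = max(groups, key=lambda k: groups[k].size)
            groups[heavy] = np.concatenate([groups[heavy], missing_idx])

        node = self.leaf(idx, fallback)
        node.attribute = split.attribute
        node.kind = split.kind
        node.threshold = split.threshold
        for key, sub in groups.items():
            node.children[key] = self.build(sub, child_available, node.prediction)
        return node


def train_tree(
    data: Dataset,
    min_leaf: int = 2,
    prune_confidence: float = 0.25,
    use_pruning: bool = True,
) -> DecisionTree:
    """Induce a decision tree; single-class data yields a single leaf."""
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    if not 0.0 < prune_confidence < 1.0:
        raise ValueError("prune_confidence must be in (0, 1)")
    trainer = _Trainer(data, min_leaf)
    idx = np.arange(data.n_instances)
    fallback = trainer.classes[0]
    root = trainer.build(idx, list(range(len(trainer.attributes))), fallback)
    if use_pruning:
        _prune(root, prune_confidence)
    return DecisionTree(
        root=root,
        classes=trainer.classes,
        attributes=list(data.attributes),
        params={
            "min_leaf": min_leaf,
            "prune_confidence": prune_confidence,
            "use_pruning": use_pruning,
        },
    )


# ---------------------------------------------------------------------------
# pessimistic pruning


def _pessimistic_errors(n: int, errors: int, confidence: float) -> float:
    """Upper-confidence estimate of the number of errors at a leaf.

    For zero observed errors the exact binomial bound n*(1 - cf^(1/n)) is
    used; otherwise the Wilson-style upper bound on the error rate at the
    given one-sided confidence.
    """
    if n == 0:
        return 0.0
    if errors == 0:
        return n * (1.0 - confidence ** (1.0 / n))
    z = float(norm.isf(confidence))
    f = errors / n
    ucf = (
        f
        + z * z / (2.0 * n)
        + z * math.sqrt(f / n - f * f / n + z * z / (4.0 * n * n))
    ) / (1.0 + z * z / n)
    return n * min(1.0, ucf)


def _node_errors_as_leaf(node: TreeNode, confidence: float) -> float:
    n = node.n
    errors = n - max(node.counts.values()) if n else 0
    return _pessimistic_errors(n, errors, confidence)


def _prune(node: TreeNode, confidence: float) -> float:
    """Bottom-up subtree replacement; returns the node's estimated errors."""
    as_leaf = _node_errors_as_leaf(node, confidence)
    if node.is_leaf:
        return as_leaf
    subtree = sum(_prune(child, confidence) for child in node.children.values())
    if as_leaf <= subtree + _EPS:
        node.children = {}
        node.attribute = None
        node.kind = None
        node.threshold = None
        return as_leaf
    return subtree


def estimated_error(tree: DecisionTree) -> float:
    """Total pessimistic error estimate summed over the tree's leaves."""
    confidence = tree.params.get("prune_confidence", 0.25)

    def walk(node: TreeNode) -> float:
        if node.is_leaf:
            return _node_errors_as_leaf(node, confidence)
        return sum(walk(c) for c in node.children.values())

    return walk(tree.root)


# ---------------------------------------------------------------------------
# prediction


def predict_tree(
    tree: DecisionTree, instance: Mapping[str, object]
) -> Tuple[str, float]:
    """Route to a leaf; returns (class, Laplace positive-class probability).

    Missing or unseen values at a tested node take the branch with the
    larger training count.  The positive class is the lexicographically
    larger label for two-class problems built by this package ("ageing" vs
    "non_ageing" sorts as ("ageing", "non_ageing"), positive first).
    """
    from agerepair.data import CLASS_POSITIVE

    node = tree.root
    while not node.is_leaf:
        v = instance.get(node.attribute)
        if is_missing(v):
            node = node.heaviest_child()
            continue
        if node.kind == "numeric":
            key = LE if float(v) <= node.threshold else GT
            node = node.children[key]
        else:
            child = node.children.get(v)
            node = child if child is not None else node.heaviest_child()
    n = node.n
    pos = node.counts.get(CLASS_POSITIVE, 0)
    return node.prediction, (pos + 1.0) / (n + 2.0)


def root_attribute(tree: DecisionTree) -> Optional[str]:
    """Name of the root split attribute; None for a single-leaf tree."""
    return None if tree.root.is_leaf else tree.root.attribute
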