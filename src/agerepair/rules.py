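"""IF-THEN rule extraction from trees and exact binomial enrichment.

A root-to-leaf path is a conjunction of attribute conditions predicting the
leaf's class.  Its coverage on a dataset gives a contingency (n trials =
instances satisfying the conditions, k successes = those in the predicted
class) which is scored against Binomial(n, p0) with p0 the predicted
class's relative frequency in the whole dataset — a one-sided (upper tail)
over-representation test, with no multiple-testing correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import gammaln

from agerepair.data import CLASS_POSITIVE, Dataset, is_missing
from agerepair.classifiers.tree import GT, LE, DecisionTree, TreeNode

logger = logging.getLogger(__name__)


@dataclass
class Condition:
    attribute: str
    operator: str  # "=", "<=", ">"
    value: object

    def render(self) -> str:
        if self.operator == "=":
            return f"({self.attribute} = {self.value})"
        if isinstance(self.value, float):
            return f"({self.attribute} {self.operator} {self.value:g})"
        return f"({self.attribute} {self.operator} {self.value})"


@dataclass
class ClassificationRule:
    conditions: List[Condition]
    predicted_class: str
    n_trials: Optional[int] = None
    n_successes: Optional[int] = None
    p0: Optional[float] = None
    p_value: Optional[float] = None

    def render(self) -> str:
        if self.conditions:
            body = " AND ".join(c.render() for c in self.conditions)
        else:
            body = "(TRUE)"
        return f"IF {body} THEN class = {self.predicted_class}"

    def to_dict(self) -> dict:
        return {
            "rule": self.render(),
            "conditions": [
                {"attribute": c.attribute, "operator": c.operator, "value": c.value}
                for c in self.conditions
            ],
            "predicted_class": self.predicted_class,
            "n_trials": self.n_trials,
            "n_successes": self.n_successes,
            "p0": self.p0,
            "p_value": self.p_value,
        }


def extract_rules(tree: DecisionTree) -> List[ClassificationRule]:
    """One rule per root-to-leaf path, conditions in root-to-leaf order.

    Repeated numeric tests on one attribute collapse to the tightest
    interval (largest lower bound for ">", smallest upper bound for "<=").
    """
    rules: List[ClassificationRule] = []

    def walk(node: TreeNode, path: List[Condition]) -> None:
        if node.is_leaf:
            rules.append(
                ClassificationRule(
                    conditions=_collapse(path), predicted_class=node.prediction
                )
            )
            return
        for key, child in node.children.items():
            if node.kind == "numeric":
                op = "<=" if key == LE else ">"
                cond = Condition(node.attribute, op, float(node.threshold))
            else:
                cond = Condition(node.attribute, "=", key)
            walk(child, path + [cond])

    walk(tree.root, [])
    return rules


def _collapse(path: List[Condition]) -> List[Condition]:
    upper: Dict[str, Condition] = {}
    lower: Dict[str, Condition] = {}
    out: List[Condition] = []
    for cond in path:
        if cond.operator == "<=":
            prior = upper.get(cond.attribute)
            if prior is None:
                cond = Condition(cond.attribute, "<=", cond.value)
                upper[cond.attribute] = cond
                out.append(cond)
            elif cond.value < prior.value:
                prior.value = cond.value
        elif cond.operator == ">":
            prior = lower.get(cond.attribute)
            if prior is None:
                cond = Condition(cond.attribute, ">", cond.value)
                lower[cond.attribute] = cond
                out.append(cond)
            elif cond.value > prior.value:
                prior.value = cond.value
        else:
            out.append(cond)
    return out


def _satisfies(row, cond: Condition) -> bool:
    v = row.get(cond.attribute)
    if is_missing(v):
        return False
    if cond.operator == "=":
        return v == cond.value
    x = float(v)
    return x <= cond.value if cond.operator == "<=" else x > cond.value


def rule_coverage(rule: ClassificationRule, data: Dataset) -> Tuple[int, int]:
    """(n_trials, n_successes) of the rule on ``data``.

    Trials = instances satisfying every condition regardless of class;
    successes = trials in the predicted class.  Instances missing a tested
    value satisfy nothing (excluded from both counts).
    """
    names = set(data.attribute_names)
    for cond in rule.conditions:
        if cond.attribute not in names:
            raise KeyError(f"rule tests unknown attribute {cond.attribute!r}")
    n = k = 0
    for i in range(data.n_instances):
        row = data.row(i)
        if all(_satisfies(row, c) for c in rule.conditions):
            n += 1
            if data.classes.iloc[i] == rule.predicted_class:
                k += 1
    return n, k


def binomial_significance(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper tail P(X >= k) for X ~ Binomial(n, p0).

    Accumulated from log-factorial terms for numerical stability; the
    result is clamped to (0, 1].
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    log_p, log_q = math.log(p0), math.log1p(-p0)
    total = 0.0
    for i in range(k, n + 1):
        log_term = (
            gammaln(n + 1)
            - gammaln(i + 1)
            - gammaln(n - i + 1)
            + i * log_p
            + (n - i) * log_q
        )
        total += math.exp(log_term)
    return min(1.0, max(total, math.ulp(0.0)))


def score_rule(rule: ClassificationRule, data: Dataset) -> ClassificationRule:
    """Fill coverage and binomial p-value (p0 = predicted-class frequency)."""
    n, k = rule_coverage(rule, data)
    p0 = data.class_frequency(rule.predicted_class)
    p = binomial_significance(k, n, p0) if n > 0 else 1.0
    return replace(rule, n_trials=n, n_successes=k, p0=p0, p_value=p)


def attribute_value_pattern(
    data: Dataset, attribute: str, value: object, target_class: str = CLASS_POSITIVE
) -> ClassificationRule:
    """Single-condition pattern (attribute = value -> target class), scored."""
    rule = ClassificationRule(
        conditions=[Condition(attribute, "=", value)], predicted_class=target_class
    )
    return score_rule(rule, data)


def tally_root_attributes(trees) -> Dict[str, int]:
    """How often each attribute labels a tree root; leaves count as "none"."""
    from agerepair.classifiers.tree import root_attribute

    tally: Dict[str, int] = {}
    for tree in trees:
        name = root_attribute(tree) or "none"
        tally[name] = tally.get(name, 0) + 1
    return tally


def rules_report(tree: DecisionTree, data: Dataset) -> List[ClassificationRule]:
    """All scored rules of a tree, annotated against ``data``.

    The number of rules tested equals the number of leaves; callers wanting
    a multiplicity correction can apply it over that count.
    """
    return [score_rule(r, data) for r in extract_rules(tree)]
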