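"""Naive Bayes with nominal frequency tables and per-class Gaussians.

The classifier scores an instance with

    P(C_k) * P(A_1 | C_k) * ... * P(A_m | C_k)

where the prior is the class relative frequency in the training set and the
conditionals are empirical per-class frequencies (pseudo-count smoothed for
nominal attributes) or Gaussian densities (for numeric attributes).  The
product is evaluated in log space and missing attribute values are simply
skipped, which is exact under the model's attribute-independence assumption.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.special import logsumexp

from agerepair.data import (
    CLASS_LABELS,
    AttributeDescriptor,
    Dataset,
    is_missing,
)

logger = logging.getLogger(__name__)

#: Relative variance floor: per-class variances are clamped to this fraction
#: of the attribute's global variance (plus a tiny absolute floor) so a
#: constant within-class column cannot produce a degenerate density.
VARIANCE_FLOOR_FRACTION = 1e-6
ABSOLUTE_VARIANCE_FLOOR = 1e-12


@dataclass
class NaiveBayesModel:
    """Fitted priors, nominal conditional tables and Gaussian parameters.

    ``nominal_tables[attr][cls][value]`` is a smoothed conditional
    probability; ``numeric_params[attr][cls]`` is ``(mean, std)`` with the
    std already floored.
    """

    classes: tuple
    class_priors: Dict[str, float]
    attributes: list
    nominal_tables: Dict[str, Dict[str, Dict[str, float]]]
    numeric_params: Dict[str, Dict[str, Tuple[float, float]]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "naive_bayes",
                "classes": list(self.classes),
                "class_priors": self.class_priors,
                "attributes": [
                    {"name": a.name, "kind": a.kind, "domain": a.domain}
                    for a in self.attributes
                ],
                "nominal_tables": self.nominal_tables,
                "numeric_params": {
                    a: {c: list(p) for c, p in per.items()}
                    for a, per in self.numeric_params.items()
                },
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NaiveBayesModel":
        doc = json.loads(text)
        if doc.get("model") != "naive_bayes":
            raise ValueError("not a serialized Naive Bayes model")
        attrs = [
            AttributeDescriptor(
                a["name"], a["kind"], tuple(a["domain"]) if a["domain"] else None
            )
            for a in doc["attributes"]
        ]
        return cls(
            classes=tuple(doc["classes"]),
            class_priors=doc["class_priors"],
            attributes=attrs,
            nominal_tables=doc["nominal_tables"],
            numeric_params={
                a: {c: (p[0], p[1]) for c, p in per.items()}
                for a, per in doc["numeric_params"].items()
            },
        )


def train_naive_bayes(data: Dataset, smoothing: float = 1.0) -> NaiveBayesModel:
    """Fit priors and conditionals from a dataset.

    Priors are unsmoothed class relative frequencies.  A nominal conditional
    is ``(count + smoothing) / (class_nonmissing + smoothing * |domain|)``.
    Numeric conditionals are per-class Gaussians on non-missing values with
    a floored variance.
    """
    data.require_both_classes()
    n = data.n_instances
    classes = tuple(sorted(data.classes.unique()))
    priors = {c: float((data.classes == c).sum()) / n for c in classes}

    nominal: Dict[str, Dict[str, Dict[str, float]]] = {}
    numeric: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for a in data.attributes:
        col = data.values[a.name]
        if a.kind == "numeric":
            vals = col.to_numpy(dtype=float)
            global_var = float(np.nanvar(vals)) if np.isfinite(vals).any() else 0.0
            floor = max(
                VARIANCE_FLOOR_FRACTION * global_var, ABSOLUTE_VARIANCE_FLOOR
            )
            numeric[a.name] = {}
            for c in classes:
                cv = vals[(data.classes == c).to_numpy()]
                cv = cv[np.isfinite(cv)]
                mean = float(cv.mean()) if cv.size else 0.0
                var = float(cv.var()) if cv.size else 0.0
                numeric[a.name][c] = (mean, math.sqrt(max(var, floor)))
        else:
            domain = list(a.domain)
            nominal[a.name] = {}
            for c in classes:
                mask = (data.classes == c).to_numpy()
                observed = [v for v in col[mask] if not is_missing(v)]
                denom = len(observed) + smoothing * len(domain)
                counts = {v: 0 for v in domain}
                for v in observed:
                    if v not in counts:
                        raise ValueError(
                            f"value {v!r} outside domain of {a.name!r}"
                        )
                    counts[v] += 1
                nominal[a.name][c] = {
                    v: (counts[v] + smoothing) / denom for v in domain
                }
    return NaiveBayesModel(
        classes=classes,
        class_priors=priors,
        attributes=list(data.attributes),
        nominal_tables=nominal,
        numeric_params=numeric,
    )


def predict_naive_bayes(
    model: NaiveBayesModel, instance: Mapping[str, object]
) -> Dict[str, float]:
    """Normalized posterior per class; missing attributes are skipped.

    A nominal value unseen in the model's domain is treated as missing (and
    logged) rather than zeroing the product.
    """
    log_scores = []
    for c in model.classes:
        s = math.log(model.class_priors[c])
        for a in model.attributes:
            v = instance.get(a.name)
            if is_missing(v):
                continue
            if a.kind == "numeric":
                mean, std = model.numeric_params[a.name][c]
                x = float(v)
                s += -0.5 * math.log(2.0 * math.pi * std * std) - (
                    (x - mean) ** 2
                ) / (2.0 * std * std)
            else:
                table = model.nominal_tables[a.name][c]
                if v not in table:
                    logger.warning(
                        "unknown value %r for attribute %r; treated as missing",
                        v,
                        a.name,
                    )
                    continue
                s += math.log(table[v])
        log_scores.append(s)
    log_scores = np.array(log_scores)
    norm = logsumexp(log_scores)
    post = np.exp(log_scores - norm)
    return {c: float(p) for c, p in zip(model.classes, post)}
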