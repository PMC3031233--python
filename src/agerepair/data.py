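"""Core containers: gene records, interaction records and the typed Dataset.

A :class:`Dataset` is the unit handed to the learners: a gene-by-attribute
value matrix with typed columns (binary yes/no, nominal, numeric), a missing
marker, and a binary class vector (ageing-related vs not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_POSITIVE = "ageing"
CLASS_NEGATIVE = "non_ageing"
CLASS_LABELS = (CLASS_NEGATIVE, CLASS_POSITIVE)

#: The DNA repair pathway vocabulary (main repair process a gene acts in).
PATHWAY_CATEGORIES = (
    "base excision repair",
    "mismatch repair",
    "nucleotide excision repair",
    "homologous recombination",
    "non-homologous end joining",
    "other types of DNA repair",
    "DNA polymerases (catalytic subunits)",
    "editing and processing nucleases",
    "Rad6 pathway",
    "disease",
    "other genes with known or suspect DNA repair function",
    "other conserved DNA damage response genes",
)

#: Token used for missing values in text serializations.
MISSING = "?"


def is_missing(value: object) -> bool:
    """True for the in-memory missing markers (None / NaN)."""
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


@dataclass(frozen=True)
class GeneRecord:
    """One DNA repair gene: label, pathway, evolutionary rate and GO terms.

    ``ka_ki`` is the human-chimp nonsynonymous substitution-rate measure;
    genes lacking an ortholog measurement carry ``None`` (kept missing,
    never imputed).  ``specific_go`` holds the most specific GO term ids
    annotated to the gene, before ancestor closure.
    """

    symbol: str
    class_label: str
    pathway: str
    ka_ki: Optional[float] = None
    specific_go: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class label {self.class_label!r} not in {CLASS_LABELS}"
            )
        if self.pathway not in PATHWAY_CATEGORIES:
            raise ValueError(f"unknown pathway category {self.pathway!r}")
        if self.ka_ki is not None and self.ka_ki < 0:
            raise ValueError("ka_ki must be non-negative")
        object.__setattr__(self, "specific_go", frozenset(self.specific_go))


@dataclass(frozen=True)
class InteractionRecord:
    """An undirected protein-protein interaction with evidence tags."""

    protein_a: str
    protein_b: str
    evidence: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("both interaction partners must be named")
        object.__setattr__(self, "evidence", frozenset(self.evidence))

    @property
    def pair(self) -> tuple:
        """Canonical unordered pair key (A-B and B-A are the same edge)."""
        return tuple(sorted((self.protein_a, self.protein_b)))


BINARY_DOMAIN = ("no", "yes")


@dataclass(frozen=True)
class AttributeDescriptor:
    """Schema entry for one dataset column."""

    name: str
    kind: str  # "binary" | "nominal" | "numeric"
    domain: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "nominal", "numeric"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "binary":
            object.__setattr__(self, "domain", BINARY_DOMAIN)
        elif self.kind == "nominal":
            if not self.domain:
                raise ValueError(f"nominal attribute {self.name!r} needs a domain")
            object.__setattr__(self, "domain", tuple(self.domain))
        else:
            object.__setattr__(self, "domain", None)


@dataclass
class Dataset:
    """Instances x typed attributes plus the class vector.

    ``values`` uses a positional integer index; nominal/binary columns are
    object dtype with NaN/None as the missing marker, numeric columns are
    float with NaN.
    """

    instance_ids: list
    attributes: list
    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        n = len(self.instance_ids)
        if len(self.values) != n or len(self.classes) != n:
            raise ValueError("instance_ids, values and classes must align")
        names = [a.name for a in self.attributes]
        if list(self.values.columns) != names:
            raise ValueError("values columns must match attribute descriptors")
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")
        bad = set(self.classes.unique()) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}")
        self.values = self.values.reset_index(drop=True)
        self.classes = self.classes.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    @property
    def attribute_names(self) -> list:
        return [a.name for a in self.attributes]

    def descriptor(self, name: str) -> AttributeDescriptor:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"no attribute named {name!r}")

    def class_frequency(self, label: str = CLASS_POSITIVE) -> float:
        """Relative frequency of ``label`` (the binomial null probability p0)."""
        return float((self.classes == label).mean())

    def class_counts(self) -> dict:
        return {c: int((self.classes == c).sum()) for c in CLASS_LABELS}

    # -- manipulation --------------------------------------------------------

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """Row subset by positional indices, preserving order."""
        idx = list(indices)
        return Dataset(
            instance_ids=[self.instance_ids[i] for i in idx],
            attributes=list(self.attributes),
            values=self.values.iloc[idx].reset_index(drop=True),
            classes=self.classes.iloc[idx].reset_index(drop=True),
        )

    def row(self, i: int) -> Mapping[str, object]:
        return self.values.iloc[i].to_dict()

    def iter_rows(self) -> Iterable[Mapping[str, object]]:
        for _, r in self.values.iterrows():
            yield r.to_dict()

    def require_both_classes(self) -> None:
        present = set(self.classes.unique())
        if len(present) < 2:
            raise ValueError(
                f"dataset contains a single class {sorted(present)}; both "
                f"{CLASS_LABELS} are required"
            )


def make_dataset(
    instance_ids: Sequence[str],
    attributes: Sequence[AttributeDescriptor],
    rows: Sequence[Mapping[str, object]],
    classes: Sequence[str],
) -> Dataset:
    """Assemble a Dataset from per-row mappings, coercing column dtypes."""
    frame = pd.DataFrame(list(rows), columns=[a.name for a in attributes])
    for a in attributes:
        if a.kind == "numeric":
            frame[a.name] = pd.to_numeric(frame[a.name], errors="coerce")
        else:
            col = frame[a.name].astype(object)
            frame[a.name] = col.where(~col.map(is_missing), other=np.nan)
    return Dataset(
        instance_ids=list(instance_ids),
        attributes=list(attributes),
        values=frame,
        classes=pd.Series(list(classes), dtype=object),
    )
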