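"""Feature construction: from gene records, PPI edges and closed GO
annotations to the classification datasets (variants D1-D5) and the
expression-only dataset.

Variant layout (columns, in order): DNA repair pathway (nominal), ka_ki
(numeric), one binary column per surviving GO term, then the variant's PPI
block — D1 none, D2 the numeric ``#partners`` count, D3/D4/D5 ``#partners``
plus binary interaction indicators for the 10/20/30 most connected proteins.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from agerepair.data import (
    BINARY_DOMAIN,
    CLASS_LABELS,
    AttributeDescriptor,
    Dataset,
    GeneRecord,
    InteractionRecord,
    PATHWAY_CATEGORIES,
    is_missing,
    make_dataset,
)
from agerepair.ontology import OntologyGraph, close_annotation

logger = logging.getLogger(__name__)

#: Evidence tags accepted as direct experimental support.
STRONG_EVIDENCE = frozenset({"in_vivo", "in_vitro"})

VARIANT_BPI = {"D1": None, "D2": 0, "D3": 10, "D4": 20, "D5": 30}
PARTNERS_ATTR = "#partners"


def filter_interactions(
    edges: Iterable[InteractionRecord], cohort: Iterable[str]
) -> List[InteractionRecord]:
    """Keep edges touching the cohort with in vivo / in vitro evidence.

    An edge survives iff at least one endpoint is a cohort gene and its
    evidence includes a direct experimental type; interactions supported
    only by high-throughput screens are dropped.  Duplicate unordered pairs
    are merged with their evidence unioned, keeping first-seen order.
    """
    cohort = set(cohort)
    merged: Dict[tuple, InteractionRecord] = {}
    for e in edges:
        if e.protein_a not in cohort and e.protein_b not in cohort:
            continue
        key = e.pair
        if key in merged:
            merged[key] = InteractionRecord(
                merged[key].protein_a,
                merged[key].protein_b,
                merged[key].evidence | e.evidence,
            )
        else:
            merged[key] = e
    return [e for e in merged.values() if e.evidence & STRONG_EVIDENCE]


def partner_map(edges: Iterable[InteractionRecord]) -> Dict[str, set]:
    """Distinct partner sets per protein; a self-edge adds the protein itself."""
    partners: Dict[str, set] = {}
    for e in edges:
        partners.setdefault(e.protein_a, set()).add(e.protein_b)
        partners.setdefault(e.protein_b, set()).add(e.protein_a)
    return partners


def count_partners(symbol: str, edges: Iterable[InteractionRecord]) -> int:
    """Number of distinct interaction partners of ``symbol``."""
    return len(partner_map(edges).get(symbol, set()))


def select_top_bpi(edges: Iterable[InteractionRecord], n: int) -> List[str]:
    """The n most connected proteins, ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = {p: len(s) for p, s in partner_map(edges).items()}
    ranked = sorted(counts, key=lambda p: (-counts[p], p))
    return ranked[:n]


def build_go_block(
    records: Sequence[GeneRecord], graph: OntologyGraph, t: int
) -> Tuple[List[AttributeDescriptor], pd.DataFrame]:
    """Binary yes/no columns for GO terms occurring in >= t closed annotations.

    Rare terms (fewer than ``t`` genes annotated after closure) carry no
    statistical support and are removed; columns are ordered by term id.
    """
    if t < 1:
        raise ValueError("occurrence threshold t must be >= 1")
    closures = [close_annotation(graph, r.specific_go) for r in records]
    freq = Counter(term for closed in closures for term in closed)
    surviving = sorted(term for term, c in freq.items() if c >= t)
    attrs = [AttributeDescriptor(term, "binary") for term in surviving]
    rows = [
        {term: ("yes" if term in closed else "no") for term in surviving}
        for closed in closures
    ]
    frame = pd.DataFrame(rows, columns=surviving, dtype=object)
    return attrs, frame


def build_dataset(
    records: Sequence[GeneRecord],
    edges: Iterable[InteractionRecord],
    graph: OntologyGraph,
    t: int = 3,
    variant: str = "D5",
    n_bpi: int | None = None,
) -> Dataset:
    """Assemble one dataset variant, then remove duplicate instances.

    ``n_bpi`` overrides the variant's default count of binary interaction
    columns (10/20/30 for D3/D4/D5).
    """
    if variant not in VARIANT_BPI:
        raise ValueError(f"variant must be one of {sorted(VARIANT_BPI)}")
    if not records:
        raise ValueError("records must be non-empty")
    labels = {r.class_label for r in records}
    if len(labels) < 2:
        raise ValueError(f"single-class input ({labels}); need both classes")

    symbols = [r.symbol for r in records]
    if len(set(symbols)) != len(symbols):
        raise ValueError("gene symbols must be unique within a cohort")

    attrs: List[AttributeDescriptor] = [
        AttributeDescriptor("pathway", "nominal", PATHWAY_CATEGORIES),
        AttributeDescriptor("ka_ki", "numeric"),
    ]
    go_attrs, go_frame = build_go_block(records, graph, t)
    attrs.extend(go_attrs)

    rows: List[dict] = []
    for i, r in enumerate(records):
        row = {"pathway": r.pathway, "ka_ki": r.ka_ki}
        row.update(go_frame.iloc[i].to_dict())
        rows.append(row)

    if variant != "D1":
        filtered = filter_interactions(edges, symbols)
        partners = partner_map(filtered)
        attrs.append(AttributeDescriptor(PARTNERS_ATTR, "numeric"))
        for r, row in zip(records, rows):
            row[PARTNERS_ATTR] = float(len(partners.get(r.symbol, set())))
        k = VARIANT_BPI[variant] if n_bpi is None else n_bpi
        if k:
            top = select_top_bpi(filtered, k)
            for prot in top:
                name = f"{prot}_interaction"
                attrs.append(AttributeDescriptor(name, "binary"))
                for r, row in zip(records, rows):
                    row[name] = (
                        "yes" if prot in partners.get(r.symbol, set()) else "no"
                    )

    dataset = make_dataset(
        symbols, attrs, rows, [r.class_label for r in records]
    )
    return deduplicate(dataset)


def deduplicate(dataset: Dataset) -> Dataset:
    """Drop instances identical on every attribute value and class.

    The first occurrence (input order) survives.  Attribute-identical
    instances with conflicting classes are all retained, with a logged
    warning — they signal that the attribute set cannot separate them.
    Idempotent.
    """
    seen: set = set()
    value_key_classes: Dict[tuple, set] = {}
    keep: List[int] = []
    for i in range(dataset.n_instances):
        vals = tuple(
            "\0missing" if is_missing(v) else v for v in dataset.values.iloc[i]
        )
        key = (vals, dataset.classes.iloc[i])
        value_key_classes.setdefault(vals, set()).add(dataset.classes.iloc[i])
        if key in seen:
            continue
        seen.add(key)
        keep.append(i)
    conflicts = sum(1 for cls in value_key_classes.values() if len(cls) > 1)
    if conflicts:
        logger.warning(
            "%d attribute-identical instance group(s) carry conflicting "
            "classes; all retained",
            conflicts,
        )
    if len(keep) == dataset.n_instances:
        return dataset
    return dataset.subset(keep)


def build_expression_dataset(
    probe_table: pd.DataFrame, class_labels: Mapping[str, str]
) -> Dataset:
    """Per-gene tissue expression profile from a probe-level table.

    ``probe_table`` has columns (gene, probe, anatomy, value).  Genes are
    often measured by several probe sets across array generations; the
    attribute value for a gene in an anatomy category is the arithmetic mean
    over all of that gene's probes there.  Categories a gene was never
    measured in become missing values.  One numeric column per anatomy
    category (sorted); instance order follows first appearance in the table.
    """
    required = {"gene", "probe", "anatomy", "value"}
    if probe_table is None or len(probe_table) == 0:
        raise ValueError("probe table is empty")
    missing_cols = required - set(probe_table.columns)
    if missing_cols:
        raise ValueError(f"probe table lacks columns {sorted(missing_cols)}")
    if (probe_table["value"].astype(float) < 0).any():
        raise ValueError("expression values must be non-negative")

    genes = list(dict.fromkeys(probe_table["gene"]))
    unlabeled = [g for g in genes if g not in class_labels]
    if unlabeled:
        raise ValueError(f"no class label for gene(s) {unlabeled[:5]}")
    tissues = sorted(probe_table["anatomy"].unique())
    means = (
        probe_table.groupby(["gene", "anatomy"])["value"].mean().unstack()
    )
    frame = means.reindex(index=genes, columns=tissues).astype(float)
    attrs = [AttributeDescriptor(tissue, "numeric") for tissue in tissues]
    return Dataset(
        instance_ids=genes,
        attributes=attrs,
        values=frame.reset_index(drop=True),
        classes=pd.Series([class_labels[g] for g in genes], dtype=object),
    )
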