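"""Synthetic cohort generator with planted, documented class signal.

Emulates the study design the pipeline targets: ~140 DNA repair genes with
33 ageing-related positives (class frequency 0.236), a biological-process
ontology DAG whose closed annotations give a sparse binary matrix, a
protein-interaction network in which positives have more partners (heavy
tail crossing 15) and one hub protein whose partners are predominantly
positive (10 of 11), and a 108-tissue expression matrix with one tissue in
which a small set of positives is highly expressed.

Generation is constructive: class labels are assigned first and every
attribute is drawn conditional on the label, so the ground truth records
planted patterns with exact realized coverage.  All randomness flows from a
single seeded generator; the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from agerepair.data import (
    CLASS_NEGATIVE,
    CLASS_POSITIVE,
    GeneRecord,
    InteractionRecord,
    PATHWAY_CATEGORIES,
)
from agerepair.features import partner_map, filter_interactions
from agerepair.ontology import BIOLOGICAL_PROCESS, OntologyGraph


@dataclass
class OntologyParams:
    n_terms: int = 150
    max_depth: int = 6
    branching: float = 2.0  # growth factor of level widths


@dataclass
class AnnotationParams:
    mean_specific_terms: float = 5.0
    n_planted_terms: int = 3
    p_positive: float = 0.8  # planted-term annotation rate in positives
    p_negative: float = 0.1


@dataclass
class PPIParams:
    neg_partner_mean: float = 4.0  # negatives: 1 + Poisson(mean), mode ~5
    pos_log_mean: float = math.log(18.0)  # positives: heavy tail crossing 15
    pos_log_sigma: float = 0.35
    # the hub is a positive cohort gene (like Ku80 in the real network)
    # wired to exactly this partner composition among the other genes
    hub_n_partners: int = 11
    hub_positive_partners: int = 10
    n_background: int = 300
    p_weak_edge: float = 0.15  # high-throughput-only edges (filtered out)
    p_duplicate: float = 0.05  # re-listed pairs (merged by the filter)


@dataclass
class ExpressionParams:
    n_tissues: int = 108
    planted_tissue: str = "T_lymphocyte"
    n_planted_genes: int = 5
    shift: float = 1.0  # log-space positive-class mean shift in the tissue
    log_mean: float = math.log(1500.0)
    log_sigma: float = 0.6
    max_probes: int = 3


@dataclass
class KaKiParams:
    log_mean: float = math.log(0.3)  # overlapping per class: non-predictive
    log_sigma: float = 0.5
    p_missing: float = 0.1


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_genes: int = 140
    n_positive: int = 33
    ontology: OntologyParams = field(default_factory=OntologyParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    ppi: PPIParams = field(default_factory=PPIParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    ka_ki: KaKiParams = field(default_factory=KaKiParams)

    def validate(self) -> None:
        if self.n_positive >= self.n_genes:
            raise ValueError("n_positive must be smaller than n_genes")
        if self.ppi.hub_n_partners >= self.n_genes:
            raise ValueError("hub cannot have more partners than genes exist")
        if self.ppi.hub_positive_partners > self.ppi.hub_n_partners:
            raise ValueError("infeasible hub partner composition")
        if self.ppi.hub_positive_partners > self.n_positive - 1:
            raise ValueError(
                "hub (itself a positive gene) needs enough other positives"
            )
        for p in (
            self.annotation.p_positive,
            self.annotation.p_negative,
            self.ppi.p_weak_edge,
            self.ppi.p_duplicate,
            self.ka_ki.p_missing,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.expression.n_planted_genes > self.n_positive:
            raise ValueError("planted expression genes must be positives")
        if self.ontology.n_terms < 3:
            raise ValueError("ontology needs at least 3 terms")


@dataclass
class GroundTruth:
    """Bookkeeping of every planted pattern, with realized coverage."""

    seed: int
    positives: List[str]
    hub_name: str
    hub_partners: List[str]
    hub_coverage: Tuple[int, int]  # (n partners, positive partners)
    planted_go_terms: List[dict]
    expression_rule: Optional[dict]
    partners_by_gene: Dict[str, int]
    planted_root_attributes: List[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    ontology: OntologyGraph
    records: List[GeneRecord]
    interactions: List[InteractionRecord]
    probe_table: pd.DataFrame
    ground_truth: GroundTruth


def _term_id(i: int) -> str:
    return f"GO:9{i:06d}"


def generate_ontology(
    params: OntologyParams, rng: np.random.Generator
) -> OntologyGraph:
    """Rooted biological-process DAG of the configured size and depth.

    Built top-down: each new term draws a target depth with probability
    proportional to branching**depth (levels widen geometrically), takes one
    parent from the level above and, with probability 0.25, a second parent
    from any shallower level — acyclic by construction.
    """
    graph = OntologyGraph()
    depth: Dict[str, int] = {}
    by_level: Dict[int, List[str]] = {0: []}

    root = _term_id(0)
    graph.parents[root] = set()
    graph.namespace[root] = BIOLOGICAL_PROCESS
    graph.label[root] = "synthetic biological process root"
    depth[root] = 0
    by_level[0].append(root)

    levels = np.arange(1, params.max_depth + 1)
    weights = params.branching ** levels.astype(float)
    weights = weights / weights.sum()
    for i in range(1, params.n_terms):
        term = _term_id(i)
        d = int(rng.choice(levels, p=weights))
        while d > 1 and not by_level.get(d - 1):
            d -= 1
        parent_pool = by_level.get(d - 1) or [root]
        parents = {parent_pool[int(rng.integers(len(parent_pool)))]}
        if d > 1 and rng.random() < 0.25:
            shallow = [t for lvl in range(d) for t in by_level.get(lvl, [])]
            parents.add(shallow[int(rng.integers(len(shallow)))])
        graph.parents[term] = parents
        graph.namespace[term] = BIOLOGICAL_PROCESS
        graph.label[term] = f"synthetic process {i}"
        depth[term] = d
        by_level.setdefault(d, []).append(term)
    graph.validate()
    return graph


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate gene records, interactions, probe table and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ontology = generate_ontology(config.ontology, rng)

    n = config.n_genes
    symbols = [f"DR{i:03d}" for i in range(1, n + 1)]
    pos_idx = set(
        int(i) for i in rng.choice(n, size=config.n_positive, replace=False)
    )
    labels = [
        CLASS_POSITIVE if i in pos_idx else CLASS_NEGATIVE for i in range(n)
    ]
    positives = [s for s, l in zip(symbols, labels) if l == CLASS_POSITIVE]
    negatives = [s for s, l in zip(symbols, labels) if l == CLASS_NEGATIVE]

    pathways = [
        PATHWAY_CATEGORIES[int(rng.integers(len(PATHWAY_CATEGORIES)))]
        for _ in range(n)
    ]
    kk = config.ka_ki
    ka_ki_vals: List[Optional[float]] = []
    for _ in range(n):
        if rng.random() < kk.p_missing:
            ka_ki_vals.append(None)
        else:
            ka_ki_vals.append(
                float(np.exp(rng.normal(kk.log_mean, kk.log_sigma)))
            )

    # --- GO annotations -----------------------------------------------------
    ann = config.annotation
    all_terms = sorted(ontology.term_ids)
    deep_terms = [
        t
        for t in all_terms
        if ontology.parents[t] and any(ontology.parents[p] for p in ontology.parents[t])
    ] or all_terms[1:]
    planted_terms = [
        deep_terms[int(i)]
        for i in rng.choice(
            len(deep_terms), size=min(ann.n_planted_terms, len(deep_terms)),
            replace=False,
        )
    ]
    background_terms = [t for t in all_terms if t not in set(planted_terms)]
    specific: List[set] = []
    planted_counts = {t: [0, 0] for t in planted_terms}  # [pos_yes, neg_yes]
    for i in range(n):
        terms: set = set()
        k = 1 + int(rng.poisson(max(ann.mean_specific_terms - 1.0, 0.0)))
        k = min(k, len(background_terms))
        picks = rng.choice(len(background_terms), size=k, replace=False)
        terms.update(background_terms[int(j)] for j in picks)
        rate = ann.p_positive if labels[i] == CLASS_POSITIVE else ann.p_negative
        for t in planted_terms:
            if rng.random() < rate:
                terms.add(t)
                planted_counts[t][0 if labels[i] == CLASS_POSITIVE else 1] += 1
        specific.append(terms)

    records = [
        GeneRecord(
            symbol=symbols[i],
            class_label=labels[i],
            pathway=pathways[i],
            ka_ki=ka_ki_vals[i],
            specific_go=frozenset(specific[i]),
        )
        for i in range(n)
    ]

    # --- PPI network ----------------------------------------------------------
    ppi = config.ppi
    background = [f"BG{i:03d}" for i in range(1, ppi.n_background + 1)]
    evidence_choices = [
        frozenset({"in_vivo"}),
        frozenset({"in_vitro"}),
        frozenset({"in_vivo", "in_vitro"}),
    ]
    edges: List[InteractionRecord] = []
    for i in range(n):
        if labels[i] == CLASS_POSITIVE:
            target = max(
                1, int(round(np.exp(rng.normal(ppi.pos_log_mean, ppi.pos_log_sigma))))
            )
        else:
            target = 1 + int(rng.poisson(ppi.neg_partner_mean))
        target = min(target, ppi.n_background)
        picks = rng.choice(ppi.n_background, size=target, replace=False)
        for j in picks:
            ev = evidence_choices[int(rng.integers(3))]
            edges.append(InteractionRecord(symbols[i], background[int(j)], ev))
        if rng.random() < ppi.p_weak_edge:
            j = int(rng.integers(ppi.n_background))
            edges.append(
                InteractionRecord(
                    symbols[i], background[j], frozenset({"high_throughput"})
                )
            )
        if rng.random() < ppi.p_duplicate and picks.size:
            j = int(picks[0])
            edges.append(
                InteractionRecord(
                    symbols[i], background[j], frozenset({"yeast_2-hybrid"})
                )
            )

    # the hub is a positive cohort gene wired to exactly the configured
    # partner composition among the other genes (so its interaction column
    # exists among the top interactors and its coverage is exact)
    hub_symbol = positives[int(rng.integers(len(positives)))]
    other_pos = [s for s in positives if s != hub_symbol]
    hub_pos = [
        other_pos[int(i)]
        for i in rng.choice(
            len(other_pos), size=ppi.hub_positive_partners, replace=False
        )
    ]
    n_hub_neg = ppi.hub_n_partners - ppi.hub_positive_partners
    hub_neg = [
        negatives[int(i)]
        for i in rng.choice(len(negatives), size=n_hub_neg, replace=False)
    ]
    hub_partners = hub_pos + hub_neg
    for g in hub_partners:
        edges.append(InteractionRecord(g, hub_symbol, frozenset({"in_vivo"})))

    filtered = filter_interactions(edges, symbols)
    realized_partners = {
        s: len(partner_map(filtered).get(s, set())) for s in symbols
    }

    # --- expression -----------------------------------------------------------
    expr = config.expression
    tissues = [expr.planted_tissue] + [
        f"tissue_{i:03d}" for i in range(1, expr.n_tissues)
    ]
    base = np.exp(
        rng.normal(expr.log_mean, expr.log_sigma, size=(n, expr.n_tissues))
    )
    expression_rule = None
    if expr.shift > 0:
        pos_mask = np.array([l == CLASS_POSITIVE for l in labels])
        base[pos_mask, 0] *= math.exp(expr.shift)
        planted_gene_idx = [
            i for i in range(n) if labels[i] == CLASS_POSITIVE
        ]
        chosen = [
            planted_gene_idx[int(i)]
            for i in rng.choice(
                len(planted_gene_idx), size=expr.n_planted_genes, replace=False
            )
        ]
        others = np.delete(base[:, 0], chosen)
        ceiling = float(others.max())
        planted_vals = ceiling * rng.uniform(1.5, 2.5, size=len(chosen))
        base[chosen, 0] = planted_vals
        threshold = float((ceiling + planted_vals.min()) / 2.0)
        expression_rule = {
            "tissue": expr.planted_tissue,
            "operator": ">",
            "threshold": threshold,
            "predicted_class": CLASS_POSITIVE,
            "genes": sorted(symbols[i] for i in chosen),
            "coverage": [len(chosen), len(chosen)],
        }

    probe_rows = []
    for i in range(n):
        for j, tissue in enumerate(tissues):
            v = base[i, j]
            n_probes = 1 + int(rng.integers(expr.max_probes))
            d = v * 0.2 * rng.random()
            if n_probes == 1:
                vals = [v]
            elif n_probes == 2:
                vals = [v - d, v + d]
            else:
                vals = [v, v - d, v + d]
            for p, pv in enumerate(vals, start=1):
                probe_rows.append(
                    (symbols[i], f"{symbols[i]}_p{p}", tissue, float(pv))
                )
    probe_table = pd.DataFrame(
        probe_rows, columns=["gene", "probe", "anatomy", "value"]
    )

    hub_positive = sum(1 for g in hub_partners if g in set(positives))
    ground_truth = GroundTruth(
        seed=config.seed,
        positives=positives,
        hub_name=hub_symbol,
        hub_partners=sorted(hub_partners),
        hub_coverage=(len(hub_partners), hub_positive),
        planted_go_terms=[
            {"term": t, "positive_yes": planted_counts[t][0],
             "negative_yes": planted_counts[t][1]}
            for t in planted_terms
        ],
        expression_rule=expression_rule,
        partners_by_gene=realized_partners,
        planted_root_attributes=sorted(
            {"#partners", f"{hub_symbol}_interaction", *planted_terms}
        ),
    )
    return SyntheticCohort(
        config=config,
        ontology=ontology,
        records=records,
        interactions=edges,
        probe_table=probe_table,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# file emission (formats consumed by agerepair.io / agerepair.ontology)


def write_obo(graph: OntologyGraph, path) -> None:
    lines = ["format-version: 1.2", ""]
    for term in sorted(graph.parents):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {graph.label[term]}")
        lines.append(f"namespace: {graph.namespace[term]}")
        for parent in sorted(graph.parents[term]):
            lines.append(f"is_a: {parent} ! {graph.label[parent]}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_cohort(cohort: SyntheticCohort, outdir) -> Dict[str, Path]:
    """Emit the five input files plus the ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "genes": outdir / "genes.tsv",
        "annotations": outdir / "annotations.tsv",
        "ppi": outdir / "ppi.tsv",
        "expression": outdir / "expression.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_obo(cohort.ontology, paths["ontology"])

    gene_lines = ["symbol\tclass\tpathway\tka_ki"]
    for r in cohort.records:
        ka = "?" if r.ka_ki is None else repr(r.ka_ki)
        gene_lines.append(f"{r.symbol}\t{r.class_label}\t{r.pathway}\t{ka}")
    paths["genes"].write_text("\n".join(gene_lines) + "\n", encoding="utf-8")

    ann_lines = ["symbol\tgo_terms"]
    for r in cohort.records:
        ann_lines.append(f"{r.symbol}\t{','.join(sorted(r.specific_go))}")
    paths["annotations"].write_text("\n".join(ann_lines) + "\n", encoding="utf-8")

    ppi_lines = ["symbol_a\tsymbol_b\tevidence"]
    for e in cohort.interactions:
        ppi_lines.append(
            f"{e.protein_a}\t{e.protein_b}\t{','.join(sorted(e.evidence))}"
        )
    paths["ppi"].write_text("\n".join(ppi_lines) + "\n", encoding="utf-8")

    expr_lines = ["gene\tprobe\tanatomy\tvalue"]
    for row in cohort.probe_table.itertuples(index=False):
        expr_lines.append(f"{row.gene}\t{row.probe}\t{row.anatomy}\t{row.value!r}")
    paths["expression"].write_text("\n".join(expr_lines) + "\n", encoding="utf-8")

    paths["ground_truth"].write_text(
        cohort.ground_truth.to_json(), encoding="utf-8"
    )
    return paths
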