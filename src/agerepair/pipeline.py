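"""Experiment orchestration: the variant x threshold x learner grid.

Reproduces the experimental design of the accuracy tables: for each dataset
variant (D1-D5), GO occurrence threshold t and learner, a stratified
cross-validated AUC and the root attribute of the tree trained on the full
dataset.  Every run is summarized with its config and seed so reports are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from agerepair import __version__
from agerepair.classifiers import LEARNERS, NaiveBayesLearner, TreeLearner
from agerepair.classifiers.tree import root_attribute, train_tree
from agerepair.data import Dataset, GeneRecord, InteractionRecord
from agerepair.evaluation import auc, cross_validate
from agerepair.features import build_dataset
from agerepair.ontology import OntologyGraph

logger = logging.getLogger(__name__)

DEFAULT_VARIANTS = ("D1", "D2", "D3", "D4", "D5")
DEFAULT_THRESHOLDS = (3, 7, 11)
DEFAULT_LEARNERS = ("tree", "naive_bayes")


def run_experiment_grid(
    records: Sequence[GeneRecord],
    edges: Iterable[InteractionRecord],
    graph: OntologyGraph,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    learners: Sequence[str] = DEFAULT_LEARNERS,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per (variant, t, learner): pooled CV AUC and tree root.

    The tree's root attribute is taken from a tree trained on the full
    dataset (the model a user would inspect), independent of the CV models.
    """
    edges = list(edges)
    rows: List[dict] = []
    for t in thresholds:
        for variant in variants:
            data = build_dataset(records, edges, graph, t=t, variant=variant)
            full_tree = train_tree(data)
            root = root_attribute(full_tree)
            for learner_name in learners:
                learner = LEARNERS[learner_name]()
                preds = cross_validate(data, learner, k=k, seed=seed)
                rows.append(
                    {
                        "variant": variant,
                        "t": t,
                        "learner": learner_name,
                        "seed": seed,
                        "n_instances": data.n_instances,
                        "n_attributes": len(data.attributes),
                        "auc": auc(preds),
                        "root_attribute": root if root else "none",
                    }
                )
    return pd.DataFrame(rows)


def run_metadata(config: dict, input_paths: Optional[dict] = None) -> dict:
    """Provenance block embedded in every report: config hash, versions, checksums."""
    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "config": config,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "agerepair_version": __version__,
        "python_version": platform.python_version(),
    }
    if input_paths:
        checksums = {}
        for name, path in input_paths.items():
            p = Path(path)
            if p.exists():
                checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        meta["input_checksums"] = checksums
    return meta


def write_report(frame: pd.DataFrame, meta: dict, outdir, stem: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
    doc = {"metadata": meta, "rows": frame.to_dict(orient="records")}
    (outdir / f"{stem}.json").write_text(json.dumps(doc, indent=1))
    logger.info("wrote %s report to %s", stem, outdir)
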