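"""Readers and writers for the pipeline's flat-file interchange formats.

Inputs: gene table TSV (symbol, class, pathway, ka_ki), annotation TSV or a
GAF 2.x column subset, PPI TSV (symbol_a, symbol_b, comma-separated evidence
tags — the documented PSI-MI TAB subset mapping), probe-level expression
TSV.  Outputs: dataset CSV (header row, "?" for missing, bit-exact float
round-trip via shortest repr) with a JSON schema sidecar, and ARFF with
declared nominal domains.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from agerepair.data import (
    CLASS_LABELS,
    MISSING,
    AttributeDescriptor,
    Dataset,
    GeneRecord,
    InteractionRecord,
    is_missing,
    make_dataset,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# input readers


def read_gene_table(path) -> List[GeneRecord]:
    """TSV columns: symbol, class, pathway, ka_ki ("?" or empty = missing)."""
    records = []
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    required = {"symbol", "class", "pathway", "ka_ki"}
    if not required <= set(frame.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    for _, row in frame.iterrows():
        raw = row["ka_ki"].strip()
        ka_ki = None if raw in ("", MISSING) else float(raw)
        records.append(
            GeneRecord(
                symbol=row["symbol"],
                class_label=row["class"],
                pathway=row["pathway"],
                ka_ki=ka_ki,
            )
        )
    return records


def read_annotations(path) -> Dict[str, set]:
    """Gene -> specific GO term ids, from TSV or GAF 2.x.

    TSV: two columns (gene_symbol, comma- or pipe-separated GO ids), with a
    header line.  GAF (detected by the ``!gaf-version`` pragma or 15+
    tab-separated columns): column 3 is the symbol, column 5 the GO id.
    """
    text = Path(path).read_text(encoding="utf-8").splitlines()
    annotations: Dict[str, set] = {}
    is_gaf = any(line.startswith("!gaf-version") for line in text[:5])
    if not is_gaf and text:
        first_data = next((l for l in text if l and not l.startswith(("!", "#"))), "")
        is_gaf = len(first_data.split("\t")) >= 15
    for line in text:
        if not line or line.startswith(("!", "#")):
            continue
        parts = line.split("\t")
        if is_gaf:
            symbol, term = parts[2], parts[4]
            annotations.setdefault(symbol, set()).add(term)
        else:
            if parts[0] == "symbol":  # header
                continue
            symbol = parts[0]
            terms = parts[1] if len(parts) > 1 else ""
            ids = {t for t in terms.replace("|", ",").split(",") if t}
            annotations.setdefault(symbol, set()).update(ids)
    return annotations


def attach_annotations(
    records: List[GeneRecord], annotations: Mapping[str, set]
) -> List[GeneRecord]:
    """Return records with their specific GO term sets filled in."""
    from dataclasses import replace

    return [
        replace(r, specific_go=frozenset(annotations.get(r.symbol, set())))
        for r in records
    ]


def read_interactions(path) -> List[InteractionRecord]:
    """TSV columns: symbol_a, symbol_b, evidence (comma-separated tags)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"symbol_a", "symbol_b", "evidence"}
    if not required <= set(frame.columns):
        raise ValueError(f"PPI table needs columns {sorted(required)}")
    edges = []
    for _, row in frame.iterrows():
        tags = frozenset(
            t.strip() for t in row["evidence"].split(",") if t.strip()
        )
        edges.append(InteractionRecord(row["symbol_a"], row["symbol_b"], tags))
    return edges


def read_probe_table(path) -> pd.DataFrame:
    """TSV columns: gene, probe, anatomy, value."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "probe", "anatomy", "value"}
    if not required <= set(frame.columns):
        raise ValueError(f"probe table needs columns {sorted(required)}")
    frame["value"] = frame["value"].astype(float)
    return frame


# ---------------------------------------------------------------------------
# dataset writers / readers


def _schema_path(path) -> Path:
    return Path(str(path) + ".schema.json")


def _format_cell(value, kind: str) -> str:
    if is_missing(value):
        return MISSING
    if kind == "numeric":
        return repr(float(value))
    return str(value)


def write_dataset_csv(dataset: Dataset, path) -> None:
    """Header row, "?" for missing; floats use shortest round-trip repr.

    A JSON schema sidecar (``<path>.schema.json``) records attribute kinds
    and nominal domains so the reader restores types bit-exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        header = ["instance_id"] + dataset.attribute_names + ["class"]
        out.write(",".join(_quote(h) for h in header) + "\n")
        for i in range(dataset.n_instances):
            cells = [_quote(str(dataset.instance_ids[i]))]
            for a in dataset.attributes:
                cells.append(_quote(_format_cell(dataset.values[a.name].iloc[i], a.kind)))
            cells.append(_quote(str(dataset.classes.iloc[i])))
            out.write(",".join(cells) + "\n")
    schema = {
        "attributes": [
            {"name": a.name, "kind": a.kind, "domain": a.domain}
            for a in dataset.attributes
        ]
    }
    _schema_path(path).write_text(json.dumps(schema, indent=1), encoding="utf-8")


def _quote(cell: str) -> str:
    if "," in cell or '"' in cell:
        return '"' + cell.replace('"', '""') + '"'
    return cell


def read_dataset_csv(path, schema: Optional[dict] = None) -> Dataset:
    """Inverse of :func:`write_dataset_csv` (uses the schema sidecar)."""
    path = Path(path)
    if schema is None:
        schema = json.loads(_schema_path(path).read_text(encoding="utf-8"))
    attrs = [
        AttributeDescriptor(
            a["name"], a["kind"], tuple(a["domain"]) if a["domain"] else None
        )
        for a in schema["attributes"]
    ]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = []
    for _, raw in frame.iterrows():
        row = {}
        for a in attrs:
            cell = raw[a.name]
            if cell == MISSING:
                row[a.name] = None
            elif a.kind == "numeric":
                row[a.name] = float(cell)
            else:
                row[a.name] = cell
        rows.append(row)
    return make_dataset(
        list(frame["instance_id"]), attrs, rows, list(frame["class"])
    )


def write_dataset_arff(dataset: Dataset, path, relation: str = "agerepair") -> None:
    """ARFF export with declared nominal domains and typed numerics."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write(f"@relation {relation}\n\n")
        for a in dataset.attributes:
            if a.kind == "numeric":
                out.write(f"@attribute {_arff_name(a.name)} numeric\n")
            else:
                domain = ",".join(_arff_name(v) for v in a.domain)
                out.write(f"@attribute {_arff_name(a.name)} {{{domain}}}\n")
        out.write(
            "@attribute class {" + ",".join(CLASS_LABELS) + "}\n\n@data\n"
        )
        for i in range(dataset.n_instances):
            cells = []
            for a in dataset.attributes:
                v = dataset.values[a.name].iloc[i]
                if is_missing(v):
                    cells.append(MISSING)
                elif a.kind == "numeric":
                    cells.append(repr(float(v)))
                else:
                    cells.append(_arff_name(str(v)))
            cells.append(str(dataset.classes.iloc[i]))
            out.write(",".join(cells) + "\n")


def _arff_name(name: str) -> str:
    if any(ch in name for ch in " ,{}%'\"#"):
        return "'" + name.replace("'", "\\'") + "'"
    return name
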