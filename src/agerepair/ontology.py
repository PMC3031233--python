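"""Gene Ontology is_a hierarchy and ancestor closure of gene annotations.

Databases record only a gene's most specific GO terms; the ontology's
semantics implies every ancestor term along the is_a hierarchy also applies.
Closure makes that implicit annotation explicit so that per-term statistics
are computed on the right counts.  Only the ``is_a`` relationship is
followed, and only biological_process terms survive the closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Set

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

BIOLOGICAL_PROCESS = "biological_process"
NAMESPACES = (BIOLOGICAL_PROCESS, "molecular_function", "cellular_component")


class OboParseError(ValueError):
    """Malformed OBO input (e.g. a [Term] stanza without an id)."""


class OntologyCycleError(ValueError):
    """The is_a relation is not acyclic."""


class UnknownTermError(KeyError):
    """A term identifier not present in the ontology."""


@dataclass
class OntologyGraph:
    """Term universe with direct is_a parent links and per-term namespace.

    ``aliases`` maps secondary (alt_id) identifiers to their canonical term.
    """

    parents: Dict[str, Set[str]] = field(default_factory=dict)
    namespace: Dict[str, str] = field(default_factory=dict)
    label: Dict[str, str] = field(default_factory=dict)
    aliases: Dict[str, str] = field(default_factory=dict)

    @property
    def term_ids(self) -> Set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.aliases

    def resolve(self, term: str) -> str:
        """Canonical id for ``term`` (resolving alt_id aliases)."""
        if term in self.parents:
            return term
        if term in self.aliases:
            return self.aliases[term]
        raise UnknownTermError(term)

    def validate(self) -> None:
        for term, ps in self.parents.items():
            missing = ps - self.parents.keys()
            if missing:
                raise ValueError(
                    f"term {term} references unknown parent(s) {sorted(missing)}"
                )
            if self.namespace.get(term) not in NAMESPACES:
                raise ValueError(f"term {term} has no valid namespace")
        g = nx.DiGraph(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise OntologyCycleError(f"is_a cycle detected: {cycle}")


def load_obo(path) -> OntologyGraph:
    """Read an OBO flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped, only ``is_a`` edges populate the parent
    relation, and ``alt_id`` lines become aliases of the canonical term.
    Raises :class:`OboParseError` naming the line of a [Term] stanza that
    lacks an id, and :class:`OntologyCycleError` if is_a edges form a cycle.
    """
    _prescan(path)
    net = obonet.read_obo(str(path))
    default_ns = (net.graph.get("default-namespace") or [None])[0]

    graph = OntologyGraph()
    for term, attrs in net.nodes(data=True):
        graph.parents[term] = set()
        ns = attrs.get("namespace", default_ns)
        if ns not in NAMESPACES:
            raise OboParseError(f"term {term} has unknown namespace {ns!r}")
        graph.namespace[term] = ns
        graph.label[term] = attrs.get("name", term)
        for alias in attrs.get("alt_id", []):
            graph.aliases[alias] = term
    for child, parent, key in net.edges(keys=True):
        if key != "is_a":
            continue
        if parent in graph.parents:
            graph.parents[child].add(parent)
    graph.validate()
    logger.info(
        "loaded ontology: %d terms, %d aliases (format %s)",
        len(graph.parents),
        len(graph.aliases),
        net.graph.get("format-version", "?"),
    )
    return graph


def _prescan(path) -> None:
    """Check every [Term] stanza carries an id; report the offending line."""
    stanza_line = None
    has_id = True  # header pseudo-stanza needs no id
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if line.startswith("["):
                if not has_id:
                    raise OboParseError(
                        f"[Term] stanza at line {stanza_line} has no id"
                    )
                stanza_line = lineno
                has_id = line != "[Term]"
            elif line.startswith("id:"):
                has_id = True
    if not has_id:
        raise OboParseError(f"[Term] stanza at line {stanza_line} has no id")


def ancestors(graph: OntologyGraph, term: str) -> Set[str]:
    """All proper ancestors of ``term`` reachable over is_a edges."""
    start = graph.resolve(term)
    seen: Set[str] = set()
    frontier = list(graph.parents[start])
    while frontier:
        t = frontier.pop()
        if t in seen:
            continue
        seen.add(t)
        frontier.extend(graph.parents[t])
    return seen


def close_annotation(graph: OntologyGraph, specific_terms: Iterable[str]) -> Set[str]:
    """Extend a gene's specific terms with all is_a ancestors, BP only.

    Unknown terms are skipped with a logged warning (ontology releases
    drift); the namespace filter is applied after closure, so the result is
    the biological_process part of specifics-union-ancestors.  Idempotent
    and monotone in the input set.
    """
    closed: Set[str] = set()
    for term in specific_terms:
        try:
            canonical = graph.resolve(term)
        except UnknownTermError:
            logger.warning("annotation term %s not in ontology; skipped", term)
            continue
        closed.add(canonical)
        closed.update(ancestors(graph, canonical))
    return {t for t in closed if graph.namespace[t] == BIOLOGICAL_PROCESS}
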