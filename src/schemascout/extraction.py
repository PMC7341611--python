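"""Instantiated-schema extraction from a private RDF dataset.

Four strategies, ordered by the amount of inference they fold in:

DIRECT
    Only what the data itself uses: every IRI in predicate position becomes
    an ``rdf:Property``, every IRI object of ``rdf:type`` an ``rdfs:Class``,
    with usage-derived ``rdfs:domain``/``rdfs:range`` statements and the
    terms' one-hop descriptions from the data.  Works with zero knowledge of
    the employed vocabularies.
ENTAILED
    Assumes a fully materialized store (entailment-supporting endpoint, or
    local materialization over data plus vocabularies) and simply takes the
    descriptions of all instantiated predicates and type objects.
LOCAL
    Re-creates what entailment would have added — generalizations and
    equivalences of the instantiated terms, plus classes reachable through
    declared domains/ranges — by closing over the data and locally available
    vocabulary files.  No endpoint entailment support needed.
FEDERATED
    As LOCAL, but every closure round also consults remote terminology
    services, so cross-vocabulary equivalences unknown to the local files
    are resolved too.

All strategies share the privacy contract: schema subjects are only
class/property terms, never individuals, and never blank nodes.  The
extracted schema is a query-authoring artifact — it is deliberately *not*
fed back into entailment (usage-derived multiple domains/ranges would entail
nonsense under conjunctive RDFS semantics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Sequence

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .core import DataSource, LocalSource, graph_union
from .entailment import (ClosureKind, equivalence_closure,
                         generalization_closure, materialize_entailment)

__all__ = [
    "ExtractionMode",
    "ExtractionConfig",
    "SchemaGraph",
    "extract",
    "extract_direct",
    "extract_entailed",
    "extract_local",
    "extract_federated",
]

logger = logging.getLogger(__name__)

_BUILTIN_NAMESPACES = (str(RDF), str(RDFS), str(OWL), str(XSD))


class ExtractionMode(Enum):
    DIRECT = "direct"
    ENTAILED = "entailed"
    LOCAL = "local"
    FEDERATED = "federated"


@dataclass
class ExtractionConfig:
    """Configuration shared by all extraction strategies.

    ``blank_node_policy`` is fixed: blank-node subjects are always excluded
    from published schema, to avoid renaming/resolution issues between blank
    nodes from different sources.
    """

    mode: ExtractionMode = ExtractionMode.DIRECT
    vocabularies: Sequence[DataSource] = ()
    terminology_endpoints: Sequence[DataSource] = ()
    include_builtin_terms: bool = True
    usage_domain_range: bool = True
    max_closure_rounds: int = 30
    #: output dialect for usage-derived statements: "rdfs" emits
    #: rdfs:domain/rdfs:range; "schema.org" emits schema:domainIncludes/
    #: schema:rangeIncludes, which carries the semantically safer
    #: disjunctive reading.
    domain_range_dialect: str = "rdfs"

    blank_node_policy: str = field(default="exclude", init=False)

    def __post_init__(self):
        if self.max_closure_rounds < 1:
            raise ValueError("max_closure_rounds must be positive")
        if self.domain_range_dialect not in ("rdfs", "schema.org"):
            raise ValueError("domain_range_dialect must be 'rdfs' or 'schema.org'")


@dataclass
class SchemaGraph:
    """An extracted, publishable schema.

    Invariants: every property term is declared ``rdf:Property`` and every
    class term ``rdfs:Class`` in :attr:`graph`; every subject of the graph is
    one of those terms and never a blank node (the privacy contract — no
    individual of the private data can leak through subject position).
    """

    graph: Graph
    mode: ExtractionMode
    source_id: str
    extracted_at: datetime
    property_terms: set[URIRef]
    class_terms: set[URIRef]

    def __len__(self) -> int:
        return len(self.graph)

    @property
    def subjects(self) -> set:
        return set(self.graph.subjects())


_SCHEMA_ORG_DIALECT = {
    RDFS.domain: URIRef("http://schema.org/domainIncludes"),
    RDFS.range: URIRef("http://schema.org/rangeIncludes"),
}


def _is_builtin(term: URIRef) -> bool:
    return str(term).startswith(_BUILTIN_NAMESPACES)


def _seed_terms(data: DataSource, config: ExtractionConfig):
    """Instantiated properties and classes of the data source."""
    props = set(data.predicate_iris())
    classes = {t for t in data.type_objects() if isinstance(t, URIRef)}
    if not config.include_builtin_terms:
        props = {p for p in props if not _is_builtin(p)}
        classes = {c for c in classes if not _is_builtin(c)}
    return props, classes


def _usage_triples(data: DataSource, props: set, config: ExtractionConfig) -> set:
    """Usage-derived domain/range statements, one per distinct
    (property, observed type) pair.  Literal objects never yield a range."""
    if not config.usage_domain_range:
        return set()
    out = set()
    for p, rel, t in data.usage_domain_range():
        if p in props and isinstance(t, URIRef):
            if config.domain_range_dialect == "schema.org":
                rel = _SCHEMA_ORG_DIALECT[rel]
            out.add((p, rel, t))
    return out


def _assemble(triples: set, props: set, classes: set, mode: ExtractionMode,
              source_id: str) -> SchemaGraph:
    """Build the SchemaGraph: type declarations + gathered triples, with
    blank-node subjects dropped."""
    g = Graph()
    g.bind("rdf", RDF)
    g.bind("rdfs", RDFS)
    g.bind("owl", OWL)
    for p in props:
        g.add((p, RDF.type, RDF.Property))
    for c in classes:
        g.add((c, RDF.type, RDFS.Class))
    for s, p, o in triples:
        if isinstance(s, BNode):
            continue
        g.add((s, p, o))
    return SchemaGraph(
        graph=g, mode=mode, source_id=source_id,
        extracted_at=datetime.now(timezone.utc),
        property_terms=props, class_terms=classes,
    )


def _source_id(data: DataSource) -> str:
    return getattr(data, "endpoint", None) or f"local:{id(data.__dict__.get('graph', data)):x}"


def extract_direct(data: DataSource, config: ExtractionConfig | None = None) -> SchemaGraph:
    """Directly instantiated schema: predicates, type objects, usage-derived
    domain/range, and the terms' own triples from the data — nothing inferred.
    """
    config = config or ExtractionConfig(mode=ExtractionMode.DIRECT)
    props, classes = _seed_terms(data, config)
    if not props and not classes:
        logger.warning("dataset is empty; extracted schema is empty")
    triples = _usage_triples(data, props, config)
    triples |= data.describe(props | classes)
    return _assemble(triples, props, classes, ExtractionMode.DIRECT, _source_id(data))


def extract_entailed(data: DataSource, config: ExtractionConfig | None = None) -> SchemaGraph:
    """Entailment-supported schema: descriptions of every instantiated
    predicate and type object of the *materialized* graph.

    For a local source the materialization is done here, over the data plus
    the configured vocabularies.  A remote source must advertise entailment
    support; otherwise the result falls back to directly instantiated
    semantics, with a warning.
    """
    config = config or ExtractionConfig(mode=ExtractionMode.ENTAILED)
    if isinstance(data, LocalSource):
        vocab_graphs = []
        for v in config.vocabularies:
            if not isinstance(v, LocalSource):
                raise ValueError(
                    "entailed extraction materializes locally and requires "
                    "local vocabulary sources"
                )
            vocab_graphs.append(v.graph)
        materialized = materialize_entailment(graph_union([data.graph, *vocab_graphs]))
        src: DataSource = LocalSource(graph=materialized)
    elif data.supports_entailment:
        src = data
    else:
        warnings.warn(
            "remote endpoint does not advertise entailment support; result "
            "carries directly-instantiated semantics"
        )
        schema = extract_direct(data, config)
        schema.mode = ExtractionMode.ENTAILED
        return schema
    props, classes = _seed_terms(src, config)
    triples = src.describe(props | classes)
    return _assemble(triples, props, classes, ExtractionMode.ENTAILED, _source_id(data))


def _closed_terms(data: DataSource, sources: Sequence[DataSource],
                  config: ExtractionConfig):
    """Seed from the data, then close properties and classes over *sources*:
    generalizations and equivalences, plus classes reachable through declared
    domains/ranges of the closed properties (re-closed to a fixed point)."""
    prop_seeds, class_seeds = _seed_terms(data, config)
    props = generalization_closure(prop_seeds, sources, ClosureKind.PROPERTY,
                                   max_rounds=config.max_closure_rounds)
    classes = generalization_closure(class_seeds, sources, ClosureKind.CLASS,
                                     max_rounds=config.max_closure_rounds)
    while True:
        declared = set()
        for src in sources:
            for s, _p, o in src.expand_links(props, (RDFS.domain, RDFS.range)):
                if s in props and isinstance(o, URIRef):
                    declared.add(o)
        new = declared - classes
        if not new:
            break
        classes = generalization_closure(classes | new, sources, ClosureKind.CLASS,
                                         max_rounds=config.max_closure_rounds)
    if not config.include_builtin_terms:
        props = {p for p in props if not _is_builtin(p)}
        classes = {c for c in classes if not _is_builtin(c)}
    return props, classes


def _extract_closed(data: DataSource, sources: Sequence[DataSource],
                    config: ExtractionConfig, mode: ExtractionMode) -> SchemaGraph:
    props, classes = _closed_terms(data, sources, config)
    triples = _usage_triples(data, props, config)
    for src in sources:
        triples |= src.describe(sorted(props | classes))
    return _assemble(triples, props, classes, mode, _source_id(data))


def extract_local(data: DataSource, config: ExtractionConfig | None = None) -> SchemaGraph:
    """Locally inferred schema over the data plus local vocabulary files.

    A superset of :func:`extract_direct` on the same data; with no
    vocabularies configured the two coincide.
    """
    config = config or ExtractionConfig(mode=ExtractionMode.LOCAL)
    sources = [data, *config.vocabularies]
    return _extract_closed(data, sources, config, ExtractionMode.LOCAL)


def extract_federated(data: DataSource, config: ExtractionConfig) -> SchemaGraph:
    """Terminology-federated schema: every closure round also consults the
    configured terminology endpoints, and term descriptions are fetched from
    them too (batched lookups, not one query per term).

    Staged pipeline: (1) seed instantiated terms from the data; (2) iterate
    closure rounds alternating local and remote expansion to a fixed point or
    the round limit; (3) fetch describing triples of all terms everywhere;
    (4) assemble, dropping blank-node subjects.  An unreachable endpoint
    aborts the run — a silently partial schema would violate completeness.
    """
    if not config.terminology_endpoints:
        raise ValueError("federated extraction requires at least one terminology endpoint")
    sources = [data, *config.vocabularies, *config.terminology_endpoints]
    return _extract_closed(data, sources, config, ExtractionMode.FEDERATED)


_DISPATCH = {
    ExtractionMode.DIRECT: extract_direct,
    ExtractionMode.ENTAILED: extract_entailed,
    ExtractionMode.LOCAL: extract_local,
    ExtractionMode.FEDERATED: extract_federated,
}


def extract(data: DataSource, config: ExtractionConfig) -> SchemaGraph:
    """Dispatch to the strategy named by ``config.mode``."""
    return _DISPATCH[config.mode](data, config)
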