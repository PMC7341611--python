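"""RDF data model, serialization I/O and data-source abstraction.

Triples are held in :class:`rdflib.Graph`; terms are rdflib's ``URIRef``,
``BNode`` and ``Literal``.  Literal identity follows rdflib's node identity:
value-space for recognized XSD datatypes (``"1"^^xsd:integer`` and
``"01"^^xsd:integer`` are one node), lexical form + datatype + language tag
otherwise — deterministic either way, which is what dataset statistics need.

Every consumer of RDF data in this package goes through :class:`DataSource`:
either a :class:`LocalSource` over parsed files, or a :class:`RemoteSource`
speaking SPARQL 1.1 Query over HTTP.  Remote sources are query-only; this
package never issues updates against foreign endpoints.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Iterable, Sequence

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

__all__ = [
    "ParseError",
    "SourceError",
    "parse_graph",
    "serialize_graph",
    "graph_union",
    "DataSource",
    "LocalSource",
    "RemoteSource",
]

#: rdflib parser names per accepted input format.
_PARSE_FORMATS = {
    "turtle": "turtle",
    "ntriples": "nt",
    "rdfxml": "xml",
    "jsonld": "json-ld",
}

_SERIALIZE_FORMATS = {"turtle": "turtle", "ntriples": "nt"}

_EXTENSION_FORMATS = {
    ".ttl": "turtle",
    ".turtle": "turtle",
    ".nt": "ntriples",
    ".ntriples": "ntriples",
    ".rdf": "rdfxml",
    ".xml": "rdfxml",
    ".owl": "rdfxml",
    ".jsonld": "jsonld",
    ".json": "jsonld",
}


class ParseError(ValueError):
    """Raised when an RDF document cannot be parsed."""


class SourceError(RuntimeError):
    """Raised when a data source is unreachable or misbehaves."""


def _detect_format(path: Path) -> str:
    fmt = _EXTENSION_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ParseError(
            f"cannot auto-detect RDF format from extension {path.suffix!r} "
            f"({path}); pass format explicitly"
        )
    return fmt


def parse_graph(path: str | Path, format: str = "auto") -> Graph:
    """Parse an RDF file into a deduplicated :class:`rdflib.Graph`.

    Parameters
    ----------
    path:
        File to read.  Must exist.
    format:
        One of ``turtle | ntriples | rdfxml | jsonld | auto``.  With ``auto``
        the format is detected from the file extension.

    Named-graph (quad) structure, if any, is flattened to the default graph:
    all downstream queries are triple-pattern based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such RDF file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in _PARSE_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; expected one of "
            f"{sorted(_PARSE_FORMATS)} or 'auto'"
        )
    g = Graph()
    try:
        g.parse(path, format=_PARSE_FORMATS[format])
    except Exception as exc:  # rdflib raises assorted exception types
        raise ParseError(f"failed to parse {path} as {format}: {exc}") from exc
    return g


def serialize_graph(g: Graph, format: str = "turtle") -> str:
    """Serialize a graph to Turtle or N-Triples text.

    Round-trip property: ``parse(serialize(g))`` equals ``g`` triple-for-triple
    up to consistent blank-node relabeling.
    """
    if format not in _SERIALIZE_FORMATS:
        raise ValueError(
            f"unknown output format {format!r}; expected one of "
            f"{sorted(_SERIALIZE_FORMATS)}"
        )
    return g.serialize(format=_SERIALIZE_FORMATS[format])


def graph_union(graphs: Sequence[Graph]) -> Graph:
    """Set-union of graphs with per-input blank-node scoping.

    Blank-node identity is file-scoped: blank nodes from different inputs are
    kept distinct by relabeling, mirroring the resolution issues blank nodes
    cause between sources.  Prefix bindings merge first-wins.
    """
    out = Graph()
    bound: dict[str, URIRef] = {}
    for i, g in enumerate(graphs):
        relabel: dict[BNode, BNode] = {}

        def rename(term, i=i, relabel=relabel):
            if isinstance(term, BNode):
                if term not in relabel:
                    relabel[term] = BNode(f"u{i}_{term}")
                return relabel[term]
            return term

        for s, p, o in g:
            out.add((rename(s), p, rename(o)))
        for prefix, ns in g.namespaces():
            if prefix and prefix not in bound:
                bound[prefix] = ns
                out.bind(prefix, ns)
    return out


class DataSource(ABC):
    """Uniform query surface over a local graph or a remote SPARQL endpoint.

    The closure and extraction engines only ever need four capabilities:
    seed discovery (instantiated predicates and ``rdf:type`` objects),
    link expansion along a fixed predicate set, one-hop description, and
    usage-derived domain/range observation.
    """

    #: whether the source materializes entailed triples itself
    supports_entailment: bool = False

    @abstractmethod
    def predicate_iris(self) -> set[URIRef]:
        """All IRIs used in predicate position."""

    @abstractmethod
    def type_objects(self) -> set:
        """All terms in object position of ``rdf:type`` triples (unfiltered)."""

    @abstractmethod
    def expand_links(self, terms: set[URIRef], predicates: Sequence[URIRef]) -> set[tuple]:
        """Triples ``(s, p, o)`` with ``p`` in *predicates* touching *terms*
        in subject or object position."""

    @abstractmethod
    def describe(self, terms: Iterable[URIRef]) -> set[tuple]:
        """One-hop description: all triples whose subject is in *terms*."""

    @abstractmethod
    def usage_domain_range(self) -> set[tuple]:
        """Observed ``(property, rdfs:domain|rdfs:range, class)`` facts.

        For every data triple ``s p o``: each IRI type of ``s`` yields a
        domain observation on ``p``; each IRI type of a *non-literal* ``o``
        yields a range observation.  Untyped nodes contribute nothing;
        literal objects never yield a range.
        """


class LocalSource(DataSource):
    """A data source backed by one or more parsed local files."""

    def __init__(self, graph: Graph | None = None, paths: Sequence[str | Path] = (),
                 format: str = "auto", supports_entailment: bool = False):
        parts = [graph] if graph is not None else []
        parts += [parse_graph(p, format=format) for p in paths]
        self.graph = parts[0] if len(parts) == 1 else graph_union(parts)
        self.supports_entailment = supports_entailment

    def predicate_iris(self) -> set[URIRef]:
        return {p for p in self.graph.predicates() if isinstance(p, URIRef)}

    def type_objects(self) -> set:
        return set(self.graph.objects(None, RDF.type))

    def expand_links(self, terms, predicates):
        out = set()
        for pred in predicates:
            for s, o in self.graph.subject_objects(pred):
                if s in terms or o in terms:
                    out.add((s, pred, o))
        return out

    def describe(self, terms):
        out = set()
        for t in terms:
            for p, o in self.graph.predicate_objects(t):
                out.add((t, p, o))
        return out

    def usage_domain_range(self):
        g = self.graph
        types: dict = {}

        def iri_types(node):
            if node not in types:
                types[node] = {t for t in g.objects(node, RDF.type)
                               if isinstance(t, URIRef)}
            return types[node]

        out = set()
        for s, p, o in g:
            for t in iri_types(s):
                out.add((p, RDFS.domain, t))
            if not isinstance(o, Literal):
                for t in iri_types(o):
                    out.add((p, RDFS.range, t))
        return out


def _term_from_json(b: dict):
    t = b["type"]
    if t == "uri":
        return URIRef(b["value"])
    if t == "bnode":
        return BNode(b["value"])
    # 'literal' / legacy 'typed-literal'
    return Literal(b["value"], lang=b.get("xml:lang"),
                   datatype=URIRef(b["datatype"]) if b.get("datatype") else None)


def _values_block(var: str, terms: Iterable[URIRef]) -> str:
    inner = " ".join(f"<{t}>" for t in terms)
    return f"VALUES ?{var} {{ {inner} }}"


class RemoteSource(DataSource):
    """A remote SPARQL 1.1 query endpoint (query-only; never updated).

    Term lookups are batched into VALUES blocks of ``batch_size`` IRIs rather
    than one query per term, since federated lookups are where the runtime
    cost of remote schema extraction concentrates.  A failed request is
    retried once, then surfaced as :class:`SourceError` — never as a silent
    partial result, which would corrupt schema-completeness guarantees.
    """

    def __init__(self, endpoint: str, auth_token: str | None = None,
                 timeout: float = 30.0, supports_entailment: bool = False,
                 batch_size: int = 100):
        self.endpoint = endpoint
        self.auth_token = auth_token
        self.timeout = timeout
        self.supports_entailment = supports_entailment
        self.batch_size = batch_size

    def query(self, sparql: str) -> list[dict]:
        """Run a SELECT query, returning a list of binding rows."""
        data = urllib.parse.urlencode({"query": sparql}).encode()
        headers = {
            "Accept": "application/sparql-results+json",
            "Content-Type": "application/x-www-form-urlencoded",
        }
        if self.auth_token:
            headers["Authorization"] = f"Bearer {self.auth_token}"
        last_exc = None
        for _attempt in range(2):  # one retry on transient failure
            req = urllib.request.Request(self.endpoint, data=data, headers=headers)
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    payload = json.load(resp)
                rows = []
                for binding in payload["results"]["bindings"]:
                    rows.append({k: _term_from_json(v) for k, v in binding.items()})
                return rows
            except (urllib.error.URLError, OSError, KeyError, ValueError) as exc:
                last_exc = exc
        raise SourceError(
            f"SPARQL endpoint {self.endpoint} unreachable or returned an "
            f"invalid response: {last_exc}"
        )

    def predicate_iris(self):
        rows = self.query("SELECT DISTINCT ?p WHERE { ?s ?p ?o }")
        return {r["p"] for r in rows if isinstance(r["p"], URIRef)}

    def type_objects(self):
        rows = self.query(
            "SELECT DISTINCT ?t WHERE { ?s "
            f"<{RDF.type}> ?t }}"
        )
        return {r["t"] for r in rows}

    def _batches(self, terms):
        terms = sorted(terms)  # deterministic batching
        for i in range(0, len(terms), self.batch_size):
            yield terms[i:i + self.batch_size]

    def expand_links(self, terms, predicates):
        out = set()
        if not terms or not predicates:
            return out
        preds = " ".join(f"<{p}>" for p in predicates)
        for batch in self._batches(terms):
            q = (
                "SELECT ?s ?p ?o WHERE { "
                f"VALUES ?p {{ {preds} }} "
                "{ " + _values_block("s", batch) + " ?s ?p ?o } UNION "
                "{ " + _values_block("o", batch) + " ?s ?p ?o } }"
            )
            for r in self.query(q):
                out.add((r["s"], r["p"], r["o"]))
        return out

    def describe(self, terms):
        out = set()
        terms = [t for t in terms if isinstance(t, URIRef)]
        for batch in self._batches(terms):
            q = ("SELECT ?s ?p ?o WHERE { " + _values_block("s", batch)
                 + " ?s ?p ?o }")
            for r in self.query(q):
                out.add((r["s"], r["p"], r["o"]))
        return out

    def usage_domain_range(self):
        out = set()
        qd = ("SELECT DISTINCT ?p ?t WHERE { ?s ?p ?o . ?s "
              f"<{RDF.type}> ?t . FILTER(isIRI(?t)) }}")
        for r in self.query(qd):
            out.add((r["p"], RDFS.domain, r["t"]))
        qr = ("SELECT DISTINCT ?p ?t WHERE { ?s ?p ?o . ?o "
              f"<{RDF.type}> ?t . FILTER(isIRI(?t) && !isLiteral(?o)) }}")
        for r in self.query(qr):
            out.add((r["p"], RDFS.range, r["t"]))
        return out
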