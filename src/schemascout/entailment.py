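"""Bounded RDFS/OWL entailment: rule materialization and term closures.

The rule set is deliberately small.  Schema extraction for query authoring
needs subclass/subproperty generalization (rdfs5, rdfs7, rdfs9, rdfs11),
domain/range typing (rdfs2, rdfs3) and the three OWL equivalence predicates
``owl:equivalentClass``, ``owl:equivalentProperty`` and ``owl:sameAs`` —
nothing else.  ``owl:sameAs`` is formally an individual-level predicate but
is widely (mis)used between vocabulary terms, so it participates here, with
substitution restricted to class/property positions: no individual-level
sameAs smushing is performed.

Equivalence predicates are treated as symmetric regardless of the direction
in which they were asserted, per OWL semantics.

No other OWL construct (disjointness, restrictions, property chains) is
interpreted; the extracted schema is a query-authoring aid, not a reasoning
substrate.
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import FrozenSet, Iterable, Sequence

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .core import DataSource

__all__ = [
    "RuleId",
    "ClosureKind",
    "ALL_RULES",
    "materialize_entailment",
    "equivalence_closure",
    "generalization_closure",
]


class RuleId(Enum):
    """The entailment rules this engine may apply — never any other."""

    RDFS2 = "rdfs2"            # p rdfs:domain c  &  x p y   =>  x a c
    RDFS3 = "rdfs3"            # p rdfs:range c   &  x p y   =>  y a c   (y non-literal)
    RDFS5 = "rdfs5"            # subPropertyOf transitivity
    RDFS7 = "rdfs7"            # p subPropertyOf q  &  x p y  =>  x q y
    RDFS9 = "rdfs9"            # x a c  &  c subClassOf d  =>  x a d
    RDFS11 = "rdfs11"          # subClassOf transitivity
    OWL_EQ_CLASS = "owl-eq-class"    # equivalentClass => symmetric + mutual subClassOf
    OWL_EQ_PROP = "owl-eq-prop"      # equivalentProperty => symmetric + mutual subPropertyOf
    OWL_SAMEAS = "owl-sameas"        # symmetric/transitive; schema-position substitution


ALL_RULES: FrozenSet[RuleId] = frozenset(RuleId)


class ClosureKind(Enum):
    """Which hierarchy a term closure ascends.

    CLASS closures never consult ``rdfs:subPropertyOf`` and vice versa.
    """

    CLASS = "class"
    PROPERTY = "property"


_EQ_PREDICATES = {
    ClosureKind.CLASS: (OWL.equivalentClass, OWL.sameAs),
    ClosureKind.PROPERTY: (OWL.equivalentProperty, OWL.sameAs),
}

_SUB_PREDICATE = {
    ClosureKind.CLASS: RDFS.subClassOf,
    ClosureKind.PROPERTY: RDFS.subPropertyOf,
}


def _apply_rules_once(triples: set, rules: frozenset) -> set:
    """One joint application round of every active rule; returns new triples."""
    new: set = set()

    # Index by predicate once per round.
    by_pred: dict = {}
    for t in triples:
        by_pred.setdefault(t[1], set()).add(t)

    sub_class = by_pred.get(RDFS.subClassOf, set())
    sub_prop = by_pred.get(RDFS.subPropertyOf, set())
    typed = by_pred.get(RDF.type, set())
    domains = by_pred.get(RDFS.domain, set())
    ranges = by_pred.get(RDFS.range, set())

    if RuleId.RDFS2 in rules:
        for p, _, c in domains:
            for s, _, o in by_pred.get(p, ()):
                new.add((s, RDF.type, c))
    if RuleId.RDFS3 in rules:
        for p, _, c in ranges:
            for s, _, o in by_pred.get(p, ()):
                if not isinstance(o, Literal):
                    new.add((o, RDF.type, c))
    if RuleId.RDFS5 in rules:
        supers: dict = {}
        for a, _, b in sub_prop:
            supers.setdefault(a, set()).add(b)
        for a, _, b in sub_prop:
            for c in supers.get(b, ()):
                new.add((a, RDFS.subPropertyOf, c))
    if RuleId.RDFS7 in rules:
        for p, _, q in sub_prop:
            if isinstance(q, URIRef):
                for s, _, o in by_pred.get(p, ()):
                    new.add((s, q, o))
    if RuleId.RDFS9 in rules:
        supers = {}
        for c, _, d in sub_class:
            supers.setdefault(c, set()).add(d)
        for x, _, c in typed:
            for d in supers.get(c, ()):
                new.add((x, RDF.type, d))
    if RuleId.RDFS11 in rules:
        supers = {}
        for a, _, b in sub_class:
            supers.setdefault(a, set()).add(b)
        for a, _, b in sub_class:
            for c in supers.get(b, ()):
                new.add((a, RDFS.subClassOf, c))
    if RuleId.OWL_EQ_CLASS in rules:
        for a, _, b in by_pred.get(OWL.equivalentClass, ()):
            new.add((b, OWL.equivalentClass, a))
            new.add((a, RDFS.subClassOf, b))
            new.add((b, RDFS.subClassOf, a))
    if RuleId.OWL_EQ_PROP in rules:
        for a, _, b in by_pred.get(OWL.equivalentProperty, ()):
            new.add((b, OWL.equivalentProperty, a))
            new.add((a, RDFS.subPropertyOf, b))
            new.add((b, RDFS.subPropertyOf, a))
    if RuleId.OWL_SAMEAS in rules:
        same = by_pred.get(OWL.sameAs, set())
        alias: dict = {}
        for a, _, b in same:
            new.add((b, OWL.sameAs, a))
            alias.setdefault(a, set()).add(b)
        for a, _, b in same:
            for c in alias.get(b, ()):
                new.add((a, OWL.sameAs, c))
        # Substitution only in schema-level positions.
        for a, bs in alias.items():
            for b in bs:
                # class positions
                for x, _, c in typed:
                    if c == a:
                        new.add((x, RDF.type, b))
                for s, pred, o in sub_class | by_pred.get(OWL.equivalentClass, set()):
                    if s == a:
                        new.add((b, pred, o))
                    if o == a:
                        new.add((s, pred, b))
                for p, pred, c in domains | ranges:
                    if c == a:
                        new.add((p, pred, b))
                    if p == a:
                        new.add((b, pred, c))
                # property positions
                if isinstance(b, URIRef):
                    for s, _, o in by_pred.get(a, ()):
                        new.add((s, b, o))
                for s, pred, o in sub_prop | by_pred.get(OWL.equivalentProperty, set()):
                    if s == a:
                        new.add((b, pred, o))
                    if o == a:
                        new.add((s, pred, b))
    return new - triples


def materialize_entailment(g: Graph, rules: Iterable[RuleId] = ALL_RULES) -> Graph:
    """Fixed point of the active rules over *g* (pure; *g* is not mutated).

    Monotone (``g`` is contained in the result), idempotent, and monotone in
    the rule set.  Cycle-safe by construction: the loop adds triples until no
    rule fires, and the term universe is finite.
    """
    rules = frozenset(rules)
    triples = set(g)
    while True:
        new = _apply_rules_once(triples, rules)
        if not new:
            break
        triples |= new
    out = Graph()
    for prefix, ns in g.namespaces():
        out.bind(prefix, ns)
    for t in triples:
        out.add(t)
    return out


def equivalence_closure(seeds: Iterable[URIRef], sources: Sequence[DataSource],
                        kind: ClosureKind) -> set[URIRef]:
    """Smallest superset of *seeds* closed under the kind's equivalence
    predicates, treated as symmetric and transitive across all *sources*.
    """
    eq_preds = _EQ_PREDICATES[kind]
    closed = set(seeds)
    frontier = set(closed)
    while frontier:
        found = set()
        for src in sources:
            for s, _p, o in src.expand_links(frontier, eq_preds):
                if s in closed and isinstance(o, URIRef):
                    found.add(o)
                if o in closed and isinstance(s, URIRef):
                    found.add(s)
        frontier = found - closed
        closed |= frontier
    return closed


def generalization_closure(seeds: Iterable[URIRef], sources: Sequence[DataSource],
                           kind: ClosureKind, max_rounds: int | None = None) -> set[URIRef]:
    """Equivalents and generalizations of *seeds*, to a fixed point.

    Alternates equivalence closure with one-step ascent along
    ``rdfs:subClassOf`` (CLASS) or ``rdfs:subPropertyOf`` (PROPERTY) across
    all sources.  Always contains the seeds; terminates on cyclic
    hierarchies via the visited set.  If *max_rounds* is reached before the
    fixed point, a warning names the unexpanded frontier.
    """
    sub_pred = _SUB_PREDICATE[kind]
    closed = equivalence_closure(seeds, sources, kind)
    rounds = 0
    while True:
        supers = set()
        for src in sources:
            for s, _p, o in src.expand_links(closed, (sub_pred,)):
                if s in closed and isinstance(o, URIRef):
                    supers.add(o)
        new = supers - closed
        if not new:
            return closed
        rounds += 1
        if max_rounds is not None and rounds > max_rounds:
            warnings.warn(
                f"generalization closure hit the round limit ({max_rounds}); "
                f"unexpanded frontier: {sorted(str(t) for t in new)}"
            )
            return closed
        closed = equivalence_closure(closed | new, sources, kind)
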