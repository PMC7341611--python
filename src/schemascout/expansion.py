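"""Schema-aided SPARQL query expansion.

A private endpoint usually has no entailment support, so a query for "all
persons" must spell out everything entailment would have resolved: the
equivalent classes, the subclasses and *their* equivalents, and the
properties whose declared domain or range provides indirect type evidence
(a subject of a property with domain Person is a person even without a type
triple).  This module turns a class or property IRI plus an extracted schema
into such an explicit plan, and renders the plan as a SPARQL 1.1 UNION query
that evaluates correctly over the raw, non-materialized data.

Expansion *descends* the hierarchies (instance retrieval needs
specializations: a Patient qualifies as a Person), interleaving equivalence
steps exactly as the entailment engine does on the way up.  Domain/range
evidence properties are themselves closed downward over sub-properties and
equivalents — an assertion via a sub-property of a domain-bearing property
carries the same type evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from rdflib import Graph, URIRef
from rdflib.namespace import OWL, RDFS

from .extraction import SchemaGraph

__all__ = ["QueryKind", "QueryPlan", "expand_class_query",
           "expand_property_query", "render_sparql"]


class QueryKind(Enum):
    CLASS = "class"
    PROPERTY = "property"


@dataclass
class QueryPlan:
    """Explicit expansion of a class/property query over an extracted schema.

    For CLASS plans, an individual qualifies if it is an instance of any
    type atom, the subject of any domain-evidence property, or the
    (non-literal) object of any range-evidence property.
    """

    target: URIRef
    kind: QueryKind
    type_atoms: set[URIRef] = field(default_factory=set)
    domain_evidence: set[URIRef] = field(default_factory=set)
    range_evidence: set[URIRef] = field(default_factory=set)
    property_atoms: set[URIRef] = field(default_factory=set)


_CLASS_EQ = (OWL.equivalentClass, OWL.sameAs)
_PROP_EQ = (OWL.equivalentProperty, OWL.sameAs)


def _descend(seeds: set[URIRef], g: Graph, sub_pred, eq_preds) -> set[URIRef]:
    """Downward closure: specializations (subjects of sub_pred edges into the
    set) and equivalents (both directions), to a fixed point.  Cycle-safe."""
    closed = set(seeds)
    frontier = set(closed)
    while frontier:
        found: set[URIRef] = set()
        for t in frontier:
            for s in g.subjects(sub_pred, t):
                if isinstance(s, URIRef):
                    found.add(s)
            for ep in eq_preds:
                for o in g.objects(t, ep):
                    if isinstance(o, URIRef):
                        found.add(o)
                for s in g.subjects(ep, t):
                    if isinstance(s, URIRef):
                        found.add(s)
        frontier = found - closed
        closed |= frontier
    return closed


def expand_class_query(cls: URIRef, schema: SchemaGraph,
                       include_evidence: bool = True) -> QueryPlan:
    """Expand a class query into type atoms plus domain/range evidence.

    ``include_evidence=False`` drops the domain/range branches: usage-derived
    domains are heuristic (observing a property on one type does not
    logically restrict it), and some integration queries want only asserted
    and equivalent types.
    """
    g = schema.graph
    atoms = _descend({cls}, g, RDFS.subClassOf, _CLASS_EQ)
    plan = QueryPlan(target=cls, kind=QueryKind.CLASS, type_atoms=atoms)
    if include_evidence:
        dom = {p for p in g.subjects(RDFS.domain, None)
               if isinstance(p, URIRef)
               and any(d in atoms for d in g.objects(p, RDFS.domain))}
        rng = {p for p in g.subjects(RDFS.range, None)
               if isinstance(p, URIRef)
               and any(r in atoms for r in g.objects(p, RDFS.range))}
        # sub-properties / equivalents of an evidence property carry the
        # same domain/range evidence
        plan.domain_evidence = _descend(dom, g, RDFS.subPropertyOf, _PROP_EQ)
        plan.range_evidence = _descend(rng, g, RDFS.subPropertyOf, _PROP_EQ)
    return plan


def expand_property_query(prop: URIRef, schema: SchemaGraph) -> QueryPlan:
    """Expand a property query over sub-properties, equivalent properties
    and sameAs links declared in the schema."""
    atoms = _descend({prop}, schema.graph, RDFS.subPropertyOf, _PROP_EQ)
    return QueryPlan(target=prop, kind=QueryKind.PROPERTY, property_atoms=atoms)


def render_sparql(plan: QueryPlan) -> str:
    """Render a plan as a SPARQL 1.1 SELECT DISTINCT query.

    Branches are ordered deterministically (type atoms, then domain
    evidence, then range evidence, each lexicographic).  IRIs are always
    written in full — never as prefixed names — for endpoint portability.
    Range branches exclude literal bindings, which could never be instances.
    """
    branches: list[str] = []
    if plan.kind is QueryKind.CLASS:
        rdf_type = "<http://www.w3.org/1999/02/22-rdf-syntax-ns#type>"
        for c in sorted(plan.type_atoms):
            branches.append(f"{{ ?x {rdf_type} <{c}> }}")
        for p in sorted(plan.domain_evidence):
            branches.append(f"{{ ?x <{p}> ?o }}")
        for p in sorted(plan.range_evidence):
            branches.append(f"{{ ?s <{p}> ?x . FILTER(!isLiteral(?x)) }}")
        head = "SELECT DISTINCT ?x"
    else:
        for p in sorted(plan.property_atoms):
            branches.append(f"{{ ?x <{p}> ?y }}")
        head = "SELECT DISTINCT ?x ?y"
    if not branches:
        warnings.warn("empty query plan; rendered query matches nothing")
        return f"{head} WHERE {{ ?x <urn:schemascout:nothing> <urn:schemascout:nothing> }}"
    body = "\n  UNION\n  ".join(branches)
    return f"{head} WHERE {{\n  {body}\n}}"
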