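"""Independent brute-force entailment oracle for the test suite.

Deliberately naive: every rule is applied by scanning all triple pairs, over
and over, until no new triple appears.  No indexing, no shared code with the
production engine — this is the reference the fixed-point implementation is
checked against on small random graphs.
"""

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from schemascout.entailment import RuleId


def naive_materialize(g, rules) -> set:
    triples = set(g)
    changed = True
    while changed:
        changed = False
        snapshot = list(triples)
        new = set()
        for t1 in snapshot:
            s1, p1, o1 = t1
            if RuleId.RDFS7 in rules and p1 == RDFS.subPropertyOf and isinstance(o1, URIRef):
                for s2, p2, o2 in snapshot:
                    if p2 == s1:
                        new.add((s2, o1, o2))
            if RuleId.RDFS2 in rules and p1 == RDFS.domain:
                for s2, p2, o2 in snapshot:
                    if p2 == s1:
                        new.add((s2, RDF.type, o1))
            if RuleId.RDFS3 in rules and p1 == RDFS.range:
                for s2, p2, o2 in snapshot:
                    if p2 == s1 and not isinstance(o2, Literal):
                        new.add((o2, RDF.type, o1))
            if RuleId.RDFS5 in rules and p1 == RDFS.subPropertyOf:
                for s2, p2, o2 in snapshot:
                    if p2 == RDFS.subPropertyOf and s2 == o1:
                        new.add((s1, RDFS.subPropertyOf, o2))
            if RuleId.RDFS9 in rules and p1 == RDF.type:
                for s2, p2, o2 in snapshot:
                    if p2 == RDFS.subClassOf and s2 == o1:
                        new.add((s1, RDF.type, o2))
            if RuleId.RDFS11 in rules and p1 == RDFS.subClassOf:
                for s2, p2, o2 in snapshot:
                    if p2 == RDFS.subClassOf and s2 == o1:
                        new.add((s1, RDFS.subClassOf, o2))
            if RuleId.OWL_EQ_CLASS in rules and p1 == OWL.equivalentClass:
                new.add((o1, OWL.equivalentClass, s1))
                new.add((s1, RDFS.subClassOf, o1))
                new.add((o1, RDFS.subClassOf, s1))
            if RuleId.OWL_EQ_PROP in rules and p1 == OWL.equivalentProperty:
                new.add((o1, OWL.equivalentProperty, s1))
                new.add((s1, RDFS.subPropertyOf, o1))
                new.add((o1, RDFS.subPropertyOf, s1))
            if RuleId.OWL_SAMEAS in rules and p1 == OWL.sameAs:
                a, b = s1, o1
                new.add((b, OWL.sameAs, a))
                for s2, p2, o2 in snapshot:
                    if p2 == OWL.sameAs and s2 == b:
                        new.add((a, OWL.sameAs, o2))
                    # class positions
                    if p2 == RDF.type and o2 == a:
                        new.add((s2, RDF.type, b))
                    if p2 in (RDFS.subClassOf, OWL.equivalentClass):
                        if s2 == a:
                            new.add((b, p2, o2))
                        if o2 == a:
                            new.add((s2, p2, b))
                    if p2 in (RDFS.domain, RDFS.range):
                        if o2 == a:
                            new.add((s2, p2, b))
                        if s2 == a:
                            new.add((b, p2, o2))
                    # property positions
                    if p2 == a and isinstance(b, URIRef):
                        new.add((s2, b, o2))
                    if p2 in (RDFS.subPropertyOf, OWL.equivalentProperty):
                        if s2 == a:
                            new.add((b, p2, o2))
                        if o2 == a:
                            new.add((s2, p2, b))
        if new - triples:
            triples |= new
            changed = True
    return triples
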