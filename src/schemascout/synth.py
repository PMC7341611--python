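"""Synthetic RDF inputs: patient records, the hospital worked example, and
random graph/vocabulary instances for property-based testing.

The patient-records generator emulates a privacy-sensitive registry: personal
information (name, birthday, phone number, email) for a configurable number
of individuals, with half of the records encoded in the FoaF vocabulary and
half in Schema.org — the archetypal mixed-vocabulary dataset whose schema a
data provider would want to publish without publishing the records.  The
default field set is chosen for clarity; it makes no claim of matching any
particular published registry's field list.  Every value comes from embedded
word lists and a seeded generator: no network, no locale dependence,
bit-for-bit reproducible output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import FOAF, OWL, RDF, RDFS, XSD

__all__ = [
    "EX", "SNOMED", "SCHEMA",
    "FieldMapping", "GeneratorConfig", "DEFAULT_FIELDS",
    "generate_patient_records", "worked_example", "vocabulary_fragment",
    "random_instance",
]

EX = Namespace("http://example.org/")
SNOMED = Namespace("http://purl.bioontology.org/ontology/SNOMEDCT/")
SCHEMA = Namespace("http://schema.org/")

_FIRST_NAMES = [
    "Alice", "Bruno", "Clara", "Daan", "Emma", "Felix", "Greta", "Hugo",
    "Ines", "Jonas", "Katja", "Liam", "Mara", "Nils", "Olga", "Paul",
    "Rosa", "Sven", "Tessa", "Yusuf",
]
_LAST_NAMES = [
    "Bauer", "Claes", "Dekker", "Engel", "Fischer", "Garcia", "Hansen",
    "Iversen", "Jansen", "Keller", "Lange", "Meyer", "Novak", "Okafor",
    "Peters", "Richter", "Schulz", "Tanaka", "Vogel", "Weber",
]
_STREETS = ["Main Street", "Ahorn Way", "Sand Lane", "Schloss Road", "Ring Avenue"]


@dataclass(frozen=True)
class FieldMapping:
    """One personal-information field and its encoding in each vocabulary."""

    name: str
    foaf_property: URIRef
    schema_property: URIRef
    value_kind: str  # person name | date | phone | email | free text


DEFAULT_FIELDS: tuple[FieldMapping, ...] = (
    FieldMapping("name", FOAF.name, SCHEMA.name, "person name"),
    FieldMapping("birthday", FOAF.birthday, SCHEMA.birthDate, "date"),
    FieldMapping("phone", FOAF.phone, SCHEMA.telephone, "phone"),
    FieldMapping("email", FOAF.mbox, SCHEMA.email, "email"),
)


@dataclass
class GeneratorConfig:
    """Patient-records generator settings.

    ``n_individuals`` defaults to 10,000 records with an even FoaF /
    Schema.org split — the registry scale this generator is meant to
    emulate.  Identical configs produce identical graphs.
    """

    n_individuals: int = 10_000
    foaf_fraction: float = 0.5
    seed: int = 0
    fields: Sequence[FieldMapping] = DEFAULT_FIELDS
    typed_address_nodes: bool = False

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        if not 0.0 <= self.foaf_fraction <= 1.0:
            raise ValueError("foaf_fraction must lie in [0, 1]")


def _field_value(rng: random.Random, kind: str, i: int) -> Literal:
    if kind == "person name":
        return Literal(f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}")
    if kind == "date":
        y, m, d = rng.randint(1920, 2005), rng.randint(1, 12), rng.randint(1, 28)
        return Literal(f"{y:04d}-{m:02d}-{d:02d}", datatype=XSD.date)
    if kind == "phone":
        return Literal(f"+49-{rng.randint(100, 999)}-{rng.randint(1000000, 9999999)}")
    if kind == "email":
        return Literal(f"person{i}@example.org")
    return Literal(f"note {rng.randint(0, 10**6)}")


def generate_patient_records(config: GeneratorConfig | None = None) -> Graph:
    """Generate the synthetic patient-records dataset.

    ``floor(n * foaf_fraction)`` individuals are typed ``foaf:Person`` and
    described with FoaF properties; the rest are ``schema:Person`` with
    Schema.org properties.  Each individual carries one type triple plus one
    triple per field, so the total is exactly ``n * (1 + len(fields))`` —
    plus three address triples per individual when ``typed_address_nodes``
    adds the blank postal-address nodes (the only blank nodes the generator
    ever emits).
    """
    config = config or GeneratorConfig()
    rng = random.Random(config.seed)
    g = Graph()
    g.bind("foaf", FOAF)
    g.bind("schema", SCHEMA)
    g.bind("ex", EX)
    n_foaf = int(config.n_individuals * config.foaf_fraction)
    for i in range(config.n_individuals):
        person = EX[f"person/{i:05d}"]
        use_foaf = i < n_foaf
        g.add((person, RDF.type, FOAF.Person if use_foaf else SCHEMA.Person))
        for f in config.fields:
            prop = f.foaf_property if use_foaf else f.schema_property
            g.add((person, prop, _field_value(rng, f.value_kind, i)))
        if config.typed_address_nodes:
            addr = BNode(f"addr{i:05d}")
            g.add((person, SCHEMA.address, addr))
            g.add((addr, RDF.type, SCHEMA.PostalAddress))
            g.add((addr, SCHEMA.streetAddress,
                   Literal(f"{rng.randint(1, 200)} {rng.choice(_STREETS)}")))
    return g


def worked_example() -> tuple[Graph, Graph]:
    """The two-triple hospital example and its five-triple vocabulary.

    Data: john is a Patient treated at the university hospital.  Vocabulary:
    Patient specializes Person; treatedAt runs from Patient to Hospital; the
    Person and Hospital classes each have a SNOMED CT equivalent.  Small
    enough to verify every extraction and entailment result by hand.
    """
    data = Graph()
    data.bind("ex", EX)
    data.add((EX.john, RDF.type, EX.Patient))
    data.add((EX.john, EX.treatedAt, EX.uh))

    vocab = Graph()
    vocab.bind("ex", EX)
    vocab.bind("snomed", SNOMED)
    vocab.add((EX.Patient, RDFS.subClassOf, EX.Person))
    vocab.add((EX.treatedAt, RDFS.domain, EX.Patient))
    vocab.add((EX.treatedAt, RDFS.range, EX.Hospital))
    vocab.add((EX.Person, OWL.equivalentClass, SNOMED.Person))
    vocab.add((EX.Hospital, OWL.equivalentClass, SNOMED.Hospital))
    return data, vocab


def vocabulary_fragment() -> Graph:
    """A small *synthetic* FoaF/Schema.org vocabulary fragment.

    Hand-written stand-in covering just the terms the patient-records
    generator uses, with the class hierarchy, domains/ranges and
    cross-vocabulary equivalences a terminology service would serve.  It is
    not the authoritative FoaF or Schema.org file and makes no claim of
    matching their content.
    """
    g = Graph()
    g.bind("foaf", FOAF)
    g.bind("schema", SCHEMA)
    for cls, sup in [(FOAF.Person, FOAF.Agent), (SCHEMA.Person, SCHEMA.Thing),
                     (SCHEMA.PostalAddress, SCHEMA.Thing)]:
        g.add((cls, RDF.type, RDFS.Class))
        g.add((cls, RDFS.subClassOf, sup))
    g.add((FOAF.Agent, RDF.type, RDFS.Class))
    g.add((SCHEMA.Thing, RDF.type, RDFS.Class))
    g.add((FOAF.Person, OWL.equivalentClass, SCHEMA.Person))
    for f in DEFAULT_FIELDS:
        for prop, dom in [(f.foaf_property, FOAF.Person),
                          (f.schema_property, SCHEMA.Person)]:
            g.add((prop, RDF.type, RDF.Property))
            g.add((prop, RDFS.domain, dom))
        g.add((f.foaf_property, OWL.equivalentProperty, f.schema_property))
    g.add((SCHEMA.address, RDF.type, RDF.Property))
    g.add((SCHEMA.address, RDFS.domain, SCHEMA.Person))
    g.add((SCHEMA.address, RDFS.range, SCHEMA.PostalAddress))
    return g


def random_instance(seed: int, n_classes: int = 6, n_properties: int = 5,
                    n_individuals: int = 8, n_assertions: int = 12
                    ) -> tuple[Graph, Graph]:
    """A random (data, vocabulary) pair for property-based testing.

    The vocabulary is a random subclass/subproperty hierarchy (mostly a DAG,
    with occasional back edges to exercise cycle handling) sprinkled with
    equivalence and sameAs links and domain/range declarations.  The data
    types random individuals and asserts random property links between them
    (objects are individuals or literals).  Deterministic under *seed*;
    predicates are always IRIs by construction.
    """
    rng = random.Random(seed)
    R = Namespace(EX["rand/"])
    classes = [R[f"C{i}"] for i in range(n_classes)]
    props = [R[f"p{i}"] for i in range(n_properties)]
    people = [R[f"x{i}"] for i in range(n_individuals)]

    vocab = Graph()
    for i, c in enumerate(classes):
        if i and rng.random() < 0.6:
            vocab.add((c, RDFS.subClassOf, classes[rng.randrange(i)]))
        if i and rng.random() < 0.1:  # back edge: cycle
            vocab.add((classes[rng.randrange(i)], RDFS.subClassOf, c))
        if rng.random() < 0.2:
            vocab.add((c, OWL.equivalentClass, rng.choice(classes)))
        if rng.random() < 0.1:
            vocab.add((c, OWL.sameAs, rng.choice(classes)))
    for i, p in enumerate(props):
        if i and rng.random() < 0.5:
            vocab.add((p, RDFS.subPropertyOf, props[rng.randrange(i)]))
        if rng.random() < 0.15:
            vocab.add((p, OWL.equivalentProperty, rng.choice(props)))
        if rng.random() < 0.1:
            vocab.add((p, OWL.sameAs, rng.choice(props)))
        if classes and rng.random() < 0.4:
            vocab.add((p, RDFS.domain, rng.choice(classes)))
        if classes and rng.random() < 0.3:
            vocab.add((p, RDFS.range, rng.choice(classes)))

    data = Graph()
    for x in people:
        if classes and rng.random() < 0.8:
            for _ in range(rng.randint(1, 2)):
                data.add((x, RDF.type, rng.choice(classes)))
    for _ in range(n_assertions):
        if not props or not people:
            break
        s = rng.choice(people)
        p = rng.choice(props)
        o = (Literal(f"v{rng.randrange(100)}") if rng.random() < 0.3
             else rng.choice(people))
        data.add((s, p, o))
    return data, vocab
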