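# schemascout

**Instantiated RDFS/OWL schema extraction from private RDF datasets, with
schema-aided SPARQL query expansion.**

## The problem

Federated health-data architectures (Personal Health Train and kin) bring the
analysis to the data: a client writes a SPARQL selection query that is
evaluated inside the data provider's private network, and only aggregate
results leave. But you cannot write a sensible query against a dataset you
are not allowed to look at. What the client actually needs is not the data —
it is the *schema of the data as used*: which classes are instantiated, which
properties occur, and how they relate through `rdfs:subClassOf`,
`rdfs:domain`/`rdfs:range` and the OWL equivalence predicates.

`schemascout` extracts exactly that: a concise RDFS/OWL schema containing
**only the instantiated subset** of all vocabulary knowledge — every IRI used
in predicate position becomes an `rdf:Property`, every IRI object of an
`rdf:type` triple an `rdfs:Class`, with usage-derived domain/range statements
and the terms' one-hop descriptions. Because schema subjects are only class
and property terms (never individuals, never blank nodes), the result can be
published without exposing the records themselves.

Three inference levels control how much implied knowledge the schema folds
in:

| mode        | uses                                            |
|-------------|-------------------------------------------------|
| `direct`    | only the data itself                            |
| `local`     | + local vocabulary files (generalizations, equivalences, domain/range-implied classes, via a bounded rule set: rdfs2, rdfs3, rdfs5, rdfs7, rdfs9, rdfs11 and `owl:equivalentClass`/`equivalentProperty`/`sameAs`) |
| `federated` | + remote terminology services, consulted in every closure round |

(`entailed` additionally covers the idealized case of an
entailment-supporting endpoint.) The extracted schemas form a chain:
`direct ⊆ local ⊆ federated` whenever the terminology services subsume the
local vocabularies.

On top of the schema, the package builds **expanded SPARQL queries**: a query
for all instances of a class is unfolded into an explicit UNION over the
class, its subclasses and equivalents, and the properties whose declared
domain/range provide indirect type evidence — so the private endpoint needs
no entailment support at all. It also computes the seven **HCLS core
statistics** (triples, typed entities, subjects, properties, objects,
classes, literals) for datasets, vocabularies and schemas, and ships a
seeded **synthetic patient-records generator** (10,000 individuals by
default, half FoaF, half Schema.org) for experimentation and testing.

## Worked example

The package ships a two-triple hospital example (`schemascout fixture`):
john is a `ex:Patient` treated at `ex:uh`, and a five-triple vocabulary
relating Patient, Person, Hospital and their SNOMED CT equivalents.

```sh
schemascout fixture --out-dir .
schemascout extract --input example-data.ttl --vocab example-vocab.ttl \
    --mode local --output schema.ttl
# wrote 13 schema triples to schema.ttl
schemascout stats --input schema.ttl --report tsv
```

```text
n_triples  n_typed_entities  n_subjects  n_properties  n_objects  n_classes  n_literals
13         7                 7           5             7          2          0
```

The 13-triple schema declares five classes (`ex:Patient`, `ex:Person`,
`ex:Hospital` and both SNOMED equivalents — everything local inference can
reach from the two data triples) and the `ex:treatedAt` property with its
declared domain and range. Direct extraction of the same data yields just
5 triples (`ex:Patient`, `ex:treatedAt`, `rdf:type` and the usage-derived
domain). A client can now ask for "all persons" without endpoint entailment:

```sh
schemascout expand --schema schema.ttl --class http://example.org/Person
```

```sparql
SELECT DISTINCT ?x WHERE {
  { ?x <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://example.org/Patient> }
  UNION
  { ?x <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://example.org/Person> }
  UNION
  { ?x <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://purl.bioontology.org/ontology/SNOMEDCT/Person> }
  UNION
  { ?x <http://example.org/treatedAt> ?o }
  UNION
  { ?x <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> ?o }
}
```

Evaluated over the raw two-triple dataset this returns exactly `ex:john` —
the same answer entailment-supported type querying would give. (The last
two branches are domain evidence from the usage-derived schema; pass
`--no-evidence` to drop them.)

The same workflow from Python:

```python
from schemascout import (LocalSource, ExtractionConfig, ExtractionMode,
                         extract_local, worked_example)

data, vocab = worked_example()
schema = extract_local(LocalSource(graph=data), ExtractionConfig(
    mode=ExtractionMode.LOCAL, vocabularies=[LocalSource(graph=vocab)]))
print(len(schema.graph), sorted(schema.class_terms))   # 13 classes as above
```

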