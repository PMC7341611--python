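# Methods

## The extraction model

An RDF dataset instantiates a schema implicitly: every IRI in predicate
position is being used as an `rdf:Property`, and every IRI in object
position of an `rdf:type` triple as an `rdfs:Class`. `schemascout` takes
this *instantiated* subset — not the full closure of every vocabulary the
dataset touches — as the unit of publication, on the premise that a query
author needs exactly the terms that can actually match data, and that
publishing more both dilutes schema introspection and widens the privacy
surface.

A published `SchemaGraph` contains, for each discovered term:

* a type declaration (`rdf:Property` / `rdfs:Class`);
* usage-derived `rdfs:domain` / `rdfs:range` statements: one per distinct
  (property, observed subject-type) and (property, observed object-type)
  pair. Untyped subjects/objects contribute nothing; literal objects never
  contribute a range. Multiple observed types yield multiple statements —
  under strict RDFS semantics these would read conjunctively, which is
  wrong, but the representation is deliberately kept close to the data
  because RDFS domains/ranges are what schema-introspection tools actually
  consume. The `domain_range_dialect="schema.org"` option emits
  `schema:domainIncludes`/`rangeIncludes` instead, which carries the
  correct disjunctive reading at the cost of tool support.
* the term's one-hop description (all triples with the term as subject)
  from the consulted sources. Description is deliberately not recursive:
  complex axioms (OWL restrictions, disjointness) are out of scope for
  query authoring.

The schema is a query-authoring artifact, **not** an entailment substrate:
extraction never feeds its own output back into materialization, precisely
because of the conjunctive domain/range caveat above.

### Privacy contract

Schema subjects are restricted to class/property terms; blank-node subjects
are always dropped (non-negotiable, not a configuration switch), because
blank nodes cannot be referenced across sources and may encode record
structure. Consequently no individual of the private data can appear in
subject position of the published schema. Individuals *can* appear in
object position of a describing triple of a schema term (e.g. a vocabulary
annotation pointing at an example instance); the extractor only emits such
triples when their subject is a schema term, which in practice means they
come from vocabulary descriptions rather than the private records.

### Inference levels

* **direct** — seeds only; works with zero vocabulary knowledge.
* **entailed** — the idealized case: the store already materializes
  entailment, so seed discovery and description over the materialized
  graph suffice. Locally this is emulated by materializing
  data ∪ vocabularies first. A remote endpoint that does not advertise
  entailment support degrades to direct semantics with a warning rather
  than silently under-reporting.
* **local** — seeds are closed over the data plus local vocabulary files:
  property seeds ascend `rdfs:subPropertyOf`, class seeds ascend
  `rdfs:subClassOf`, both interleaved with equivalence steps
  (`owl:equivalentClass` / `owl:equivalentProperty` / `owl:sameAs`, all
  treated as symmetric); classes appearing as declared `rdfs:domain` /
  `rdfs:range` of any closed property are added and re-closed to a fixed
  point (this is the rdfs2/rdfs3 justification for their class-ness).
* **federated** — identical closure, but every round also consults remote
  terminology endpoints, so equivalences across vocabularies unknown
  locally are resolved. Lookups are batched (VALUES blocks, default 100
  IRIs) because per-term federated queries dominate runtime in practice. An
  endpoint failure (after one retry) aborts the extraction: a silently
  partial schema would break the completeness guarantees downstream tools
  rely on.

With superset terminology services the three published levels form a chain,
`triples(direct) ⊆ triples(local) ⊆ triples(federated)`, which the test
suite checks on randomized instances.

## The entailment engine

`materialize_entailment` computes the fixed point of a deliberately bounded
rule set: rdfs2/rdfs3 (domain/range typing), rdfs5/rdfs7
(sub-property transitivity and inheritance), rdfs9/rdfs11 (sub-class
instance propagation and transitivity), plus the three OWL equivalence
predicates. `owl:equivalentClass`/`equivalentProperty` expand to symmetric
assertions plus mutual sub-class/sub-property edges. `owl:sameAs` — an
individual-level predicate that is routinely used between vocabulary terms —
is closed symmetrically and transitively and substituted **only in
class/property positions** (type objects, hierarchy edges, domain/range
positions, predicate position); general individual-level smushing is
neither needed for schema extraction nor affordable.

Properties of the engine (all under test): monotone in the input graph,
idempotent, monotone in the rule set, order-independent, cycle-safe (the
term universe is finite and the loop only adds triples). The test suite
checks it against an independent, deliberately naive oracle that rescans
all triple pairs per rule until exhaustion.

## Query expansion

A class query `?x a C` under entailment returns instances of `C`'s
subclasses, equivalents, and subjects/objects of properties whose declared
domain/range is (a specialization of) `C`. Expansion reconstructs this over
the raw data: it *descends* the schema's hierarchies from the target
(instance retrieval needs specializations, the mirror image of the upward
closure used during extraction), then collects domain/range evidence
properties, then closes those property sets downward as well — a design
choice this package makes because an assertion via a sub-property (or
equivalent) of a domain-bearing property carries the same type evidence;
without that step, expansion would miss instances entailment finds.
Range-evidence branches filter out literal bindings, which could never be
instances. Branches are rendered in deterministic order with full IRIs.

The central correctness property: for schemas whose domain/range statements
are the *declared* ones (`usage_domain_range=False`), the expanded query
over the raw data returns exactly the bindings of the plain type query over
the materialized graph. With usage-derived statements (the default), the
expanded result is a superset: an observed domain types *all* subjects of
the property, which is heuristic evidence, not entailment — useful for
recall-oriented data selection, and switchable off per query
(`include_evidence=False`). Both behaviors are under test.

## HCLS statistics

The seven core counts are computed per graph: unique triples, typed
entities, subjects, properties, objects, classes, literals. Two readings
the profile leaves open are pinned here: *typed entities* are distinct
subjects with at least one `rdf:type` triple, and *objects* excludes
literals (which have their own metric). Literal identity follows rdflib's
node identity — value-space for recognized XSD datatypes, lexical
form/datatype/tag otherwise — which is deterministic, the property the
counts need. The overhead report compares an extracted schema with an
authoritative vocabulary: term-set differences in both directions and the
schema:vocabulary triple ratio (percentages rendered to two decimals).

## Synthetic data

`generate_patient_records` emulates a privacy-sensitive person registry:
`n` individuals (default 10,000), a FoaF/Schema.org vocabulary split
(default 0.5 — the mixed-vocabulary situation schema extraction exists
for), and per individual one type triple plus one literal-valued triple per
field. The default fields (name, birthday, phone, email) are a clarity
choice; total triples are exactly `n·(1+|fields|)`. The optional
`typed_address_nodes` flag attaches a blank postal-address node (three
extra triples per individual), introducing a third class and the only blank
nodes the generator ever emits — used to exercise the blank-node filter.
Values come from embedded word lists through `random.Random(seed)`:
identical configs are bit-for-bit reproducible after canonical
serialization, with no locale or network dependence.

What the generator does *not* emulate: real registries' field inventories,
value distributions, data-entry noise, or partially missing fields — every
synthetic individual is completely and uniformly described. Passing tests
therefore demonstrate the extraction/expansion machinery's correctness on
mixed-vocabulary person data, not robustness to messy real-world encodings,
and the synthetic counts are not comparable to any published registry's.
The shipped FoaF/Schema.org *fragment* (`vocabulary_fragment`) is likewise
a synthetic stand-in covering only the generator's terms.

`random_instance` drives the property-based tests: random subclass /
sub-property hierarchies (mostly DAGs with occasional deliberate cycles),
equivalence and sameAs links, domain/range declarations, and random typed
individuals with property assertions. Instances are small (tens of
triples) by design — the invariants under test are size-independent, and
small instances make the naive entailment oracle affordable.

## Numerical and procedural choices

* Closure iteration is a visited-set fixed point; `max_closure_rounds`
  (default 30) caps only the generalization-ascent rounds and warns with
  the unexpanded frontier when hit — relevant only for pathological or
  remote-backed hierarchies.
* Blank nodes are file-scoped: `graph_union` relabels per input, so equal
  labels in different files never merge.
* Remote queries are retried once, then fail loudly. Remote sources are
  query-only; this package never issues SPARQL UPDATE against a foreign
  endpoint.
* All serialization for publication sorts triples first, so repeated runs
  are byte-identical regardless of hash randomization; extraction
  timestamps go into a sidecar JSON, never into the published schema.
* The acceptance script sizes its checks to desk scale (100 subset-chain
  instances, 200 oracle graphs of ≤ 50 triples, 50 expansion instances,
  a 10,000-individual synthetic registry) — small enough to verify in
  seconds, large enough that the randomized properties are meaningfully
  exercised.

## Known limitations

* Only the bounded rule subset is interpreted; OWL disjointness,
  restrictions and property chains never enter the schema.
* Usage-derived domains/ranges are descriptive, not prescriptive; consumers
  wanting sound entailment must use the declared-only configuration.
* Named-graph structure is flattened on parse; provenance per graph is not
  preserved.
* The published reference counts for external corpora (patient-records
  dump, Bio2RDF release 3) can only be checked when those files are
  supplied; the synthetic generator intentionally does not mimic them.
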