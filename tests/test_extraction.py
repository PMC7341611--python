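"""The four extraction strategies: worked-example exactness, subset chain,
completeness, privacy, determinism."""

import pytest
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from schemascout import (ExtractionConfig, ExtractionMode, LocalSource,
                         extract, extract_direct, extract_entailed,
                         extract_federated, extract_local, graph_union,
                         random_instance)
from schemascout.core import DataSource
from schemascout.synth import EX, SNOMED


def _sources(seed):
    data, vocab = random_instance(seed)
    return data, vocab, LocalSource(graph=data), LocalSource(graph=vocab)


def _individual_only_terms(data: Graph) -> set:
    """Terms occurring in the data only as individuals: never in predicate
    position and never as an rdf:type object."""
    schema_positions = set(data.predicates()) | set(data.objects(None, RDF.type))
    individuals = set()
    for s, p, o in data:
        if s not in schema_positions:
            individuals.add(s)
        if p != RDF.type and not isinstance(o, Literal) and o not in schema_positions:
            individuals.add(o)
    return individuals


class TestDirect:
    def test_worked_example_exact_five_triples(self, example_data):
        schema = extract_direct(LocalSource(graph=example_data))
        expected = {
            (EX.treatedAt, RDF.type, RDF.Property),
            (RDF.type, RDF.type, RDF.Property),
            (EX.Patient, RDF.type, RDFS.Class),
            (EX.treatedAt, RDFS.domain, EX.Patient),
            (RDF.type, RDFS.domain, EX.Patient),
        }
        assert set(schema.graph) == expected
        assert schema.property_terms == {EX.treatedAt, RDF.type}
        assert schema.class_terms == {EX.Patient}

    def test_empty_dataset_gives_empty_schema(self):
        schema = extract_direct(LocalSource(graph=Graph()))
        assert len(schema.graph) == 0
        assert schema.property_terms == set() and schema.class_terms == set()

    def test_literal_objects_never_generate_range(self):
        g = Graph()
        g.add((EX.a, RDF.type, EX.T))
        g.add((EX.a, EX.p, Literal("v")))
        schema = extract_direct(LocalSource(graph=g))
        assert not list(schema.graph.triples((None, RDFS.range, None)))

    def test_describing_triples_of_schema_terms_included(self):
        g = Graph()
        g.add((EX.a, RDF.type, EX.T))
        g.add((EX.T, RDFS.label, Literal("a type")))  # annotation on a class
        schema = extract_direct(LocalSource(graph=g))
        assert (EX.T, RDFS.label, Literal("a type")) in schema.graph

    def test_exclude_builtins_flag(self, example_data):
        cfg = ExtractionConfig(include_builtin_terms=False)
        schema = extract_direct(LocalSource(graph=example_data), cfg)
        assert RDF.type not in schema.property_terms
        assert schema.property_terms == {EX.treatedAt}

    def test_schema_org_dialect(self, example_data):
        cfg = ExtractionConfig(domain_range_dialect="schema.org")
        schema = extract_direct(LocalSource(graph=example_data), cfg)
        inc = URIRef("http://schema.org/domainIncludes")
        assert (EX.treatedAt, inc, EX.Patient) in schema.graph
        assert not list(schema.graph.triples((None, RDFS.domain, None)))


class TestEntailed:
    def test_worked_example_subjects(self, example_data, example_vocab):
        cfg = ExtractionConfig(mode=ExtractionMode.ENTAILED,
                               vocabularies=[LocalSource(graph=example_vocab)])
        schema = extract_entailed(LocalSource(graph=example_data), cfg)
        for term in (EX.Patient, EX.Person, EX.Hospital, SNOMED.Person,
                     SNOMED.Hospital, EX.treatedAt, RDF.type, RDFS.subClassOf,
                     RDFS.domain, RDFS.range, OWL.equivalentClass):
            assert term in schema.subjects, term

    def test_empty_graph(self):
        assert len(extract_entailed(LocalSource(graph=Graph())).graph) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_direct_subjects_subset_of_entailed(self, seed):
        data, vocab, ds, vs = _sources(seed)
        cfg = ExtractionConfig(mode=ExtractionMode.ENTAILED, vocabularies=[vs])
        assert extract_direct(ds).subjects <= extract_entailed(ds, cfg).subjects

    def test_remote_without_entailment_warns_and_degrades(self, example_data,
                                                          sparql_endpoint):
        remote = sparql_endpoint(example_data)
        with pytest.warns(UserWarning, match="entailment"):
            schema = extract_entailed(remote)
        direct = extract_direct(LocalSource(graph=example_data))
        assert set(schema.graph) == set(direct.graph)
        assert schema.mode is ExtractionMode.ENTAILED


class TestLocal:
    def test_worked_example_classes_and_descriptions(self, example_data, example_vocab):
        cfg = ExtractionConfig(mode=ExtractionMode.LOCAL,
                               vocabularies=[LocalSource(graph=example_vocab)])
        schema = extract_local(LocalSource(graph=example_data), cfg)
        assert schema.class_terms == {EX.Patient, EX.Person, EX.Hospital,
                                      SNOMED.Person, SNOMED.Hospital}
        assert (EX.Patient, RDFS.subClassOf, EX.Person) in schema.graph
        assert (EX.treatedAt, RDFS.domain, EX.Patient) in schema.graph
        assert (EX.treatedAt, RDFS.range, EX.Hospital) in schema.graph
        assert (EX.Person, OWL.equivalentClass, SNOMED.Person) in schema.graph
        assert (EX.Hospital, OWL.equivalentClass, SNOMED.Hospital) in schema.graph

    def test_no_vocabularies_equals_direct(self, example_data):
        ds = LocalSource(graph=example_data)
        local = extract_local(ds, ExtractionConfig(mode=ExtractionMode.LOCAL))
        direct = extract_direct(ds)
        assert set(local.graph) == set(direct.graph)

    def test_missing_vocabulary_file_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope"):
            LocalSource(paths=[tmp_path / "nope.ttl"])


class _BlankDescriber(DataSource):
    """Stub source whose descriptions leak a blank-node subject."""

    def __init__(self, inner):
        self.inner = inner

    def predicate_iris(self):
        return self.inner.predicate_iris()

    def type_objects(self):
        return self.inner.type_objects()

    def expand_links(self, terms, predicates):
        return self.inner.expand_links(terms, predicates)

    def describe(self, terms):
        return self.inner.describe(terms) | {(BNode("leak"), RDFS.label, Literal("x"))}

    def usage_domain_range(self):
        return self.inner.usage_domain_range()


class TestFederated:
    def test_requires_endpoint(self, example_data):
        cfg = ExtractionConfig(mode=ExtractionMode.FEDERATED)
        with pytest.raises(ValueError, match="terminology endpoint"):
            extract_federated(LocalSource(graph=example_data), cfg)

    def test_stub_equal_to_local(self, example_data, example_vocab):
        ds = LocalSource(graph=example_data)
        vs = LocalSource(graph=example_vocab)
        local = extract_local(ds, ExtractionConfig(mode=ExtractionMode.LOCAL,
                                                   vocabularies=[vs]))
        fed = extract_federated(ds, ExtractionConfig(
            mode=ExtractionMode.FEDERATED, vocabularies=[vs],
            terminology_endpoints=[LocalSource(graph=example_vocab)]))
        assert set(fed.graph) == set(local.graph)

    def test_extra_remote_equivalence_extends_classes(self, example_data, example_vocab):
        extra = Graph()
        for t in example_vocab:
            extra.add(t)
        human = URIRef("http://example.org/extra/Human")
        extra.add((SNOMED.Person, OWL.equivalentClass, human))
        fed = extract_federated(LocalSource(graph=example_data), ExtractionConfig(
            mode=ExtractionMode.FEDERATED,
            vocabularies=[LocalSource(graph=example_vocab)],
            terminology_endpoints=[LocalSource(graph=extra)]))
        assert human in fed.class_terms

    def test_blank_node_subjects_dropped(self, example_data, example_vocab):
        stub = _BlankDescriber(LocalSource(graph=example_vocab))
        fed = extract_federated(LocalSource(graph=example_data), ExtractionConfig(
            mode=ExtractionMode.FEDERATED, terminology_endpoints=[stub]))
        for s in fed.graph.subjects():
            assert not isinstance(s, BNode)


class TestInvariantsOnRandomInstances:
    @pytest.mark.parametrize("seed", range(20))
    def test_subset_chain(self, seed):
        data, vocab, ds, vs = _sources(seed)
        direct = extract_direct(ds)
        local = extract_local(ds, ExtractionConfig(mode=ExtractionMode.LOCAL,
                                                   vocabularies=[vs]))
        fed = extract_federated(ds, ExtractionConfig(
            mode=ExtractionMode.FEDERATED, vocabularies=[vs],
            terminology_endpoints=[LocalSource(graph=vocab)]))
        assert set(direct.graph) <= set(local.graph) <= set(fed.graph)

    @pytest.mark.parametrize("seed", range(10))
    def test_completeness_and_declarations(self, seed):
        data, vocab, ds, vs = _sources(seed)
        data_preds = {p for p in data.predicates() if isinstance(p, URIRef)}
        data_classes = {c for c in data.objects(None, RDF.type)
                        if isinstance(c, URIRef)}
        for schema in (extract_direct(ds),
                       extract_local(ds, ExtractionConfig(
                           mode=ExtractionMode.LOCAL, vocabularies=[vs]))):
            assert data_preds <= schema.property_terms
            assert data_classes <= schema.class_terms
            for p in schema.property_terms:
                assert (p, RDF.type, RDF.Property) in schema.graph
            for c in schema.class_terms:
                assert (c, RDF.type, RDFS.Class) in schema.graph

    @pytest.mark.parametrize("seed", range(10))
    def test_privacy_invariant(self, seed):
        data, vocab, ds, vs = _sources(seed)
        leakable = _individual_only_terms(data)
        for schema in (extract_direct(ds),
                       extract_local(ds, ExtractionConfig(
                           mode=ExtractionMode.LOCAL, vocabularies=[vs]))):
            subjects = schema.subjects
            assert not subjects & leakable
            for s in subjects:
                assert not isinstance(s, BNode)
                assert s in schema.property_terms | schema.class_terms

    @pytest.mark.parametrize("seed", range(5))
    def test_determinism(self, seed):
        data, vocab, ds, vs = _sources(seed)
        cfg = ExtractionConfig(mode=ExtractionMode.LOCAL, vocabularies=[vs])
        a = extract(ds, cfg)
        b = extract(ds, cfg)
        assert set(a.graph) == set(b.graph)
        assert a.property_terms == b.property_terms
        assert a.class_terms == b.class_terms
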