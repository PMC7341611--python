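"""HCLS core dataset statistics and schema-vs-vocabulary overhead reports.

Implements the seven core counts of the W3C Health Care and Life Sciences
dataset-description profile (metrics 6.6.1.1–6.6.1.7): unique triples, typed
entities, subjects, properties, objects, classes and literals.  Two readings
the profile leaves ambiguous are pinned down here and isolated behind this
module so they can be swapped:

* *typed entities* are distinct subjects carrying at least one ``rdf:type``
  triple;
* *objects* are distinct non-literal object terms — literals have their own
  metric and are counted by term identity (lexical form + datatype + tag).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from .extraction import SchemaGraph

__all__ = ["HclsStats", "OverheadReport", "compute_stats", "compare_with_vocabulary"]


@dataclass(frozen=True)
class HclsStats:
    """The seven HCLS core counts of one graph."""

    n_triples: int
    n_typed_entities: int
    n_subjects: int
    n_properties: int
    n_objects: int
    n_classes: int
    n_literals: int

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def as_tsv_row(self) -> str:
        return "\t".join(str(v) for v in asdict(self).values())

    TSV_HEADER = ("n_triples\tn_typed_entities\tn_subjects\tn_properties\t"
                  "n_objects\tn_classes\tn_literals")


def compute_stats(g: Graph) -> HclsStats:
    """Compute the seven HCLS core counts of *g*.

    Invariant under triple reordering and duplicate insertion (the graph is
    a set); all counts are zero for the empty graph.
    """
    subjects = set()
    typed = set()
    predicates = set()
    objects = set()
    classes = set()
    literals = set()
    for s, p, o in g:
        subjects.add(s)
        predicates.add(p)
        if isinstance(o, Literal):
            literals.add(o)
        else:
            objects.add(o)
        if p == RDF.type:
            typed.add(s)
            if isinstance(o, URIRef):
                classes.add(o)
    return HclsStats(
        n_triples=len(g),
        n_typed_entities=len(typed),
        n_subjects=len(subjects),
        n_properties=len(predicates),
        n_objects=len(objects),
        n_classes=len(classes),
        n_literals=len(literals),
    )


@dataclass
class OverheadReport:
    """Size and term-coverage comparison of an extracted schema against an
    authoritative vocabulary.

    ``triple_ratio`` is schema triples over vocabulary triples (> 1 means the
    schema carries terms the authoritative vocabulary does not define, e.g.
    because the dataset mixes in further vocabularies); ``None`` when the
    vocabulary is empty.
    """

    schema_stats: HclsStats
    vocab_stats: HclsStats
    triple_ratio: float | None
    extra_terms: set[URIRef]
    missing_terms: set[URIRef]

    @property
    def overhead_percent(self) -> float | None:
        """Percentage of schema triples in excess of the vocabulary, rendered
        to two decimals (``None`` for an empty vocabulary)."""
        if self.triple_ratio is None:
            return None
        return round((self.triple_ratio - 1.0) * 100.0, 2)

    def as_dict(self) -> dict:
        return {
            "schema_stats": self.schema_stats.as_dict(),
            "vocab_stats": self.vocab_stats.as_dict(),
            "triple_ratio": self.triple_ratio,
            "overhead_percent": self.overhead_percent,
            "extra_terms": sorted(str(t) for t in self.extra_terms),
            "missing_terms": sorted(str(t) for t in self.missing_terms),
        }

    def as_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def compare_with_vocabulary(schema: SchemaGraph, vocab: Graph) -> OverheadReport:
    """Compare an extracted schema with an authoritative vocabulary graph.

    ``extra_terms`` are schema terms that the vocabulary never defines (does
    not use in subject position); ``missing_terms`` are vocabulary subjects
    not present in the schema — empty whenever every vocabulary term is
    actually instantiated in the data.
    """
    schema_stats = compute_stats(schema.graph)
    vocab_stats = compute_stats(vocab)
    vocab_subjects = {s for s in vocab.subjects() if isinstance(s, URIRef)}
    schema_terms = set(schema.property_terms) | set(schema.class_terms)
    if vocab_stats.n_triples == 0:
        warnings.warn("vocabulary graph is empty; triple ratio undefined")
        ratio = None
    else:
        ratio = schema_stats.n_triples / vocab_stats.n_triples
    return OverheadReport(
        schema_stats=schema_stats,
        vocab_stats=vocab_stats,
        triple_ratio=ratio,
        extra_terms=schema_terms - vocab_subjects,
        missing_terms=vocab_subjects - schema_terms,
    )
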