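"""Shared fixtures: small synthetic knowledge graphs and concept builders."""

from __future__ import annotations

import pytest
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from ontomine import (
    KnowledgeGraph,
    Lexicon,
    LexiconEntry,
    generate_fixture_corpus,
    generate_fixture_kb,
)
from ontomine.discovery import DiscoveredConcept
from ontomine.enrichment import enrich

EX = Namespace("http://example.org/kb/")


@pytest.fixture(scope="session")
def standard_fixture():
    """A mid-size noise-free fixture shared by read-only tests."""
    return generate_fixture_kb(
        n_concepts=20, hierarchy_depth=3, cross_edge_rate=0.05,
        ambiguity_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def ambiguous_fixture():
    return generate_fixture_kb(
        n_concepts=20, hierarchy_depth=2, cross_edge_rate=0.05,
        ambiguity_rate=0.3, seed=23,
    )


def make_kb(triples) -> KnowledgeGraph:
    g = Graph()
    for t in triples:
        g.add(t)
    return KnowledgeGraph(g)


def concept_node(graph: Graph, iri: URIRef, label: str,
                 definition: str | None = None,
                 alt: str | None = None) -> None:
    graph.add((iri, RDF.type, OWL.Class))
    graph.add((iri, RDFS.label, Literal(label)))
    graph.add((iri, SKOS.prefLabel, Literal(label)))
    if alt:
        graph.add((iri, SKOS.altLabel, Literal(alt)))
    if definition:
        graph.add((iri, SKOS.definition, Literal(definition)))


def enriched(kb: KnowledgeGraph, surface: str, iris, lexicon=None, lam=3):
    lexicon = lexicon if lexicon is not None else Lexicon()
    concept = DiscoveredConcept(
        surface=surface, span=(0, 0, len(surface.split())), iris=tuple(iris)
    )
    return enrich(concept, kb, lexicon, lam)
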