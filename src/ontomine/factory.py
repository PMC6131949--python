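"""Ontology factory: encode enriched concepts and relation candidates as a
formal OWL/SKOS ontology and serialize it to Turtle or RDF/XML.

The encoding follows a fixed mapping: each concept becomes an ``owl:Class``
whose IRI is its top-ranked URI; its other ranked URIs become
``owl:sameAs``; preferred label, synonyms, definitions and scheme become
``skos:prefLabel`` / ``skos:altLabel`` / ``skos:definition`` /
``skos:inScheme`` annotations; synonyms that resolve to class-typed graph
nodes additionally yield ``owl:equivalentClass``; the is-a hierarchy and
taxonomic candidates yield ``rdfs:subClassOf``; semantic types yield
``rdf:type`` assertions; non-taxonomic candidates become object-property
assertions under their candidate predicate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from .enrichment import EnrichedConcept
from .kb import KnowledgeGraph
from .triples import TripleCandidate, hierarchy_pair, split_candidates

__all__ = [
    "Axiom",
    "OntologyModel",
    "build_ontology",
    "to_graph",
    "serialize",
    "load_model_graph",
    "subclass_closure",
]

logger = logging.getLogger(__name__)

DEFAULT_BASE_IRI = "urn:ontomine:"

_ANNOTATION_PROPS = {
    "prefLabel": SKOS.prefLabel,
    "altLabel": SKOS.altLabel,
    "definition": SKOS.definition,
    "inScheme": SKOS.inScheme,
}


@dataclass(frozen=True)
class Axiom:
    """A typed axiom; ``predicate`` is only set for kind='property'."""

    kind: str  # subClassOf | equivalentClass | sameAs | type | property
    subject: URIRef
    object: URIRef
    predicate: URIRef | None = None


@dataclass
class OntologyModel:
    base_iri: str = DEFAULT_BASE_IRI
    #: class IRI -> source concept surface
    classes: dict[URIRef, str] = field(default_factory=dict)
    axioms: set[Axiom] = field(default_factory=set)
    #: (IRI, annotation property name, literal or IRI value)
    annotations: set[tuple[URIRef, str, object]] = field(default_factory=set)


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text.strip()).strip("_")


def build_ontology(
    enriched: list[EnrichedConcept],
    candidates: list[TripleCandidate],
    graph: KnowledgeGraph | None = None,
    base_iri: str = DEFAULT_BASE_IRI,
) -> OntologyModel:
    """Assemble the ontology model from enrichment facets and candidates.

    Concepts without any IRI are skipped with a warning (they cannot anchor
    a class identifier). subClassOf cycles introduced by noisy candidate
    sets are broken by dropping the lexicographically later edge.
    """
    model = OntologyModel(base_iri=base_iri)
    class_nodes = graph.class_iris() if graph is not None else set()

    for concept in enriched:
        class_iri = concept.primary_iri
        if class_iri is None:
            logger.warning("concept %r has no IRI; skipped", concept.surface)
            continue
        model.classes[class_iri] = concept.surface
        label = concept.pref_label or concept.surface
        model.annotations.add((class_iri, "prefLabel", label))
        for alt in concept.alt_labels:
            model.annotations.add((class_iri, "altLabel", alt))
            if graph is not None:
                with_label = graph.lookup_by_label(alt) & class_nodes
                for other in sorted(with_label):
                    if other != class_iri:
                        model.axioms.add(
                            Axiom("equivalentClass", class_iri, other)
                        )
        for definition in concept.definitions:
            model.annotations.add((class_iri, "definition", definition))
        if concept.scheme is not None:
            model.annotations.add((class_iri, "inScheme", concept.scheme))
        for level, ancestor in concept.ancestors:
            if level == 1:
                model.axioms.add(Axiom("subClassOf", class_iri, ancestor))
        for ranked in concept.ranked_uris[1:]:
            model.axioms.add(Axiom("sameAs", class_iri, ranked.iri))
        for stype in concept.semantic_types:
            type_iri = URIRef(f"{base_iri}semantic-type/{_slug(stype)}")
            model.axioms.add(Axiom("type", class_iri, type_iri))

    taxonomic, non_taxonomic = split_candidates(candidates)
    for cand in taxonomic:
        child, parent = hierarchy_pair(cand)
        if child.primary_iri and parent.primary_iri:
            model.axioms.add(
                Axiom("subClassOf", child.primary_iri, parent.primary_iri)
            )
    for cand in non_taxonomic:
        if cand.subject.primary_iri and cand.object.primary_iri:
            model.axioms.add(
                Axiom(
                    "property",
                    cand.subject.primary_iri,
                    cand.object.primary_iri,
                    predicate=cand.predicate,
                )
            )

    _break_subclass_cycles(model)
    return model


def _break_subclass_cycles(model: OntologyModel) -> None:
    digraph = nx.DiGraph()
    for ax in model.axioms:
        if ax.kind == "subClassOf":
            digraph.add_edge(str(ax.subject), str(ax.object))
    while True:
        try:
            cycle = nx.find_cycle(digraph)
        except nx.NetworkXNoCycle:
            return
        drop = max(cycle)  # lexicographically later (subject, object) edge
        digraph.remove_edge(*drop[:2])
        model.axioms.discard(
            Axiom("subClassOf", URIRef(drop[0]), URIRef(drop[1]))
        )
        logger.warning("dropped subClassOf %s -> %s to break a cycle", *drop[:2])


def to_graph(model: OntologyModel) -> Graph:
    """Render the model as an rdflib graph (with ontology header)."""
    g = Graph()
    g.bind("owl", OWL)
    g.bind("skos", SKOS)
    g.add((URIRef(model.base_iri), RDF.type, OWL.Ontology))
    for class_iri in model.classes:
        g.add((class_iri, RDF.type, OWL.Class))
    for ax in sorted(
        model.axioms, key=lambda a: (a.kind, str(a.subject), str(a.object))
    ):
        if ax.kind == "subClassOf":
            g.add((ax.subject, RDFS.subClassOf, ax.object))
        elif ax.kind == "equivalentClass":
            g.add((ax.subject, OWL.equivalentClass, ax.object))
        elif ax.kind == "sameAs":
            g.add((ax.subject, OWL.sameAs, ax.object))
        elif ax.kind == "type":
            g.add((ax.subject, RDF.type, ax.object))
        elif ax.kind == "property":
            g.add((ax.subject, ax.predicate, ax.object))
        else:
            raise ValueError(f"unknown axiom kind {ax.kind!r}")
    for iri, prop, value in sorted(
        model.annotations, key=lambda t: (str(t[0]), t[1], str(t[2]))
    ):
        obj = value if isinstance(value, URIRef) else Literal(value)
        g.add((iri, _ANNOTATION_PROPS[prop], obj))
    return g


_SERIALIZE_FORMATS = {"turtle": ("turtle", ".ttl"), "rdfxml_owl": ("xml", ".owl")}


def serialize(model: OntologyModel, destination, format: str = "turtle") -> None:
    """Write the model to ``destination`` as Turtle or OWL/RDF-XML."""
    if format not in _SERIALIZE_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; expected {sorted(_SERIALIZE_FORMATS)}"
        )
    rdflib_format, _ = _SERIALIZE_FORMATS[format]
    to_graph(model).serialize(destination=str(destination), format=rdflib_format)


def load_model_graph(path, format: str = "turtle") -> Graph:
    """Parse a serialized ontology back into an rdflib graph."""
    if format not in _SERIALIZE_FORMATS:
        raise ValueError(f"unknown format {format!r}")
    g = Graph()
    g.parse(str(path), format=_SERIALIZE_FORMATS[format][0])
    return g


def subclass_closure(graph: Graph) -> set[tuple[URIRef, URIRef]]:
    """Transitive closure of rdfs:subClassOf — the RDFS entailment the
    generated hierarchy supports (subClassOf(A,B) ∧ subClassOf(B,C) ⇒
    subClassOf(A,C))."""
    digraph = nx.DiGraph()
    for s, o in graph.subject_objects(RDFS.subClassOf):
        digraph.add_edge(s, o)
    closure: set[tuple[URIRef, URIRef]] = set()
    for node in digraph.nodes:
        for desc in nx.descendants(digraph, node):
            closure.add((node, desc))
    return closure
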