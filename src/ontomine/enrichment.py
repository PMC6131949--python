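"""Semantic enrichment: attach labels, glosses, scheme, semantic categories
and a depth-bounded ancestor hierarchy to each discovered concept.

Ancestors are collected by level-synchronous breadth-first search over the
broader-direction hierarchy (``skos:broader``, ``rdfs:subClassOf``, and
inverted ``skos:narrower``), bounded by λ levels; each ancestor is reported
once at its minimal level, and cycles terminate through the visited set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import URIRef
from rdflib.namespace import RDFS

from .discovery import DiscoveredConcept
from .kb import KnowledgeGraph, Lexicon
from .ranking import RankedURI, build_vocabulary, rank_uris

__all__ = ["EnrichedConcept", "enrich", "identify_scheme", "ancestors_bfs"]


@dataclass(frozen=True)
class EnrichedConcept:
    concept: DiscoveredConcept
    pref_label: str | None = None
    alt_labels: tuple[str, ...] = ()
    definitions: tuple[str, ...] = ()
    scheme: URIRef | None = None
    semantic_types: tuple[str, ...] = ()
    semantic_groups: tuple[str, ...] = ()
    ancestors: tuple[tuple[int, URIRef], ...] = ()
    ranked_uris: tuple[RankedURI, ...] = ()

    @property
    def surface(self) -> str:
        return self.concept.surface

    @property
    def surface_key(self) -> str:
        return self.concept.surface_key

    @property
    def iris(self) -> tuple[URIRef, ...]:
        return self.concept.iris

    @property
    def primary_iri(self) -> URIRef | None:
        if self.ranked_uris:
            return self.ranked_uris[0].iri
        return self.iris[0] if self.iris else None

    @property
    def ancestor_iris(self) -> frozenset[URIRef]:
        return frozenset(iri for _, iri in self.ancestors)


def identify_scheme(iri: URIRef) -> URIRef | None:
    """Namespace base of an IRI: up to '#', else up to the last '/'.

    Returns None when the IRI has no separable local part (e.g. a bare
    URN), so the scheme is always a proper prefix of the IRI.
    """
    s = str(iri)
    if "#" in s:
        base = s[: s.index("#") + 1]
        return URIRef(base) if len(base) < len(s) else None
    scheme_sep = s.find("://")
    cut = s.rfind("/")
    if cut <= (scheme_sep + 2 if scheme_sep >= 0 else 0):
        return None
    base = s[: cut + 1]
    return URIRef(base) if len(base) < len(s) else None


def ancestors_bfs(
    graph: KnowledgeGraph, iri: URIRef, lam: int
) -> list[tuple[int, URIRef]]:
    """Ancestors of ``iri`` up to λ levels, each at its minimal level.

    Level-synchronous BFS up the hierarchy; output ordered by level then
    IRI. λ = 0 yields nothing.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out: list[tuple[int, URIRef]] = []
    visited = {iri}
    frontier = [iri]
    for level in range(1, lam + 1):
        nxt: set[URIRef] = set()
        for node in frontier:
            nxt |= graph.hierarchy_neighbors(node, "up")
        nxt -= visited
        if not nxt:
            break
        for anc in sorted(nxt):
            out.append((level, anc))
        visited |= nxt
        frontier = sorted(nxt)
    return out


def enrich(
    concept: DiscoveredConcept,
    graph: KnowledgeGraph,
    lexicon: Lexicon,
    lam: int = 3,
) -> EnrichedConcept:
    """Populate every enrichment facet for one discovered concept.

    Facets the sources do not provide are simply left empty; the function
    is pure, so identical inputs always yield identical output.
    """
    iris = list(concept.iris)
    ranked = tuple(rank_uris(iris, lexicon)) if iris else ()
    ordered_iris = [r.iri for r in ranked]
    primary = ordered_iris[0] if ordered_iris else None

    # preferred label: skos:prefLabel anywhere first (in rank order), then
    # the rdfs:label of the top-ranked URI
    pref_label = None
    for iri in ordered_iris:
        labels = graph.pref_labels_of(iri)
        if labels:
            pref_label = sorted(labels)[0]
            break
    if pref_label is None and primary is not None:
        rdfs_labels = [str(o) for o in graph.graph.objects(primary, RDFS.label)]
        if rdfs_labels:
            pref_label = sorted(rdfs_labels)[0]

    alt: list[str] = []
    for iri in ordered_iris:
        for label in graph.alt_labels_of(iri):
            if label != pref_label and label not in alt:
                alt.append(label)
    entry = lexicon.by_id(concept.concept_id) if concept.concept_id else None
    if entry is None:
        entry = lexicon.lookup(concept.surface)
    if entry is not None:
        for surface_form in entry.surface_forms:
            if (
                surface_form != pref_label
                and surface_form.casefold() != concept.surface.casefold()
                and surface_form not in alt
            ):
                alt.append(surface_form)

    definitions: list[str] = []
    if concept.sense_definition is not None:
        definitions.append(concept.sense_definition)
    for iri in ordered_iris:
        for d in graph.definitions_of(iri):
            if d not in definitions:
                definitions.append(d)

    sem_types: list[str] = []
    sem_groups: list[str] = []
    if entry is not None:
        sem_types.extend(entry.semantic_types)
        sem_groups.extend(entry.semantic_groups)
    for iri in ordered_iris:
        types, groups = lexicon.semantics_for_iri(iri)
        sem_types.extend(t for t in types if t not in sem_types)
        sem_groups.extend(g for g in groups if g not in sem_groups)

    return EnrichedConcept(
        concept=concept,
        pref_label=pref_label,
        alt_labels=tuple(alt),
        definitions=tuple(definitions),
        scheme=identify_scheme(primary) if primary is not None else None,
        semantic_types=tuple(sem_types),
        semantic_groups=tuple(sem_groups),
        ancestors=tuple(ancestors_bfs(graph, primary, lam))
        if primary is not None
        else (),
        ranked_uris=ranked,
    )
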