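"""Deterministic synthetic knowledge-graph, lexicon and corpus generation.

These generators emulate the structures the pipeline consumes from real
linked data: class-typed concept nodes carrying ``rdfs:label`` /
``skos:prefLabel`` / ``skos:altLabel``, ``skos:definition`` glosses built
from concept-specific keyword bags, a bounded-depth ``skos:broader`` /
``rdfs:subClassOf`` / ``skos:narrower`` hierarchy, cross-concept predicate
edges, and ambiguous surface forms shared by two IRIs whose glosses are
disjoint. Every random draw flows from the single ``seed``, and the
returned :class:`GroundTruth` records exactly what was planted so tests can
score recovery.

Concept names are pseudo-words with globally unique Porter stems, which
keeps label, synonym and definition overlap between *different* concepts
near zero — the "bimodal" regime in which a relatedness threshold separates
planted relations from noise cleanly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from . import porter
from .kb import KnowledgeGraph, Lexicon, LexiconEntry
from .textproc import normalize_text

__all__ = [
    "GroundTruth",
    "generate_fixture_kb",
    "generate_fixture_corpus",
    "generate_pattern_sentences",
]

_SYLLABLES = [
    c + v
    for c in "b d f g k l m n p r s t v z".split()
    for v in "a e i o u".split()
]

_SCHEMES = (
    "http://fixture.ontomine.dev/vocab/disease/",
    "http://fixture.ontomine.dev/vocab/chem/",
    "http://fixture.ontomine.dev/vocab/pheno/",
)
_DECOY_SCHEME = "http://fixture.ontomine.dev/vocab/decoy/"

REL = Namespace("http://fixture.ontomine.dev/rel/")
_CROSS_PREDICATES = (REL.associatedWith, REL.interactsWith, REL.modulates)

_TYPE_POOL = (
    "Disease or Syndrome",
    "Pharmacologic Substance",
    "Finding",
    "Anatomical Structure",
    "Gene or Genome",
)
_GROUP_POOL = ("Disorders", "Chemicals & Drugs", "Phenomena", "Anatomy", "Genes")


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports."""

    #: normalized surface -> intended (non-decoy) IRI
    concept_iris: dict[str, URIRef] = field(default_factory=dict)
    #: normalized surface -> normalized synonym (altLabel) surface
    synonyms: dict[str, str] = field(default_factory=dict)
    #: normalized ambiguous surface -> decoy IRI sharing that surface
    decoy_iris: dict[str, URIRef] = field(default_factory=dict)
    #: directed (child IRI, parent IRI) pairs
    hierarchy_pairs: set[tuple[URIRef, URIRef]] = field(default_factory=set)
    #: planted non-taxonomic (subject IRI, predicate, object IRI) triples
    cross_edges: set[tuple[URIRef, URIRef, URIRef]] = field(default_factory=set)
    #: IRI -> gloss keyword bag used to build its definition
    gloss_keywords: dict[URIRef, tuple[str, ...]] = field(default_factory=dict)
    #: hierarchy level of each intended IRI (roots at 0)
    levels: dict[URIRef, int] = field(default_factory=dict)

    @property
    def concept_surfaces(self) -> set[str]:
        return set(self.concept_iris)

    @property
    def ambiguous_surfaces(self) -> set[str]:
        return set(self.decoy_iris)

    def hierarchy_surface_pairs(self) -> set[tuple[str, str]]:
        by_iri = {iri: s for s, iri in self.concept_iris.items()}
        return {
            (by_iri[c], by_iri[p])
            for c, p in self.hierarchy_pairs
            if c in by_iri and p in by_iri
        }

    def cross_surface_triples(self) -> set[tuple[str, str, str]]:
        by_iri = {iri: s for s, iri in self.concept_iris.items()}
        return {
            (by_iri[s], str(p), by_iri[o])
            for s, p, o in self.cross_edges
            if s in by_iri and o in by_iri
        }


class _WordMint:
    """Pseudo-word factory guaranteeing globally unique Porter stems."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def word(self) -> str:
        while True:
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(3))
            s = porter.stem(w)
            if w not in self.used and s not in self.used:
                self.used.update((w, s))
                return w

    def words(self, n: int) -> list[str]:
        return [self.word() for _ in range(n)]


def generate_fixture_kb(
    n_concepts: int,
    hierarchy_depth: int = 2,
    cross_edge_rate: float = 0.05,
    ambiguity_rate: float = 0.0,
    seed: int = 0,
) -> tuple[KnowledgeGraph, Lexicon, GroundTruth]:
    """Generate a synthetic knowledge graph, its lexicon and ground truth.

    Parameters
    ----------
    n_concepts:
        Number of genuine concepts (decoy senses come on top).
    hierarchy_depth:
        Maximum number of up-steps from any concept to its root. The first
        ``hierarchy_depth + 1`` concepts form a witness chain of exactly
        this depth; the rest attach to random parents above the bottom
        level, so the bound holds everywhere.
    cross_edge_rate:
        Bernoulli rate at which each ordered non-adjacent concept pair
        receives a planted non-taxonomic predicate edge.
    ambiguity_rate:
        Fraction of concepts whose surface form is shared with a second,
        decoy IRI carrying a disjoint gloss keyword bag.
    """
    if n_concepts <= 0:
        raise ValueError("n_concepts must be positive")
    if hierarchy_depth < 0:
        raise ValueError("hierarchy_depth must be >= 0")
    if hierarchy_depth > n_concepts - 1:
        raise ValueError(
            f"hierarchy_depth={hierarchy_depth} impossible with "
            f"n_concepts={n_concepts}"
        )
    for name, val in (("cross_edge_rate", cross_edge_rate),
                      ("ambiguity_rate", ambiguity_rate)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    rng = random.Random(seed)
    mint = _WordMint(rng)
    truth = GroundTruth()
    graph = Graph()
    graph.bind("skos", SKOS)
    graph.bind("owl", OWL)
    graph.bind("rel", REL)

    # gloss keywords shared by every genuine concept: the "domain" signal
    # exploited by gloss-overlap disambiguation
    domain_kws = tuple(mint.words(2))

    surfaces: list[str] = []
    iris: list[URIRef] = []
    entries: list[LexiconEntry] = []
    iri_sem: dict[URIRef, tuple[tuple[str, ...], tuple[str, ...]]] = {}

    for i in range(n_concepts):
        n_words = 2 if rng.random() < 0.3 else 1
        surface = " ".join(mint.words(n_words))
        synonym = mint.word()
        scheme = _SCHEMES[rng.randrange(len(_SCHEMES))]
        iri = URIRef(f"{scheme}C{i:04d}")
        gloss_kws = domain_kws + tuple(mint.words(4))
        definition = " ".join(gloss_kws)

        typing = rng.choice(("owl", "skos", "both"))
        if typing in ("owl", "both"):
            graph.add((iri, RDF.type, OWL.Class))
        if typing in ("skos", "both"):
            graph.add((iri, RDF.type, SKOS.Concept))
        label_variant = rng.choice((surface, surface.title()))
        graph.add((iri, RDFS.label, Literal(label_variant)))
        graph.add((iri, SKOS.prefLabel, Literal(surface)))
        graph.add((iri, SKOS.altLabel, Literal(synonym)))
        graph.add((iri, SKOS.definition, Literal(definition)))
        if rng.random() < 0.3:
            graph.add((iri, SKOS.note, Literal(" ".join(mint.words(2)))))

        stype = _TYPE_POOL[rng.randrange(len(_TYPE_POOL))]
        group = _GROUP_POOL[_TYPE_POOL.index(stype)]
        types = (stype,) if rng.random() < 0.7 else (
            stype, _TYPE_POOL[(rng.randrange(len(_TYPE_POOL)))]
        )
        types = tuple(dict.fromkeys(types))
        entries.append(
            LexiconEntry(
                concept_id=f"C{1_000_000 + i}",
                surface_forms=(surface, synonym),
                semantic_types=types,
                semantic_groups=(group,),
            )
        )
        iri_sem[iri] = (types, (group,))

        key = normalize_text(surface)
        surfaces.append(surface)
        iris.append(iri)
        truth.concept_iris[key] = iri
        truth.synonyms[key] = normalize_text(synonym)
        truth.gloss_keywords[iri] = gloss_kws

    # hierarchy: witness chain 0..depth, everyone else attaches above the
    # bottom level; edges planted in all three predicate spellings
    levels = {}
    for i in range(n_concepts):
        if hierarchy_depth == 0:
            levels[i] = 0
            continue
        if i <= hierarchy_depth:
            levels[i] = i
            parent = i - 1 if i > 0 else None
        else:
            parent = rng.choice(
                [j for j in range(i) if levels[j] < hierarchy_depth]
            )
            levels[i] = levels[parent] + 1
        if parent is not None:
            child_iri, parent_iri = iris[i], iris[parent]
            style = rng.choice(("broader", "subclass", "narrower"))
            if style == "broader":
                graph.add((child_iri, SKOS.broader, parent_iri))
            elif style == "subclass":
                graph.add((child_iri, RDFS.subClassOf, parent_iri))
            else:
                graph.add((parent_iri, SKOS.narrower, child_iri))
            truth.hierarchy_pairs.add((child_iri, parent_iri))
    truth.levels = {iris[i]: lvl for i, lvl in levels.items()}

    # non-taxonomic cross edges between non-adjacent concepts
    adjacent = truth.hierarchy_pairs | {(p, c) for c, p in truth.hierarchy_pairs}
    for i in range(n_concepts):
        for j in range(n_concepts):
            if i == j or (iris[i], iris[j]) in adjacent:
                continue
            if rng.random() < cross_edge_rate:
                pred = _CROSS_PREDICATES[rng.randrange(len(_CROSS_PREDICATES))]
                graph.add((iris[i], pred, iris[j]))
                truth.cross_edges.add((iris[i], pred, iris[j]))

    # ambiguous surfaces: decoy IRIs with the same label but a gloss bag
    # disjoint from every genuine gloss and from every other decoy gloss
    n_ambiguous = round(ambiguity_rate * n_concepts)
    for idx, i in enumerate(sorted(rng.sample(range(n_concepts), n_ambiguous))):
        decoy = URIRef(f"{_DECOY_SCHEME}D{i:04d}")
        decoy_kws = tuple(mint.words(6))
        graph.add((decoy, RDF.type, OWL.Class))
        graph.add((decoy, RDFS.label, Literal(surfaces[i])))
        graph.add((decoy, SKOS.definition, Literal(" ".join(decoy_kws))))
        truth.decoy_iris[normalize_text(surfaces[i])] = decoy
        truth.gloss_keywords[decoy] = decoy_kws
        iri_sem[decoy] = (("Natural Phenomenon",), ("Phenomena",))

    lexicon = Lexicon(entries, iri_sem)
    return KnowledgeGraph(graph), lexicon, truth


_CORPUS_TEMPLATES = (
    "The {a} was linked to the {b} in patients.",
    "Researchers observed the {a} along with the {b}.",
    "The {a} appears together with the {b} in most cohorts.",
    "Reports described the {a} accompanied by the {b}.",
)


def generate_fixture_corpus(
    truth: GroundTruth, n_sentences: int = 50, seed: int = 0
) -> list[str]:
    """Declarative sentences mentioning pairs of planted concepts.

    Every concept surface is mentioned at least once (round-robin over the
    concept list), and ambiguous concepts are always paired with an
    unambiguous partner so gloss-overlap disambiguation has context. The
    filler vocabulary avoids the literals of the default pattern
    repository, so these sentences exercise graph mining only.
    """
    rng = random.Random(seed)
    surfaces = sorted(truth.concept_surfaces)
    if len(surfaces) < 2:
        raise ValueError("need >= 2 concepts to build a corpus")
    unambiguous = sorted(truth.concept_surfaces - truth.ambiguous_surfaces)
    if not unambiguous:
        raise ValueError("need >= 1 unambiguous concept for corpus context")
    sentences = []
    for k in range(max(n_sentences, len(surfaces))):
        a = surfaces[k % len(surfaces)]
        if a in truth.ambiguous_surfaces:
            pool = [s for s in unambiguous if s != a]
        else:
            pool = [s for s in surfaces if s != a]
        b = pool[rng.randrange(len(pool))]
        template = _CORPUS_TEMPLATES[rng.randrange(len(_CORPUS_TEMPLATES))]
        sentences.append(template.format(a=a, b=b))
    return sentences


def generate_pattern_sentences(
    truth: GroundTruth,
    patterns,
    n_sentences: int = 100,
    seed: int = 0,
    use_synonyms: bool = False,
) -> tuple[list[str], set[tuple[str, str, str]]]:
    """Sentences instantiated from pattern templates, with expected triples.

    Slots are filled with planted concept surfaces — or their synonyms when
    ``use_synonyms`` — and letter case is randomized to exercise
    case-insensitive matching. Returns the sentences and the expected
    (subject surface, predicate, object surface) set, normalized and keyed
    by the canonical surface even when a synonym was written.
    """
    rng = random.Random(seed)
    surfaces = sorted(truth.concept_surfaces)
    if len(surfaces) < 2:
        raise ValueError("need >= 2 concepts")
    syn_of = truth.synonyms
    sentences: list[str] = []
    expected: set[tuple[str, str, str]] = set()
    pat_list = list(patterns)
    for _ in range(n_sentences):
        pat = pat_list[rng.randrange(len(pat_list))]
        x, y = rng.sample(surfaces, 2)
        fill_x, fill_y = x, y
        if use_synonyms:
            if rng.random() < 0.5:
                fill_x = syn_of.get(x, x)
            if rng.random() < 0.5:
                fill_y = syn_of.get(y, y)
        if rng.random() < 0.3:
            fill_x = fill_x.upper()
        if rng.random() < 0.3:
            fill_y = fill_y.title()
        text = pat.template.replace("[X]", fill_x).replace("[Y]", fill_y)
        sentences.append(text + ".")
        expected.add((x, str(pat.predicate), y))
    return sentences, expected
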