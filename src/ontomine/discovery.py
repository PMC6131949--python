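"""Concept discovery: n-gram candidates, dictionary/graph mapping,
longest-match filtering, and gloss-overlap sense disambiguation.

A token window becomes a concept when the surface either has a lexicon
entry (UMLS-style dictionary hit) or matches the label of a class-typed
node in the knowledge graph — the hybrid that catches dictionary gaps such
as surfaces missing from the concept lexicon. When a surface matches
several class IRIs, the Lesk-style disambiguator scores each candidate
sense by the number of content-word stems its gloss shares with the glosses
of the other concepts discovered in the same text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from rdflib import URIRef

from .kb import KnowledgeGraph, Lexicon
from .textproc import Sentence, content_stems, normalize_text

__all__ = [
    "CandidateEntity",
    "DiscoveredConcept",
    "candidate_ngrams",
    "map_candidates",
    "longest_match_filter",
    "disambiguate",
]

logger = logging.getLogger(__name__)

#: (sentence index, start token, end token) with a half-open token range
Span = tuple[int, int, int]


@dataclass(frozen=True)
class CandidateEntity:
    surface: str
    span: Span
    n: int


@dataclass(frozen=True)
class DiscoveredConcept:
    """A surface span resolved to a lexicon id and/or graph IRIs."""

    surface: str
    span: Span
    concept_id: str | None = None
    iris: tuple[URIRef, ...] = ()
    sense_definition: str | None = None
    unresolved: bool = False

    def __post_init__(self):
        if self.concept_id is None and not self.iris:
            raise ValueError("concept needs a lexicon id or >= 1 IRI")

    @property
    def surface_key(self) -> str:
        return normalize_text(self.surface)


def _eligible(token) -> bool:
    # stop words and verbs never participate in concept candidates, and
    # punctuation carries no surface content
    return (not token.is_stop) and token.pos != "VB" and token.pos != "."


def candidate_ngrams(sentence: Sentence, max_n: int = 4) -> list[CandidateEntity]:
    """All 1..max_n token windows over contiguous runs of eligible tokens.

    Exclusion happens before windowing, so a window never crosses a stop
    word, verb or punctuation token. Output is ordered by start position,
    then window length.
    """
    if not 1 <= max_n <= 8:
        raise ValueError("max_n must be in [1, 8]")
    if not sentence.tokens:
        return []
    runs: list[list] = []
    current: list = []
    for tok in sentence.tokens:
        if _eligible(tok):
            current.append(tok)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    out: list[CandidateEntity] = []
    for run in runs:
        m = len(run)
        for start in range(m):
            for k in range(1, min(max_n, m - start) + 1):
                window = run[start : start + k]
                out.append(
                    CandidateEntity(
                        surface=" ".join(t.surface for t in window),
                        span=(
                            sentence.sentence_index,
                            window[0].index,
                            window[-1].index + 1,
                        ),
                        n=k,
                    )
                )
    out.sort(key=lambda c: (c.span[1], c.n))
    return out


def map_candidates(
    candidates: list[CandidateEntity],
    graph: KnowledgeGraph,
    lexicon: Lexicon,
) -> list[DiscoveredConcept]:
    """Resolve candidates against the lexicon and the graph's class nodes.

    A candidate survives iff the dictionary knows its surface or the graph
    holds a class-typed node labelled with it; both resolutions are kept
    when both hit.
    """
    class_nodes = graph.class_iris()
    out: list[DiscoveredConcept] = []
    for cand in candidates:
        entry = lexicon.lookup(cand.surface)
        iris = tuple(
            sorted(graph.lookup_by_label(cand.surface) & class_nodes)
        )
        if entry is None and not iris:
            continue
        out.append(
            DiscoveredConcept(
                surface=cand.surface,
                span=cand.span,
                concept_id=entry.concept_id if entry else None,
                iris=iris,
            )
        )
    return out


def longest_match_filter(
    concepts: list[DiscoveredConcept],
) -> list[DiscoveredConcept]:
    """Drop concepts whose span is strictly contained in another's span.

    Concepts with identical spans are all retained. Containment is only
    meaningful within one sentence.
    """
    def contains(outer: Span, inner: Span) -> bool:
        return (
            outer[0] == inner[0]
            and outer[1] <= inner[1]
            and inner[2] <= outer[2]
            and (outer[1], outer[2]) != (inner[1], inner[2])
        )

    kept = [
        c
        for c in concepts
        if not any(contains(other.span, c.span) for other in concepts)
    ]
    kept.sort(key=lambda c: (c.span[0], c.span[1], c.span[2]))
    return kept


def disambiguate(
    concepts: list[DiscoveredConcept],
    graph: KnowledgeGraph,
    overlap_threshold: int = 1,
) -> list[DiscoveredConcept]:
    """Select senses for multi-IRI concepts by gloss overlap.

    Each candidate IRI is scored as the number of content-word stems shared
    between its definitions and the pooled definitions of the *other*
    discovered concepts (mentions of the same surface do not support
    themselves). IRIs with the maximal score are retained when that score
    reaches ``overlap_threshold``; otherwise all IRIs stay and the concept
    is flagged unresolved. Output IRIs are always a subset of input IRIs.
    """
    bag_cache: dict[URIRef, frozenset[str]] = {}

    def bag(iri: URIRef) -> frozenset[str]:
        if iri not in bag_cache:
            stems: set[str] = set()
            for definition in graph.definitions_of(iri):
                stems |= content_stems(definition)
            bag_cache[iri] = frozenset(stems)
        return bag_cache[iri]

    out: list[DiscoveredConcept] = []
    for concept in concepts:
        if len(concept.iris) < 2:
            out.append(concept)
            continue
        context: set[str] = set()
        for other in concepts:
            if other.surface_key == concept.surface_key:
                continue
            for iri in other.iris:
                context |= bag(iri)
        scores = {iri: len(bag(iri) & context) for iri in concept.iris}
        if all(not bag(iri) for iri in concept.iris):
            logger.warning(
                "concept %r has no definitions for any sense; left unresolved",
                concept.surface,
            )
            out.append(replace(concept, unresolved=True))
            continue
        best = max(scores.values())
        if best >= overlap_threshold:
            chosen = tuple(sorted(i for i, s in scores.items() if s == best))
            defs = graph.definitions_of(chosen[0])
            out.append(
                replace(
                    concept,
                    iris=chosen,
                    sense_definition=defs[0] if defs else None,
                    unresolved=False,
                )
            )
        else:
            logger.warning(
                "gloss overlap below threshold for %r; keeping all senses",
                concept.surface,
            )
            out.append(replace(concept, unresolved=True))
    return out
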