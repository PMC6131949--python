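"""RDF triple mining: depth-bounded BFS over the knowledge graph plus a
four-signal relatedness score that links mined triple endpoints back to the
discovered concepts.

The miner walks the graph outward from each concept's primary IRI (depth γ,
default 5), collecting every triple asserted about a visited node. A triple
becomes a candidate relation between two concepts when each of its
endpoints matches a discovered concept: exactly (the endpoint is one of the
concept's IRIs, relatedness 1) or softly, with the endpoint's best-matching
concept scoring at least the threshold δ on the combined relatedness. The
combined score is the maximum of the four signals — label, synonym,
definition and hierarchy overlap — mirroring an "any one strong signal
passes" reading of per-signal threshold tests. Hierarchy-predicate triples
are routed to the taxonomic output; everything else is non-taxonomic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from rdflib import Literal, URIRef
from rdflib.namespace import RDFS

from .enrichment import EnrichedConcept, ancestors_bfs
from .kb import (
    HIERARCHY_DOWN_PREDICATES,
    HIERARCHY_UP_PREDICATES,
    KBTriple,
    KnowledgeGraph,
)
from .textproc import content_stems

__all__ = [
    "RelatednessScore",
    "TripleCandidate",
    "bfs_neighborhood",
    "relatedness",
    "extract_triples",
    "split_candidates",
    "hierarchy_pair",
]

logger = logging.getLogger(__name__)

_HIERARCHY_PREDICATES = set(HIERARCHY_UP_PREDICATES) | set(
    HIERARCHY_DOWN_PREDICATES
)


@dataclass(frozen=True)
class RelatednessScore:
    label_score: float
    synonym_score: float
    definition_score: float
    hierarchy_score: float

    @property
    def combined(self) -> float:
        return max(
            self.label_score,
            self.synonym_score,
            self.definition_score,
            self.hierarchy_score,
        )


_PERFECT = RelatednessScore(1.0, 1.0, 1.0, 1.0)
_ZERO = RelatednessScore(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TripleCandidate:
    subject: EnrichedConcept
    predicate: URIRef
    object: EnrichedConcept
    score: RelatednessScore
    provenance: str  # "graph_mined" | "pattern_matched"
    source_path: tuple[URIRef, ...] = ()
    mined_triple: KBTriple | None = None

    @property
    def is_taxonomic(self) -> bool:
        return self.predicate in _HIERARCHY_PREDICATES


def hierarchy_pair(candidate: TripleCandidate) -> tuple[EnrichedConcept, EnrichedConcept]:
    """Normalize a taxonomic candidate to (child, parent) regardless of
    whether the graph asserted broader/subClassOf or narrower."""
    if not candidate.is_taxonomic:
        raise ValueError("not a taxonomic candidate")
    if candidate.predicate in HIERARCHY_DOWN_PREDICATES:
        return candidate.object, candidate.subject
    return candidate.subject, candidate.object


def split_candidates(
    candidates: list[TripleCandidate],
) -> tuple[list[TripleCandidate], list[TripleCandidate]]:
    """(taxonomic, non-taxonomic) partition of a candidate list."""
    tax = [c for c in candidates if c.is_taxonomic]
    non = [c for c in candidates if not c.is_taxonomic]
    return tax, non


def _bfs(graph: KnowledgeGraph, start: URIRef, gamma: int):
    """Distance labels, parents and collected triples of the γ-ball.

    A node's triples (as subject) are collected when the node lies within
    γ−1 hops of ``start``; traversal follows every predicate
    subject→object and hierarchy predicates in both directions. Literal
    objects are terminal.
    """
    dist: dict[URIRef, int] = {start: 0}
    parent: dict[URIRef, URIRef | None] = {start: None}
    collected: list[tuple[KBTriple, int]] = []
    frontier = [start]
    for d in range(gamma):
        nxt: list[URIRef] = []
        for node in sorted(frontier):
            for s, p, o in graph.graph.triples((node, None, None)):
                collected.append(((s, p, o), d + 1))
                if isinstance(o, URIRef) and o not in dist:
                    dist[o] = d + 1
                    parent[o] = node
                    nxt.append(o)
            for pred in _HIERARCHY_PREDICATES:
                for s in graph.graph.subjects(pred, node):
                    if isinstance(s, URIRef) and s not in dist:
                        dist[s] = d + 1
                        parent[s] = node
                        nxt.append(s)
        frontier = nxt
        if not frontier:
            break
    collected.sort(key=lambda item: (item[1], str(item[0][0]), str(item[0][1]), str(item[0][2])))
    return collected, dist, parent


def bfs_neighborhood(
    graph: KnowledgeGraph, start: URIRef, gamma: int = 5
) -> list[tuple[KBTriple, int]]:
    """Triples describing ``start``'s γ-neighbourhood, with hop distance.

    A triple at hop k has its subject at distance k−1 from ``start``; with
    γ=1 this is exactly the triples whose subject is ``start``. Ordering is
    deterministic: (distance, subject, predicate, object).
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    present = any(graph.graph.triples((start, None, None))) or any(
        graph.graph.triples((None, None, start))
    )
    if not present:
        warnings.warn(f"start node {start} not present in graph", stacklevel=2)
        return []
    collected, _, _ = _bfs(graph, start, gamma)
    return collected


def _jaccard(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    union = a | b
    return len(a & b) / len(union)


def _label_stems(labels) -> set[str]:
    stems: set[str] = set()
    for label in labels:
        stems |= content_stems(label)
    return stems


def relatedness(
    endpoint: URIRef,
    target: EnrichedConcept,
    graph: KnowledgeGraph,
    lam: int = 3,
) -> RelatednessScore:
    """Four-signal relatedness between a graph node and an enriched concept.

    Signals: Jaccard over stemmed label tokens, over stemmed synonym
    (altLabel) tokens, over definition content-stem bags, and over
    hierarchy signatures (the node itself plus its λ-bounded ancestors).
    An endpoint that *is* one of the concept's IRIs scores 1 everywhere.
    Missing facets score 0.
    """
    if endpoint in target.iris:
        return _PERFECT

    ep_labels = [str(o) for o in graph.graph.objects(endpoint, RDFS.label)]
    ep_labels += graph.pref_labels_of(endpoint)
    ep_alt = graph.alt_labels_of(endpoint)
    ep_defs = graph.definitions_of(endpoint)

    target_labels = [target.surface]
    if target.pref_label:
        target_labels.append(target.pref_label)
    for iri in target.iris:
        target_labels += [str(o) for o in graph.graph.objects(iri, RDFS.label)]
        target_labels += graph.pref_labels_of(iri)

    label_score = _jaccard(_label_stems(ep_labels), _label_stems(target_labels))
    synonym_score = _jaccard(_label_stems(ep_alt), _label_stems(target.alt_labels))

    ep_def_bag: set[str] = set()
    for d in ep_defs:
        ep_def_bag |= content_stems(d)
    target_def_bag: set[str] = set()
    for d in target.definitions:
        target_def_bag |= content_stems(d)
    definition_score = _jaccard(ep_def_bag, target_def_bag)

    ep_hier = {endpoint} | {a for _, a in ancestors_bfs(graph, endpoint, lam)}
    target_hier = set(target.iris) | set(target.ancestor_iris)
    hierarchy_score = _jaccard(ep_hier, target_hier)

    return RelatednessScore(
        label_score=label_score,
        synonym_score=synonym_score,
        definition_score=definition_score,
        hierarchy_score=hierarchy_score,
    )


def _best_matches(
    endpoint: URIRef,
    concepts: list[EnrichedConcept],
    graph: KnowledgeGraph,
    lam: int,
    cache: dict,
) -> tuple[list[int], RelatednessScore | None]:
    """Indices of the concepts tying for best relatedness with ``endpoint``
    (requiring a strictly positive score), and that score."""
    if endpoint in cache:
        return cache[endpoint]
    best: float = 0.0
    best_idx: list[int] = []
    best_score: RelatednessScore | None = None
    for i, concept in enumerate(concepts):
        score = relatedness(endpoint, concept, graph, lam)
        if score.combined > best:
            best = score.combined
            best_idx = [i]
            best_score = score
        elif score.combined == best and best > 0.0:
            best_idx.append(i)
    cache[endpoint] = (best_idx, best_score)
    return cache[endpoint]


def extract_triples(
    concepts: list[EnrichedConcept],
    graph: KnowledgeGraph,
    gamma: int = 5,
    delta: float = 0.70,
    lam: int = 3,
) -> list[TripleCandidate]:
    """Mine candidate relations between discovered concepts.

    For each concept, BFS collects the γ-neighbourhood of its primary IRI;
    a collected triple with an IRI object becomes a candidate when both
    endpoints resolve to (distinct) discovered concepts whose best
    relatedness reaches δ. Candidates with the same
    (subject, predicate, object) concept key are merged keeping the
    highest-scoring one. The result is antitone in δ and monotone in γ.
    """
    if len(concepts) < 2:
        return []
    if gamma < 1 or gamma > 8:
        raise ValueError("gamma must be in [1, 8]")
    if gamma > 5:
        logger.warning("gamma=%d above 5 tends to mine noisy regions", gamma)
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")

    match_cache: dict = {}
    merged: dict[tuple, TripleCandidate] = {}

    for source in concepts:
        start = source.primary_iri
        if start is None:
            continue
        neighborhood, _, parent = _bfs(graph, start, gamma)
        for (s, p, o), hop in neighborhood:
            if isinstance(o, Literal) or not isinstance(o, URIRef):
                continue
            subj_idx, subj_score = _best_matches(s, concepts, graph, lam, match_cache)
            if subj_score is None or subj_score.combined < delta:
                continue
            obj_idx, obj_score = _best_matches(o, concepts, graph, lam, match_cache)
            if obj_score is None or obj_score.combined < delta:
                continue
            # path from the BFS start down to the triple's subject
            path = [s]
            while path[-1] is not None and parent.get(path[-1]) is not None:
                path.append(parent[path[-1]])
            path = tuple(reversed(path)) + (o,)
            for si in subj_idx:
                for oi in obj_idx:
                    subj_c, obj_c = concepts[si], concepts[oi]
                    if subj_c.primary_iri == obj_c.primary_iri:
                        continue
                    key = (subj_c.primary_iri, p, obj_c.primary_iri)
                    score = min((subj_score, obj_score), key=lambda r: r.combined)
                    old = merged.get(key)
                    if old is None or score.combined > old.score.combined:
                        merged[key] = TripleCandidate(
                            subject=subj_c,
                            predicate=p,
                            object=obj_c,
                            score=score,
                            provenance="graph_mined",
                            source_path=path,
                            mined_triple=(s, p, o),
                        )
    out = list(merged.values())
    out.sort(key=lambda c: (c.subject.surface_key, str(c.predicate), c.object.surface_key))
    return out
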