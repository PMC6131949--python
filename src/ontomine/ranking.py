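"""URI ranking by average pairwise cosine similarity of semantic-category
feature vectors.

A concept recovered from linked data often resolves to several URIs (one
per source vocabulary). Each URI gets a binary feature vector over the
semantic types and groups the lexicon records for it; a URI's weight is the
mean cosine similarity between its vector and every other URI's vector, so
URIs that agree with the group consensus rank first and category outliers
(or URIs with no recorded categories) sink to the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdflib import URIRef

from .kb import Lexicon

__all__ = ["FeatureVector", "RankedURI", "feature_vector", "rank_uris"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    dims: tuple[str, ...]
    values: tuple[int, ...]

    @property
    def rankable(self) -> bool:
        return any(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def build_vocabulary(uris: list[URIRef], lexicon: Lexicon) -> tuple[str, ...]:
    """Sorted union of semantic types and groups over a concept's URIs."""
    vocab: set[str] = set()
    for iri in uris:
        types, groups = lexicon.semantics_for_iri(iri)
        vocab.update(types)
        vocab.update(groups)
    return tuple(sorted(vocab))


def feature_vector(
    iri: URIRef, lexicon: Lexicon, vocabulary: tuple[str, ...]
) -> FeatureVector:
    """Binary membership indicators of ``iri``'s types/groups over the
    shared vocabulary; all-zero when the lexicon knows nothing for it."""
    types, groups = lexicon.semantics_for_iri(iri)
    members = set(types) | set(groups)
    values = tuple(1 if dim in members else 0 for dim in vocabulary)
    vec = FeatureVector(dims=vocabulary, values=values)
    if not vec.rankable:
        logger.debug("URI %s has no semantic categories; unrankable", iri)
    return vec


@dataclass(frozen=True)
class RankedURI:
    iri: URIRef
    weight: float


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def rank_uris(
    uris: list[URIRef],
    lexicon: Lexicon,
    vocabulary: tuple[str, ...] | None = None,
) -> list[RankedURI]:
    """Weight each URI by its mean cosine similarity to the others.

    A single URI gets weight 1.0 by convention. Ties (including the
    all-zero-vector case, which is warned about) are broken by IRI
    lexicographic order; the result is sorted by descending weight.
    """
    if not uris:
        raise ValueError("need >= 1 URI to rank")
    uris = list(uris)
    if len(uris) == 1:
        return [RankedURI(iri=uris[0], weight=1.0)]
    if vocabulary is None:
        vocabulary = build_vocabulary(uris, lexicon)
    vectors = [feature_vector(u, lexicon, vocabulary).as_array() for u in uris]
    if all(not v.any() for v in vectors):
        logger.warning("all URI feature vectors are zero; ranking is arbitrary")
    weights = []
    for i, u in enumerate(uris):
        sims = [
            _cosine(vectors[i], vectors[j])
            for j in range(len(uris))
            if j != i
        ]
        weights.append(RankedURI(iri=u, weight=float(np.mean(sims))))
    weights.sort(key=lambda r: (-r.weight, str(r.iri)))
    return weights
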