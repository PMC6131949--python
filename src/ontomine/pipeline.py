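"""End-to-end orchestration: text → NLP → concept discovery → enrichment →
triple mining + pattern matching → ontology serialization.

The pipeline proper is deterministic — the configuration seed only drives
fixture generation — and every stage works on the previous stage's output
without mutating it, so identical configuration and inputs reproduce
byte-identical serializations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from rdflib import Graph, URIRef

from .discovery import (
    DiscoveredConcept,
    candidate_ngrams,
    disambiguate,
    longest_match_filter,
    map_candidates,
)
from .enrichment import EnrichedConcept, enrich
from .evaluate import EvalReport
from .factory import DEFAULT_BASE_IRI, OntologyModel, build_ontology, serialize
from .kb import KnowledgeGraph, Lexicon
from .patterns import (
    PatternRepository,
    default_patterns,
    load_patterns,
    match_sentence,
)
from .textproc import Sentence, analyze, segment
from .triples import TripleCandidate, extract_triples, hierarchy_pair, split_candidates

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_files"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window: int = 4            # n-gram window for concept candidates
    lam: int = 3               # λ: ancestor depth in enrichment
    gamma: int = 5             # γ: BFS depth for triple mining
    delta: float = 0.70        # δ: relatedness threshold
    overlap_threshold: int = 1  # gloss-overlap threshold for sense choice
    seed: int = 0
    base_iri: str = DEFAULT_BASE_IRI
    format: str = "turtle"     # turtle | rdfxml_owl
    titles: bool = False       # one-title-per-line input mode

    def validate(self) -> None:
        if not 1 <= self.window <= 8:
            raise ValueError("window must be in [1, 8]")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class PipelineResult:
    sentences: list[Sentence]
    mentions: list[DiscoveredConcept]
    concepts: list[EnrichedConcept]
    candidates: list[TripleCandidate]
    model: OntologyModel
    report: dict

    # -- views used for evaluation and export ---------------------------

    def concept_surfaces(self) -> set[str]:
        return {c.surface_key for c in self.concepts}

    def hierarchy_surface_pairs(self) -> set[tuple[str, str]]:
        tax, _ = split_candidates(self.candidates)
        out = set()
        for cand in tax:
            child, parent = hierarchy_pair(cand)
            out.add((child.surface_key, parent.surface_key))
        return out

    def non_taxonomic_surface_triples(self) -> set[tuple[str, str, str]]:
        _, non = split_candidates(self.candidates)
        return {
            (c.subject.surface_key, str(c.predicate), c.object.surface_key)
            for c in non
        }


def discover(
    sentences: list[Sentence],
    graph: KnowledgeGraph,
    lexicon: Lexicon,
    window: int = 4,
    overlap_threshold: int = 1,
) -> list[DiscoveredConcept]:
    """Per-sentence candidate generation, mapping and longest-match
    filtering, then corpus-wide sense disambiguation."""
    mentions: list[DiscoveredConcept] = []
    for sentence in sentences:
        cands = candidate_ngrams(sentence, window)
        mapped = map_candidates(cands, graph, lexicon)
        mentions.extend(longest_match_filter(mapped))
    return disambiguate(mentions, graph, overlap_threshold)


def _merge_mentions(mentions: list[DiscoveredConcept]) -> list[DiscoveredConcept]:
    """One concept per normalized surface; first mention's span is kept and
    the IRI sets of all mentions are intersected (they agree on noise-free
    input; intersection is the conservative merge when they do not)."""
    merged: dict[str, DiscoveredConcept] = {}
    for mention in mentions:
        key = mention.surface_key
        if key not in merged:
            merged[key] = mention
            continue
        prev = merged[key]
        iris = tuple(sorted(set(prev.iris) & set(mention.iris))) or prev.iris
        if iris != prev.iris:
            merged[key] = DiscoveredConcept(
                surface=prev.surface,
                span=prev.span,
                concept_id=prev.concept_id or mention.concept_id,
                iris=iris,
                sense_definition=prev.sense_definition,
                unresolved=prev.unresolved and mention.unresolved,
            )
    return [merged[k] for k in sorted(merged)]


def run_pipeline(
    texts: list[str],
    graph: KnowledgeGraph,
    lexicon: Lexicon,
    repo: PatternRepository | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage over in-memory inputs and return all intermediates."""
    config = config or PipelineConfig()
    config.validate()
    repo = repo if repo is not None else default_patterns()

    sentences: list[Sentence] = []
    for doc_index, text in enumerate(texts):
        doc_id = f"doc{doc_index:04d}"
        if config.titles:
            raw = [
                Sentence(text=line.strip(), doc_id=doc_id, sentence_index=i)
                for i, line in enumerate(text.splitlines())
                if line.strip()
            ]
        else:
            raw = segment(text, doc_id)
        sentences.extend(analyze(s) for s in raw)

    mentions = discover(
        sentences, graph, lexicon, config.window, config.overlap_threshold
    )
    unique = _merge_mentions(mentions)
    concepts = [enrich(c, graph, lexicon, config.lam) for c in unique]

    graph_candidates = extract_triples(
        concepts, graph, gamma=config.gamma, delta=config.delta, lam=config.lam
    )
    pattern_candidates: list[TripleCandidate] = []
    seen = {
        (c.subject.surface_key, c.predicate, c.object.surface_key)
        for c in graph_candidates
    }
    for sentence in sentences:
        for cand in match_sentence(sentence, concepts, repo):
            key = (cand.subject.surface_key, cand.predicate, cand.object.surface_key)
            if key not in seen:
                seen.add(key)
                pattern_candidates.append(cand)

    candidates = graph_candidates + pattern_candidates
    model = build_ontology(concepts, candidates, graph, config.base_iri)

    taxonomic, non_taxonomic = split_candidates(candidates)
    report = {
        "parameters": {
            "window": config.window,
            "lambda": config.lam,
            "gamma": config.gamma,
            "delta": config.delta,
            "overlap_threshold": config.overlap_threshold,
            "seed": config.seed,
            "base_iri": config.base_iri,
            "format": config.format,
        },
        "counts": {
            "documents": len(texts),
            "sentences": len(sentences),
            "concept_mentions": len(mentions),
            "concepts": len(concepts),
            "unresolved_concepts": sum(1 for c in unique if c.unresolved),
            "graph_mined_candidates": len(graph_candidates),
            "pattern_matched_candidates": len(pattern_candidates),
            "taxonomic_candidates": len(taxonomic),
            "non_taxonomic_candidates": len(non_taxonomic),
            "classes": len(model.classes),
            "axioms": len(model.axioms),
            "annotations": len(model.annotations),
        },
    }
    return PipelineResult(
        sentences=sentences,
        mentions=mentions,
        concepts=concepts,
        candidates=candidates,
        model=model,
        report=report,
    )


def _concept_record(concept: EnrichedConcept) -> dict:
    return {
        "surface": concept.surface,
        "span": list(concept.concept.span),
        "conceptId": concept.concept.concept_id,
        "iris": [str(i) for i in concept.iris],
        "senseDefinition": concept.concept.sense_definition,
        "unresolved": concept.concept.unresolved,
        "prefLabel": concept.pref_label,
        "altLabels": list(concept.alt_labels),
        "definitions": list(concept.definitions),
        "scheme": str(concept.scheme) if concept.scheme else None,
        "semanticTypes": list(concept.semantic_types),
        "semanticGroups": list(concept.semantic_groups),
        "ancestors": [[lvl, str(iri)] for lvl, iri in concept.ancestors],
        "rankedUris": [
            {"iri": str(r.iri), "weight": r.weight} for r in concept.ranked_uris
        ],
    }


def _candidate_record(cand: TripleCandidate) -> dict:
    return {
        "subject": cand.subject.surface,
        "predicate": str(cand.predicate),
        "object": cand.object.surface,
        "provenance": cand.provenance,
        "scores": {
            "label": cand.score.label_score,
            "synonym": cand.score.synonym_score,
            "definition": cand.score.definition_score,
            "hierarchy": cand.score.hierarchy_score,
            "combined": cand.score.combined,
        },
        "sourcePath": [str(i) for i in cand.source_path],
    }


def run_files(
    input_paths: list[str | Path],
    kb_path: str | Path,
    lexicon_path: str | Path,
    output_dir: str | Path,
    patterns_path: str | Path | None = None,
    kb_format: str = "turtle",
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-level wrapper: read inputs, run the pipeline, write artifacts.

    Outputs under ``output_dir``: the ontology (``ontology.ttl`` or
    ``ontology.owl``), ``concepts.jsonl``, ``candidates.jsonl``,
    ``candidates.nt`` and ``report.json``.
    """
    from .kb import load_graph

    config = config or PipelineConfig()
    texts = [Path(p).read_text(encoding="utf-8") for p in input_paths]
    graph = load_graph(kb_path, kb_format)
    lexicon = Lexicon.from_tsv(lexicon_path)
    repo = (
        default_patterns() if patterns_path is None else load_patterns(patterns_path)
    )
    result = run_pipeline(texts, graph, lexicon, repo, config)

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = "ttl" if config.format == "turtle" else "owl"
    serialize(result.model, out / f"ontology.{suffix}", config.format)

    with open(out / "concepts.jsonl", "w", encoding="utf-8") as fh:
        for concept in sorted(result.concepts, key=lambda c: c.surface_key):
            fh.write(json.dumps(_concept_record(concept), sort_keys=True) + "\n")
    with open(out / "candidates.jsonl", "w", encoding="utf-8") as fh:
        for cand in result.candidates:
            fh.write(json.dumps(_candidate_record(cand), sort_keys=True) + "\n")
    nt = Graph()
    for cand in result.candidates:
        if cand.subject.primary_iri and cand.object.primary_iri:
            nt.add((cand.subject.primary_iri, cand.predicate, cand.object.primary_iri))
    (out / "candidates.nt").write_text(nt.serialize(format="nt"), encoding="utf-8")
    (out / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
    return result
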