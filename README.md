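# ontomine

Automatic biomedical ontology generation from free text, driven by linked
data. `ontomine` reads unstructured text (e.g. PubMed/MEDLINE titles),
discovers biomedical concepts against a knowledge graph and a UMLS-style
lexicon, enriches them with labels, glosses and a bounded ancestor
hierarchy, mines taxonomic and non-taxonomic relations by graph search and
lexico-syntactic patterns, and emits a formal OWL/SKOS ontology. It is
aimed at ontology engineers and text-mining researchers who want a
reproducible, fully scriptable pipeline from corpus to `.ttl`/`.owl`.

## The method in brief

1. **NLP** — sentence segmentation, tokenization, Porter stemming,
   stop-word flagging, coarse POS tagging.
2. **Entity discovery** — n-gram candidates (window *n* ≤ 8, default 4)
   over stop-word/verb-free token runs; a candidate survives if the
   lexicon knows it or the graph holds an `owl:Class`/`skos:Concept` node
   with that label; nested matches are pruned to the longest span;
   ambiguous surfaces are resolved by gloss overlap (Lesk): each sense's
   definition is scored by shared content stems with the other discovered
   concepts' definitions.
3. **Semantic enrichment** — prefLabel/altLabels/definitions/scheme/
   semantic types, plus ancestors from a level-synchronous BFS up
   `skos:broader` / `rdfs:subClassOf` (and inverted `skos:narrower`)
   edges, bounded by λ (default 3).
4. **URI ranking** — each of a concept's URIs gets a binary semantic-type/
   group feature vector; its weight is the mean pairwise cosine similarity
   to the concept's other URIs; the top URI becomes the class identifier.
5. **Triple mining** — BFS of depth γ (default 5) around each concept's
   primary IRI; a mined triple becomes a candidate when both endpoints
   resolve to discovered concepts with combined relatedness ≥ δ (default
   0.70), where relatedness = max of label, synonym, definition and
   hierarchy overlap (all Jaccard). Hierarchy predicates route to the
   taxonomy; the rest are association relations.
6. **Pattern relations** — six vendored lexico-syntactic templates (e.g.
   `[X] causes by [Y]` → `schema:causeOf`) matched case-insensitively with
   synonym and stem fallback.
7. **Ontology factory** — concepts → `owl:Class` (IRI = top-ranked URI),
   other URIs → `owl:sameAs`, is-a → `rdfs:subClassOf`, synonyms →
   `skos:altLabel` (+ `owl:equivalentClass` when the synonym is itself a
   class), definitions/scheme → SKOS annotations, semantic types →
   `rdf:type`, associations → object properties; serialized as Turtle or
   RDF/XML.

Evaluation helpers score precision/recall/F for concepts, directed
hierarchy pairs, and (s, p, o) triples against gold-standard files.

See `docs/methods.md` for the full model, parameter rationale and
limitations.

## Worked example

The package ships a seeded fixture generator that emulates the structures
the pipeline consumes from real linked data (class-typed labelled nodes,
glosses, a broader-hierarchy, cross-concept edges) together with the
ground truth it planted:

```sh
ontomine fixtures make --out demo/fixture --n-concepts 12 --depth 2 \
    --cross-edge-rate 0.08 --n-sentences 20 --seed 7
ontomine run --input demo/fixture/corpus.txt --kb demo/fixture/kb.ttl \
    --lexicon demo/fixture/lexicon.tsv --output demo/out --seed 7
```

which prints the per-stage counts:

```json
{
  "annotations": 53,
  "axioms": 33,
  "classes": 12,
  "concept_mentions": 40,
  "concepts": 12,
  "documents": 1,
  "graph_mined_candidates": 18,
  "non_taxonomic_candidates": 7,
  "pattern_matched_candidates": 0,
  "sentences": 20,
  "taxonomic_candidates": 11,
  "unresolved_concepts": 0
}
```

All 12 planted concepts were discovered from the 20 corpus sentences (40
mentions before merging); mining recovered the 11 planted hierarchy links
and 7 planted association edges — exactly the fixture's ground truth
(`demo/fixture/truth.json`) — and the ontology encodes them as 12 classes
with 33 axioms. `demo/out/` then holds `ontology.ttl`, e.g.:

```turtle
<http://fixture.ontomine.dev/vocab/disease/C0009> a owl:Class,
        <urn:ontomine:semantic-type/Pharmacologic_Substance> ;
    rdfs:subClassOf <http://fixture.ontomine.dev/vocab/chem/C0001> ;
    skos:altLabel "zusoge" ;
    skos:definition "pegusa deduzo ratoze sovuge zoguzi zabite" ;
    skos:inScheme <http://fixture.ontomine.dev/vocab/disease/> ;
    skos:prefLabel "linivu mapemo" .
```

plus `concepts.jsonl` (one enriched concept per line, with ranked URIs),
`candidates.jsonl` + `candidates.nt` (relation candidates with their
four-signal scores and provenance), and `report.json`. Scoring against the
planted truth:

```sh
ontomine eval --gold-concepts gold.txt --pred-concepts pred.txt
# {"concepts": {"precision": 1.0, "recall": 1.0, "f_measure": 1.0, ...}}
```

The same stages are available as a library (`ontomine.run_pipeline`,
`ontomine.extract_triples`, `ontomine.rank_uris`, ...), and a real RDF
file or a SPARQL endpoint (`SparqlKnowledgeGraph.from_endpoint`) can stand
where the fixture graph stands here.

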