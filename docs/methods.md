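# Methods

`ontomine` turns unstructured biomedical text into a formal OWL/SKOS
ontology by leaning on two external knowledge sources: a linked-data
knowledge graph (the role Linked Life Data or BioPortal plays in
production) and a concept lexicon mapping surface forms to CUI-like
identifiers with coarse semantic types and groups (the role of UMLS). This
note describes each stage's model and assumptions, the parameters that
matter, what the synthetic fixtures do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Pipeline model

**Linguistic preprocessing.** Sentences are split at `.!?` boundaries;
tokens carry a Porter stem, a coarse POS tag and a stop-word flag. Stop
words are flagged, never deleted, so all downstream spans index into the
original token sequence. Only the noun/verb distinction is consumed
downstream (verbs never enter concept candidates), so tagging is
rule-based: a pinned verb lexicon plus `-ed`/`-ing` suffix heuristics, with
noun as the default class. The Porter stemmer is implemented in-package so
stemming behaviour is pinned; it is the classic 1980 rule set and, like the
original, is not idempotent on every English word — the test suite asserts
the fixed-point property only on an enumerated list.

**Concept discovery.** Candidate entities are all contiguous token windows
of length 1..`window` (default 4; the supported range is 1–8, with 4 the
empirically best trade-off between missing multi-word terms and drowning
recall in noise) over runs of eligible tokens. Exclusion happens before
windowing: a window never crosses a stop word, verb or punctuation token. A
candidate becomes a concept if the lexicon knows its surface (dictionary
route) or the graph holds an `owl:Class`/`skos:Concept` node whose
`rdfs:label`/`skos:altLabel`/`skos:prefLabel` equals the surface
case-insensitively after NFC normalization and whitespace collapse (graph
route); both resolutions are kept when both hit. Hybrid lookup matters
because real dictionaries have gaps — a term can be absent from the lexicon
yet present as a class in linked data. Nested matches are then pruned: any
concept whose token span is strictly contained in another's is dropped
(identical spans all survive), which trades unigram recall for precision on
multi-word terms.

**Sense disambiguation.** A surface matching several class IRIs is
resolved by gloss overlap (Lesk-style): each candidate sense is scored by
the number of content-word stem *types* shared between its
`skos:definition`/`skos:note` bag and the pooled definition bags of all
other discovered concepts in the text (mentions of the same surface do not
support themselves). Senses tying for the maximal score are all retained —
URI ranking later picks a primary — provided the score reaches
`overlap_threshold` (default 1: a single shared content stem is already
evidence in the right direction, and the fixtures show higher values only
lose resolvable cases). Below threshold the concept keeps all senses and is
flagged unresolved rather than silently guessing.

**Enrichment.** Each concept is annotated with preferred label
(`skos:prefLabel` first, else the `rdfs:label` of the top-ranked URI),
synonyms, definitions, its concept scheme (the IRI truncated at `#` or at
the last path segment), all semantic types/groups the lexicon offers
(several types per concept are deliberately all kept), and a λ-bounded
ancestor list computed by level-synchronous BFS over the broader-direction
hierarchy: `skos:broader` and `rdfs:subClassOf` followed forward,
`skos:narrower` inverted, each ancestor reported once at its minimal level,
cycles cut by the visited set, same-level ties ordered lexicographically.
λ defaults to 3: coverage grows through roughly the 3–5 range but upper
levels of real vocabularies are increasingly generic, so the conservative
end is the default.

**URI ranking.** Concepts recovered from linked data typically resolve to
several URIs (one per source vocabulary). Each URI gets a binary feature
vector over the semantic types and groups recorded for it; its weight is
the mean cosine similarity to every *other* URI of the same concept
(unordered distinct pairs; a lone URI gets weight 1 by convention). URIs
agreeing with the group consensus rank first; URIs with no recorded
categories get zero vectors and sink to the bottom rather than erroring.
Features are binary, not counted — only membership of a category is
asserted by the sources. Ties break lexicographically so output is stable.

**Triple mining.** For each concept, a BFS of depth γ (default 5) collects
every triple asserted about nodes within γ−1 hops of the concept's primary
IRI. Traversal follows all predicates subject→object and hierarchy
predicates in both directions; literal objects are terminal. A collected
triple becomes a candidate relation when *both* endpoints resolve to
discovered concepts: an endpoint resolves to the concept with the highest
combined relatedness, provided that score is strictly positive and at
least δ (default 0.70). Endpoint resolution by best match — rather than
testing the triple against every concept pair — is what keeps a triple
asserted about concept B from being misattributed to concept A merely
because it was reached from A's neighbourhood. Duplicate
(subject, predicate, object) candidates keep the highest score. Hierarchy
predicates route to the taxonomic output (with `skos:narrower` normalized
to child→parent); everything else is non-taxonomic.

The relatedness score has four signals, each in [0, 1]:

- label: Jaccard over stemmed label tokens,
- synonym: the same over `skos:altLabel` tokens,
- definition: Jaccard over definition content-stem bags,
- hierarchy: Jaccard over *hierarchy signatures* — the node itself plus its
  λ-bounded ancestors.

The combined score is the **maximum** of the four: the threshold tests are
per-signal, so any one strong signal passes ("or" semantics); a weighted
mean would instead dilute a perfect label match with absent glosses. The
node itself is included in the hierarchy signature deliberately: Jaccard
over bare ancestor sets scores two siblings 1.0 (identical ancestors),
letting any sibling impersonate a relation endpoint at any threshold;
self-inclusion bounds sibling similarity at λ/(λ+2) — 0.6 at the default
λ=3, below the default δ=0.70 — while an identical node still scores 1.
Note the bound rises with λ (5/7 ≈ 0.71 at λ=5), so very deep signatures
erode the margin to the default threshold.

**Pattern relations.** Non-taxonomic relations are also mined from the
sentences themselves with a repository of lexico-syntactic templates, each
holding one `[X]` and one `[Y]` slot and mapped to a target-vocabulary
predicate; the package vendors six curated mappings (e.g.
`[X] causes by [Y]` → `http://schema.org/causeOf`,
`[X] treatment of [Y]` → `http://schema.org/possibleTreatment`). A pattern
matches when its literal tokens occur (case-insensitively; Porter-stem
comparison as an inflection fallback) and the adjacent slot gaps fill with
maximal discovered-concept mentions — by discovered surface, preferred
label or any synonym, so text that writes a synonym still resolves to the
concept, which is precisely what lifts recall. Matching is token-sequence
based; no constituency or dependency parse is consulted. Two of the
vendored templates (`[X] cancer [Y]`, `[X] disability [Y]`) are
linguistically odd but are shipped verbatim as curated.

**Ontology factory.** Each concept becomes an `owl:Class` whose IRI is its
top-ranked URI; remaining ranked URIs become `owl:sameAs`; preferred
label, synonyms, definitions and scheme become `skos:prefLabel`,
`skos:altLabel`, `skos:definition`, `skos:inScheme`; a synonym that
resolves to a class-typed graph node additionally yields
`owl:equivalentClass` (equivalence between a class and a plain string
would be ill-formed, so string-only synonyms stay annotations); level-1
ancestors and taxonomic candidates yield `rdfs:subClassOf`; semantic types
yield `rdf:type` assertions under the configurable base IRI (default
`urn:ontomine:`); non-taxonomic candidates become object-property
assertions under their candidate predicate. `rdfs:subClassOf` cycles — 
possible under noisy candidate sets — are broken by dropping the
lexicographically later edge, with a log line. Output serializes to Turtle
or RDF/XML; a transitive-closure helper (`subclass_closure`) demonstrates
the RDFS entailment the hierarchy supports. No OWL-DL profile validation
or further reasoning is attempted.

**Evaluation.** Precision, recall and F (harmonic mean, 0 when both vanish)
over three granularities: normalized concept surface strings (concept
*types*, not mention spans), directed (child, parent) hierarchy pairs, and
(s, p, o) triples with predicate equality by IRI. Empty predictions score
precision 0 with a warning; an empty gold set is an error, since recall is
undefined.

## Knowledge access

`KnowledgeGraph` answers all accessor queries by direct triple scans over
an rdflib graph (with a lazily built normalized-label index);
`SparqlKnowledgeGraph` answers the identical contract through paged SPARQL
SELECT queries memoised by query hash (optionally spilled to disk), and
works unchanged over rdflib's `SPARQLStore` for a remote endpoint. The test
suite exercises the SPARQL path over local in-memory stores only; remote
endpoints share the code path but are never contacted by tests. Label
matching in SPARQL mode is completed client-side so both backends apply
exactly the same normalization.

The lexicon TSV carries the four dictionary columns (`concept_id`,
`surface_form`, `semantic_type`, `semantic_group`, one row per
surface/type pair) plus an optional `iri` column that attaches semantic
categories to individual graph IRIs — per-URI categories are what the
ranking stage consumes, and a surface-keyed dictionary alone cannot
express them. Two entries claiming the same surface form are rejected at
load time.

## Synthetic study conditions

The fixture generator (`ontomine.fixtures`) is the package's test bed and
fully seeded; one integer seed reproduces graph, lexicon, ground truth and
corpora byte-for-byte. It emulates:

- class-typed concept nodes (`owl:Class`, `skos:Concept`, or both) with
  `rdfs:label` (case-varied), `skos:prefLabel`, `skos:altLabel` synonyms,
  and `skos:definition` glosses built from per-concept keyword bags — four
  private pseudo-words plus two domain keywords shared by every genuine
  concept (the signal gloss-overlap disambiguation exploits);
- a hierarchy of exactly the requested depth (a witness chain plus random
  attachments above the bottom level), planted in all three predicate
  spellings;
- non-taxonomic predicate edges between non-adjacent concepts at a
  Bernoulli rate;
- ambiguous surfaces: a fraction of concepts gains a decoy IRI sharing its
  label whose gloss bag is disjoint from every genuine and every other
  decoy gloss.

Concept names are pseudo-words minted with globally unique Porter stems,
which makes cross-concept label/synonym/definition overlap near zero: the
"bimodal" regime where planted relations score ≈1 and everything else
scores ≤ 0.6, so the default δ separates them cleanly. The corpus
generator wraps concept pairs in declarative filler whose vocabulary avoids
the pattern-repository literals (so graph mining is tested in isolation),
and always pairs an ambiguous concept with an unambiguous partner; a
separate generator instantiates pattern templates directly and returns the
expected (subject, predicate, object) set.

What the fixtures do **not** emulate — and hence what passing tests do not
show about real corpora: morphological and orthographic variation of real
biomedical terms, abbreviations, dictionary surface forms that overlap
between concepts, glosses that genuinely share vocabulary across senses,
incomplete or wrong hierarchy assertions in the source graph, and
discourse phenomena (coreference, negation). On real data the same
machinery yields precision/recall well below 1; the fixtures verify the
machinery, not the difficulty of the task.

## Defaults, degenerate inputs, determinism

| parameter | default | meaning |
|---|---|---|
| `window` | 4 | max n-gram length for candidates (1–8) |
| `lam` (λ) | 3 | ancestor depth in enrichment and hierarchy signatures |
| `gamma` (γ) | 5 | BFS depth for triple mining (1–8; warning above 5) |
| `delta` (δ) | 0.70 | combined-relatedness threshold for candidates |
| `overlap_threshold` | 1 | minimal gloss overlap to commit to a sense |
| `base_iri` | `urn:ontomine:` | namespace for minted semantic-type IRIs |

Degenerate inputs are absorbed, not raised: empty text yields a valid
ontology with only the header; a BFS start node absent from the graph
warns and returns nothing; a concept with no definitions anywhere stays
unresolved; zero-vector URIs rank last. The pipeline itself contains no
randomness — the seed exists for fixture generation — and all outputs are
emitted in sorted, deterministic order, so identical inputs give identical
bytes. Test and acceptance problem sizes (graphs of tens to a few hundred
nodes, corpora of 40–100 sentences) were chosen as the smallest scales at
which every structural property under test is non-trivially exercised.

## Known limitations

- Entity discovery is purely dictionary/graph-driven: no statistical NER,
  no abbreviation expansion, no spelling correction.
- The relatedness arithmetic (Jaccard everywhere, max combination) is a
  documented design choice; other monotone combinations would shift the
  meaning of δ.
- Pattern matching cannot span sentence boundaries and requires slot
  fillers adjacent to the literal tokens; free-word-order paraphrases are
  missed.
- The SPARQL endpoint path is code-complete but exercised only against
  local stores.
- No reasoning is performed over the *input* graph; the output entailment
  helper covers `rdfs:subClassOf` transitivity only.
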