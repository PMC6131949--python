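"""Knowledge-graph and lexicon backends.

The linked-data source (standing in for Linked Life Data / BioPortal) is any
RDF graph rdflib can parse, accessed through :class:`KnowledgeGraph`. The
UMLS-like concept dictionary is a TSV-backed :class:`Lexicon` mapping surface
forms to concept identifiers with semantic types and groups.

A :class:`SparqlKnowledgeGraph` variant answers the same accessor contract by
issuing SPARQL queries, so a remote endpoint (rdflib ``SPARQLStore``) and a
local file present one interface; query results are cached by query hash so
repeated traversals never re-ask the store.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from .textproc import normalize_text

__all__ = [
    "KBTriple",
    "KnowledgeGraph",
    "SparqlKnowledgeGraph",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "load_graph",
    "HIERARCHY_UP_PREDICATES",
    "HIERARCHY_DOWN_PREDICATES",
]

#: (subject, predicate, object) with rdflib terms; objects may be literals.
KBTriple = tuple[URIRef, URIRef, "URIRef | Literal"]

_FORMATS = {"turtle": "turtle", "ntriples": "nt", "rdfxml": "xml"}

_LABEL_PREDICATES = (RDFS.label, SKOS.altLabel, SKOS.prefLabel)

#: Predicates pointing from a concept to a *broader* concept.
HIERARCHY_UP_PREDICATES = (SKOS.broader, RDFS.subClassOf)
#: Predicates pointing from a concept to a *narrower* concept.
HIERARCHY_DOWN_PREDICATES = (SKOS.narrower,)


def load_graph(path: str | Path, format: str = "turtle") -> "KnowledgeGraph":
    """Parse an RDF file into a :class:`KnowledgeGraph`.

    ``format`` is one of ``turtle``, ``ntriples``, ``rdfxml``. Parse errors
    surface with the parser's line/position information attached.
    """
    if format not in _FORMATS:
        raise ValueError(
            f"unknown RDF format {format!r}; expected one of {sorted(_FORMATS)}"
        )
    g = Graph()
    try:
        g.parse(str(path), format=_FORMATS[format])
    except Exception as exc:  # rdflib raises several parser-specific types
        raise ValueError(f"failed to parse {path} as {format}: {exc}") from exc
    return KnowledgeGraph(g)


class KnowledgeGraph:
    """Accessor layer over an rdflib graph, treated as immutable once built."""

    def __init__(self, graph: Graph | None = None):
        self.graph = graph if graph is not None else Graph()
        self._label_index: dict[str, set[URIRef]] | None = None

    def __len__(self) -> int:
        return len(self.graph)

    def triples(self) -> set[KBTriple]:
        return set(self.graph)

    def serialize(self, destination: str | Path, format: str = "turtle") -> None:
        if format not in _FORMATS:
            raise ValueError(f"unknown RDF format {format!r}")
        text = self.graph.serialize(format=_FORMATS[format])
        Path(destination).write_text(text, encoding="utf-8")

    # -- accessors -------------------------------------------------------

    def class_iris(self) -> set[URIRef]:
        """Subjects typed ``owl:Class`` or ``skos:Concept``."""
        out: set[URIRef] = set()
        for klass in (OWL.Class, SKOS.Concept):
            out.update(
                s for s in self.graph.subjects(RDF.type, klass)
                if isinstance(s, URIRef)
            )
        return out

    def _build_label_index(self) -> dict[str, set[URIRef]]:
        index: dict[str, set[URIRef]] = {}
        for pred in _LABEL_PREDICATES:
            for s, o in self.graph.subject_objects(pred):
                if isinstance(s, URIRef) and isinstance(o, Literal):
                    index.setdefault(normalize_text(str(o)), set()).add(s)
        return index

    def lookup_by_label(self, term: str) -> set[URIRef]:
        """IRIs whose rdfs:label / skos:altLabel / skos:prefLabel equals
        ``term`` case-insensitively (after NFC + whitespace collapse)."""
        key = normalize_text(term)
        if not key:
            raise ValueError("lookup term is empty after normalization")
        if self._label_index is None:
            self._label_index = self._build_label_index()
        return set(self._label_index.get(key, ()))

    def labels_of(self, iri: URIRef) -> list[str]:
        """All label-predicate literals of ``iri`` (label, altLabel, prefLabel)."""
        out = []
        for pred in _LABEL_PREDICATES:
            out.extend(str(o) for o in self.graph.objects(iri, pred))
        return out

    def pref_labels_of(self, iri: URIRef) -> list[str]:
        return [str(o) for o in self.graph.objects(iri, SKOS.prefLabel)]

    def alt_labels_of(self, iri: URIRef) -> list[str]:
        return [str(o) for o in self.graph.objects(iri, SKOS.altLabel)]

    def definitions_of(self, iri: URIRef) -> list[str]:
        """skos:definition literals first, then skos:note literals."""
        defs = [str(o) for o in self.graph.objects(iri, SKOS.definition)]
        notes = [str(o) for o in self.graph.objects(iri, SKOS.note)]
        return defs + notes

    def hierarchy_neighbors(self, iri: URIRef, direction: str = "up") -> set[URIRef]:
        """Broader (``up``) or narrower (``down``) neighbours of ``iri``.

        skos:narrower edges are inverted so that ``up`` always means
        toward broader concepts regardless of how the graph asserted them.
        """
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        out: set[URIRef] = set()
        fwd, inv = (
            (HIERARCHY_UP_PREDICATES, HIERARCHY_DOWN_PREDICATES)
            if direction == "up"
            else (HIERARCHY_DOWN_PREDICATES, HIERARCHY_UP_PREDICATES)
        )
        for pred in fwd:
            out.update(o for o in self.graph.objects(iri, pred) if isinstance(o, URIRef))
        for pred in inv:
            out.update(s for s in self.graph.subjects(pred, iri) if isinstance(s, URIRef))
        return out


class SparqlKnowledgeGraph(KnowledgeGraph):
    """The same accessor contract, answered through SPARQL SELECT queries.

    Works over any rdflib store — an in-memory graph (used by the contract
    tests) or a remote endpoint mounted with ``SPARQLStore``. Results are
    paged with LIMIT/OFFSET and memoised by the SHA-256 of the query text,
    optionally spilled to ``cache_dir`` as JSON so re-runs stay offline.
    """

    def __init__(self, graph: Graph, page_size: int = 10_000,
                 cache_dir: str | Path | None = None):
        super().__init__(graph)
        self.page_size = page_size
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self._cache: dict[str, list[tuple[str, ...]]] = {}

    @classmethod
    def from_endpoint(cls, url: str, timeout: float = 30.0,
                      page_size: int = 10_000,
                      cache_dir: str | Path | None = None) -> "SparqlKnowledgeGraph":
        """Mount a remote SPARQL endpoint (network access happens lazily)."""
        from rdflib.plugins.stores.sparqlstore import SPARQLStore

        store = SPARQLStore(query_endpoint=url)
        if hasattr(store, "timeout"):
            store.timeout = timeout
        return cls(Graph(store=store), page_size=page_size, cache_dir=cache_dir)

    @classmethod
    def from_config(cls, config_path: str | Path) -> "SparqlKnowledgeGraph":
        """Read a YAML config with keys ``url``, ``timeout``, ``page_size``."""
        import yaml

        with open(config_path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_endpoint(
            url=cfg["url"],
            timeout=float(cfg.get("timeout", 30.0)),
            page_size=int(cfg.get("page_size", 10_000)),
            cache_dir=cfg.get("cache_dir"),
        )

    def _select(self, query: str) -> list[tuple[str, ...]]:
        key = hashlib.sha256(query.encode()).hexdigest()
        if key in self._cache:
            return self._cache[key]
        if self.cache_dir is not None:
            path = self.cache_dir / f"{key}.json"
            if path.exists():
                rows = [tuple(r) for r in json.loads(path.read_text())]
                self._cache[key] = rows
                return rows
        rows: list[tuple[str, ...]] = []
        offset = 0
        while True:
            page = list(
                self.graph.query(f"{query} LIMIT {self.page_size} OFFSET {offset}")
            )
            rows.extend(tuple(str(v) for v in row) for row in page)
            if len(page) < self.page_size:
                break
            offset += self.page_size
        self._cache[key] = rows
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            (self.cache_dir / f"{key}.json").write_text(json.dumps(rows))
        return rows

    def class_iris(self) -> set[URIRef]:
        rows = self._select(
            "SELECT ?s WHERE { ?s a ?t . VALUES ?t { "
            f"<{OWL.Class}> <{SKOS.Concept}> " "} }"
        )
        return {URIRef(r[0]) for r in rows}

    def lookup_by_label(self, term: str) -> set[URIRef]:
        key = normalize_text(term)
        if not key:
            raise ValueError("lookup term is empty after normalization")
        rows = self._select(
            "SELECT ?s ?l WHERE { ?s ?p ?l . VALUES ?p { "
            + " ".join(f"<{p}>" for p in _LABEL_PREDICATES)
            + " } }"
        )
        return {URIRef(s) for s, l in rows if normalize_text(l) == key}

    def definitions_of(self, iri: URIRef) -> list[str]:
        out = []
        for pred in (SKOS.definition, SKOS.note):
            rows = self._select(f"SELECT ?d WHERE {{ <{iri}> <{pred}> ?d }}")
            out.extend(r[0] for r in rows)
        return out

    def hierarchy_neighbors(self, iri: URIRef, direction: str = "up") -> set[URIRef]:
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        fwd, inv = (
            (HIERARCHY_UP_PREDICATES, HIERARCHY_DOWN_PREDICATES)
            if direction == "up"
            else (HIERARCHY_DOWN_PREDICATES, HIERARCHY_UP_PREDICATES)
        )
        out: set[URIRef] = set()
        for pred in fwd:
            rows = self._select(
                f"SELECT ?o WHERE {{ <{iri}> <{pred}> ?o . FILTER(isIRI(?o)) }}"
            )
            out.update(URIRef(r[0]) for r in rows)
        for pred in inv:
            rows = self._select(f"SELECT ?s WHERE {{ ?s <{pred}> <{iri}> }}")
            out.update(URIRef(r[0]) for r in rows)
        return out


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon input."""


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary concept: a CUI-like id with its surface forms and
    coarse semantic categories."""

    concept_id: str
    surface_forms: tuple[str, ...]
    semantic_types: tuple[str, ...]
    semantic_groups: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.concept_id:
            raise LexiconError("concept_id must be non-empty")
        if not self.surface_forms:
            raise LexiconError(f"{self.concept_id}: needs >= 1 surface form")
        if not self.semantic_types:
            raise LexiconError(f"{self.concept_id}: needs >= 1 semantic type")


class Lexicon:
    """Surface-form dictionary with optional per-IRI semantic categories.

    ``iri_semantics`` records which semantic types/groups a specific graph
    IRI carries; it feeds URI ranking, where different IRIs of one concept
    may belong to different categories.
    """

    def __init__(self, entries: list[LexiconEntry] | None = None,
                 iri_semantics: dict[URIRef, tuple[tuple[str, ...], tuple[str, ...]]] | None = None):
        self._entries: dict[str, LexiconEntry] = {}
        self._by_surface: dict[str, str] = {}
        self.iri_semantics = dict(iri_semantics or {})
        for entry in entries or ():
            self.add(entry)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def add(self, entry: LexiconEntry) -> None:
        if entry.concept_id in self._entries:
            raise LexiconError(f"duplicate concept id {entry.concept_id}")
        for surface in entry.surface_forms:
            key = normalize_text(surface)
            owner = self._by_surface.get(key)
            if owner is not None and owner != entry.concept_id:
                raise LexiconError(
                    f"surface form {surface!r} claimed by both "
                    f"{owner} and {entry.concept_id}"
                )
            self._by_surface[key] = entry.concept_id
        self._entries[entry.concept_id] = entry

    def lookup(self, surface: str) -> LexiconEntry | None:
        """Entry whose surface forms contain ``surface`` (case-insensitive)."""
        if not surface.strip():
            raise LexiconError("surface form is empty")
        cid = self._by_surface.get(normalize_text(surface))
        return self._entries.get(cid) if cid else None

    def by_id(self, concept_id: str) -> LexiconEntry | None:
        return self._entries.get(concept_id)

    def semantics_for_iri(self, iri: URIRef) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(semantic types, semantic groups) recorded for ``iri``; empty
        tuples when the IRI is unknown to the dictionary."""
        return self.iri_semantics.get(iri, ((), ()))

    # -- TSV round-trip --------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Load from TSV with columns concept_id, surface_form,
        semantic_type, semantic_group and an optional iri column; one row
        per (surface form, type) pair."""
        acc: dict[str, dict[str, list[str]]] = {}
        iri_sem: dict[URIRef, tuple[set[str], set[str]]] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"concept_id", "surface_form", "semantic_type"}
            missing = required - set(reader.fieldnames or ())
            if missing:
                raise LexiconError(f"lexicon TSV missing columns: {sorted(missing)}")
            for row in reader:
                cid = (row["concept_id"] or "").strip()
                surface_val = (row.get("surface_form") or "").strip()
                if cid == "__iri__" or (not surface_val and (row.get("iri") or "").strip()):
                    # IRI-semantics-only row: no dictionary entry behind it
                    iri = URIRef(row["iri"].strip())
                    types, groups = iri_sem.setdefault(iri, (set(), set()))
                    if (row.get("semantic_type") or "").strip():
                        types.add(row["semantic_type"].strip())
                    if (row.get("semantic_group") or "").strip():
                        groups.add(row["semantic_group"].strip())
                    continue
                if not cid:
                    raise LexiconError(f"row with empty concept_id: {row}")
                rec = acc.setdefault(
                    cid, {"surfaces": [], "types": [], "groups": []}
                )
                for key, col in (
                    ("surfaces", "surface_form"),
                    ("types", "semantic_type"),
                    ("groups", "semantic_group"),
                ):
                    val = (row.get(col) or "").strip()
                    if val and val not in rec[key]:
                        rec[key].append(val)
                iri = (row.get("iri") or "").strip()
                if iri:
                    types, groups = iri_sem.setdefault(URIRef(iri), (set(), set()))
                    if row.get("semantic_type", "").strip():
                        types.add(row["semantic_type"].strip())
                    if row.get("semantic_group", "").strip():
                        groups.add(row["semantic_group"].strip())
        lex = cls()
        for cid in sorted(acc):
            rec = acc[cid]
            lex.add(
                LexiconEntry(
                    concept_id=cid,
                    surface_forms=tuple(rec["surfaces"]),
                    semantic_types=tuple(rec["types"]),
                    semantic_groups=tuple(rec["groups"]),
                )
            )
        lex.iri_semantics = {
            iri: (tuple(sorted(t)), tuple(sorted(g)))
            for iri, (t, g) in iri_sem.items()
        }
        return lex

    def to_tsv(self, path: str | Path) -> None:
        iri_by_pair: dict[tuple[str, str], list[str]] = {}
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["concept_id", "surface_form", "semantic_type", "semantic_group", "iri"]
            )
            iri_rows = sorted(
                (str(iri), t, g)
                for iri, (types, groups) in self.iri_semantics.items()
                for t in types
                for g in (groups or ("",))
            )
            emitted: set[tuple[str, str, str, str, str]] = set()
            for entry in sorted(self, key=lambda e: e.concept_id):
                groups = entry.semantic_groups or ("",)
                for surface in entry.surface_forms:
                    for stype in entry.semantic_types:
                        for group in groups:
                            row = (entry.concept_id, surface, stype, group, "")
                            if row not in emitted:
                                emitted.add(row)
                                writer.writerow(row)
            for iri, stype, group in iri_rows:
                # IRI semantics rows carry a placeholder concept id scope
                writer.writerow(["__iri__", "", stype, group, iri])

    def copy_with_iri_semantics(
        self, iri_semantics: dict[URIRef, tuple[tuple[str, ...], tuple[str, ...]]]
    ) -> "Lexicon":
        lex = Lexicon(list(self), iri_semantics)
        return lex
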