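"""Knowledge-graph accessors, lexicon behaviour, and the SPARQL contract."""

import random

import pytest
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from ontomine import (
    KnowledgeGraph,
    Lexicon,
    LexiconEntry,
    LexiconError,
    SparqlKnowledgeGraph,
    generate_fixture_kb,
    load_graph,
)

from conftest import EX, make_kb

BIO = Namespace("http://bio.example.org/")
LLD = "http://linkedlifedata.com/resource/umls/id/"


class TestLoadGraph:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.ttl"
        path.write_text("")
        assert len(load_graph(path, "turtle")) == 0

    def test_three_triple_turtle(self, tmp_path):
        path = tmp_path / "three.ttl"
        path.write_text(
            "@prefix ex: <http://example.org/> .\n"
            "ex:a ex:p ex:b .\nex:a ex:q ex:c .\nex:b ex:p ex:c .\n"
        )
        assert len(load_graph(path, "turtle")) == 3

    @pytest.mark.parametrize("fmt", ["turtle", "ntriples", "rdfxml"])
    def test_roundtrip_is_fixed_point(self, tmp_path, standard_fixture, fmt):
        kb, _, _ = standard_fixture
        path = tmp_path / f"kb.{fmt}"
        kb.serialize(path, fmt)
        reloaded = load_graph(path, fmt)
        assert reloaded.triples() == kb.triples()

    def test_parse_failure_reports_position(self, tmp_path):
        path = tmp_path / "broken.ttl"
        path.write_text("@prefix ex: <http://example.org/> .\nex:a ex:p")
        with pytest.raises(ValueError, match="failed to parse"):
            load_graph(path, "turtle")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown RDF format"):
            load_graph(tmp_path / "x", "jsonld")


class TestClassIris:
    def test_owl_class_typing(self):
        kb = make_kb([(BIO.Antiandrogenic, RDF.type, OWL.Class)])
        assert BIO.Antiandrogenic in kb.class_iris()

    def test_skos_concept_typing(self):
        kb = make_kb([(EX.c1, RDF.type, SKOS.Concept), (EX.c2, RDF.type, EX.Other)])
        assert kb.class_iris() == {EX.c1}

    def test_empty_graph(self):
        assert make_kb([]).class_iris() == set()

    def test_matches_brute_force_scan(self, standard_fixture):
        kb, _, _ = standard_fixture
        expected = {
            s
            for s, p, o in kb.triples()
            if p == RDF.type and o in (OWL.Class, SKOS.Concept)
        }
        assert kb.class_iris() == expected


class TestLookupByLabel:
    @pytest.fixture()
    def ileus_kb(self):
        # several vocabulary URIs sharing the label of one clinical concept
        uris = [
            URIRef(LLD + "C1258215"),
            URIRef(LLD + "C0030446"),
            URIRef("http://linkedlifedata.com/resource/diseaseontology/id/DOID:8440"),
        ]
        triples = [(u, RDFS.label, Literal("Ileus")) for u in uris]
        triples.append((uris[0], SKOS.prefLabel, Literal("ileus")))
        return make_kb(triples), uris

    def test_known_concept_label(self, ileus_kb):
        kb, uris = ileus_kb
        found = kb.lookup_by_label("ileus")
        assert URIRef(LLD + "C1258215") in found
        assert found == set(uris)

    def test_absent_term(self, ileus_kb):
        kb, _ = ileus_kb
        assert kb.lookup_by_label("volvulus") == set()

    def test_case_insensitive_equals_lowercase_oracle(self, standard_fixture):
        kb, _, truth = standard_fixture
        for surface in sorted(truth.concept_surfaces)[:5]:
            mixed = surface.title()
            assert kb.lookup_by_label(mixed) == kb.lookup_by_label(surface.lower())

    def test_label_altlabel_preflabel_all_match(self):
        kb = make_kb([
            (EX.a, RDFS.label, Literal("alpha")),
            (EX.b, SKOS.altLabel, Literal("alpha")),
            (EX.c, SKOS.prefLabel, Literal("Alpha")),
        ])
        assert kb.lookup_by_label("ALPHA") == {EX.a, EX.b, EX.c}


class TestDefinitionsOf:
    def test_single_definition(self):
        kb = make_kb([(EX.a, SKOS.definition, Literal("an obstruction"))])
        assert kb.definitions_of(EX.a) == ["an obstruction"]

    def test_definitions_before_notes(self):
        kb = make_kb([
            (EX.a, SKOS.definition, Literal("def one")),
            (EX.a, SKOS.definition, Literal("def two")),
            (EX.a, SKOS.note, Literal("a note")),
        ])
        out = kb.definitions_of(EX.a)
        assert len(out) == 3
        assert out[2] == "a note"
        assert set(out[:2]) == {"def one", "def two"}

    def test_unknown_iri(self):
        assert make_kb([]).definitions_of(EX.nothing) == []


class TestHierarchyNeighbors:
    def test_leaf_single_broader_parent(self):
        kb = make_kb([(EX.child, SKOS.broader, EX.parent)])
        assert kb.hierarchy_neighbors(EX.child, "up") == {EX.parent}

    def test_union_of_predicates_and_narrower_inversion(self):
        kb = make_kb([
            (EX.c, SKOS.broader, EX.p1),
            (EX.c, RDFS.subClassOf, EX.p2),
            (EX.p3, SKOS.narrower, EX.c),
        ])
        assert kb.hierarchy_neighbors(EX.c, "up") == {EX.p1, EX.p2, EX.p3}
        # down is the exact inverse
        for parent in (EX.p1, EX.p2, EX.p3):
            assert EX.c in kb.hierarchy_neighbors(parent, "down")

    def test_root_has_no_parents(self):
        kb = make_kb([(EX.child, SKOS.broader, EX.root)])
        assert kb.hierarchy_neighbors(EX.root, "up") == set()

    def test_agrees_with_linear_scan(self, standard_fixture):
        kb, _, truth = standard_fixture
        up_preds = {SKOS.broader, RDFS.subClassOf}
        for iri in list(truth.concept_iris.values())[:10]:
            expected = {
                o for s, p, o in kb.triples() if s == iri and p in up_preds
            } | {s for s, p, o in kb.triples() if o == iri and p == SKOS.narrower}
            assert kb.hierarchy_neighbors(iri, "up") == expected


class TestLexicon:
    def make_lexicon(self):
        return Lexicon([
            LexiconEntry("C001", ("diabetes mellitus", "DM"), ("Disease or Syndrome",), ("Disorders",)),
            LexiconEntry("C002", ("aspirin",), ("Pharmacologic Substance",), ("Chemicals & Drugs",)),
        ])

    def test_missing_surface_is_absent(self):
        # dictionary gaps exist: some surfaces only live in the graph
        assert self.make_lexicon().lookup("Antiandrogenic") is None

    def test_verbatim_surface_found(self):
        assert self.make_lexicon().lookup("aspirin").concept_id == "C002"

    def test_case_insensitive_match(self):
        entry = self.make_lexicon().lookup("Diabetes Mellitus")
        assert entry is not None and entry.concept_id == "C001"

    def test_conflicting_surface_claims_rejected(self):
        lex = self.make_lexicon()
        with pytest.raises(LexiconError, match="claimed by both"):
            lex.add(LexiconEntry("C003", ("aspirin",), ("Finding",)))

    def test_entry_needs_type_and_surface(self):
        with pytest.raises(LexiconError):
            LexiconEntry("C009", (), ("Finding",))
        with pytest.raises(LexiconError):
            LexiconEntry("C009", ("x",), ())

    def test_tsv_roundtrip(self, tmp_path, standard_fixture):
        _, lexicon, _ = standard_fixture
        path = tmp_path / "lexicon.tsv"
        lexicon.to_tsv(path)
        reloaded = Lexicon.from_tsv(path)
        assert {e.concept_id for e in reloaded} == {e.concept_id for e in lexicon}
        for entry in lexicon:
            other = reloaded.by_id(entry.concept_id)
            assert set(other.surface_forms) == set(entry.surface_forms)
            assert set(other.semantic_types) == set(entry.semantic_types)
        assert set(reloaded.iri_semantics) == set(lexicon.iri_semantics)
        for iri, (types, groups) in lexicon.iri_semantics.items():
            rtypes, rgroups = reloaded.iri_semantics[iri]
            assert set(rtypes) == set(types) and set(rgroups) == set(groups)


class TestSparqlContract:
    """File backend and SPARQL backend must answer identically."""

    def test_accessors_agree_on_fixture(self, standard_fixture):
        kb, _, truth = standard_fixture
        sparql = SparqlKnowledgeGraph(kb.graph)
        assert sparql.class_iris() == kb.class_iris()
        surfaces = sorted(truth.concept_surfaces)[:5]
        for surface in surfaces:
            assert sparql.lookup_by_label(surface) == kb.lookup_by_label(surface)
        for iri in list(truth.concept_iris.values())[:5]:
            assert sparql.definitions_of(iri) == kb.definitions_of(iri)
            assert sparql.hierarchy_neighbors(iri, "up") == kb.hierarchy_neighbors(iri, "up")
            assert sparql.hierarchy_neighbors(iri, "down") == kb.hierarchy_neighbors(iri, "down")

    def test_query_cache_hits_are_stable(self, standard_fixture, tmp_path):
        kb, _, _ = standard_fixture
        sparql = SparqlKnowledgeGraph(kb.graph, cache_dir=tmp_path)
        first = sparql.class_iris()
        # second instance reads from the on-disk cache
        again = SparqlKnowledgeGraph(kb.graph, cache_dir=tmp_path).class_iris()
        assert first == again
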