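"""BFS neighbourhood, relatedness signals, and triple candidate mining."""

import random
import warnings

import networkx as nx
import pytest
from rdflib import Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from ontomine import (
    Lexicon,
    bfs_neighborhood,
    extract_triples,
    generate_fixture_kb,
    relatedness,
)
from ontomine.triples import hierarchy_pair, split_candidates

from conftest import EX, concept_node, enriched, make_kb

REL = Namespace("http://fixture.ontomine.dev/rel/")


class TestBfsNeighborhood:
    def chain(self):
        return make_kb([
            (EX.a, EX.p, EX.b),
            (EX.b, EX.p, EX.c),
            (EX.c, EX.p, EX.d),
        ])

    def test_depth_one_is_subject_triples_only(self):
        kb = make_kb([
            (EX.a, EX.p, EX.b),
            (EX.a, EX.q, Literal("text")),
            (EX.b, EX.p, EX.c),
        ])
        out = bfs_neighborhood(kb, EX.a, gamma=1)
        assert {t for t, _ in out} == {
            (EX.a, EX.p, EX.b),
            (EX.a, EX.q, Literal("text")),
        }
        assert all(hop == 1 for _, hop in out)

    def test_chain_depth_two(self):
        out = bfs_neighborhood(self.chain(), EX.a, gamma=2)
        assert {t for t, _ in out} == {(EX.a, EX.p, EX.b), (EX.b, EX.p, EX.c)}

    def test_monotone_in_gamma(self):
        kb = self.chain()
        previous: set = set()
        for gamma in range(1, 6):
            current = {t for t, _ in bfs_neighborhood(kb, EX.a, gamma)}
            assert previous <= current
            previous = current

    def test_hierarchy_edges_walked_both_ways(self):
        # c --broader--> a: reachable from a against the edge direction
        kb = make_kb([(EX.c, SKOS.broader, EX.a), (EX.c, EX.p, EX.d)])
        out = {t for t, _ in bfs_neighborhood(kb, EX.a, gamma=2)}
        assert (EX.c, EX.p, EX.d) in out

    def test_missing_start_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="not present"):
            assert bfs_neighborhood(self.chain(), EX.zzz, gamma=2) == []

    def test_literals_are_terminal(self):
        kb = make_kb([(EX.a, EX.p, Literal("leaf")), (EX.a, EX.p, EX.b)])
        out = bfs_neighborhood(kb, EX.a, gamma=5)
        assert len(out) == 2  # the literal spawned no further expansion

    def test_matches_distance_labelled_oracle(self):
        rng = random.Random(29)
        preds = [EX.p, EX.q, SKOS.broader, RDFS.subClassOf, SKOS.narrower]
        for trial in range(25):
            n = rng.randint(5, 80)
            nodes = [EX[f"t{trial}n{i}"] for i in range(n)]
            triples = set()
            for _ in range(n * 2):
                s, o = rng.sample(nodes, 2)
                triples.add((s, rng.choice(preds), o))
            kb = make_kb(triples)
            gamma = rng.randint(1, 5)
            start = nodes[0]

            walk = nx.DiGraph()
            walk.add_nodes_from(nodes)
            for s, p, o in triples:
                walk.add_edge(s, o)
                if p in (SKOS.broader, RDFS.subClassOf, SKOS.narrower):
                    walk.add_edge(o, s)
            dist = nx.single_source_shortest_path_length(
                walk, start, cutoff=gamma - 1
            )
            expected = {
                (t, dist[t[0]] + 1) for t in triples if t[0] in dist
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = set(bfs_neighborhood(kb, start, gamma))
            assert got == expected


class TestRelatedness:
    def test_own_iri_is_perfect_match(self):
        kb = make_kb([])
        concept_node(kb.graph, EX.a, "fever", "elevated body temperature")
        target = enriched(kb, "fever", [EX.a])
        assert relatedness(EX.a, target, kb).combined == 1.0

    def test_fully_disjoint_scores_zero(self):
        kb = make_kb([])
        concept_node(kb.graph, EX.a, "fever", "elevated body temperature", alt="pyrexia")
        concept_node(kb.graph, EX.b, "aspirin", "salicylate analgesic drug", alt="asa")
        target = enriched(kb, "fever", [EX.a])
        assert relatedness(EX.b, target, kb).combined == 0.0

    def test_definition_jaccard_three_of_five_shared(self):
        # bags of 5 stems each sharing 3: Jaccard 3/7; no other signal
        kb = make_kb([])
        concept_node(kb.graph, EX.a, "alpha", "nausea vomiting fatigue rash fever")
        concept_node(kb.graph, EX.b, "beta", "nausea vomiting fatigue chill cough")
        target = enriched(kb, "alpha", [EX.a])
        score = relatedness(EX.b, target, kb)
        assert score.definition_score == pytest.approx(3 / 7)
        assert score.combined == pytest.approx(3 / 7)
        assert score.label_score == 0.0 and score.hierarchy_score == 0.0

    def test_synonym_signal_uses_alt_labels(self):
        kb = make_kb([])
        concept_node(kb.graph, EX.a, "fever", "heat", alt="pyrexia")
        concept_node(kb.graph, EX.b, "calor", "warmth", alt="pyrexia")
        target = enriched(kb, "fever", [EX.a])
        score = relatedness(EX.b, target, kb)
        assert score.synonym_score == pytest.approx(1.0)

    def test_missing_facets_score_zero_components(self):
        kb = make_kb([])
        concept_node(kb.graph, EX.a, "fever", "elevated body temperature")
        bare = URIRef("http://example.org/kb/bare")
        kb.graph.add((bare, EX.p, EX.a))
        target = enriched(kb, "fever", [EX.a])
        score = relatedness(bare, target, kb)
        assert score.label_score == 0.0
        assert score.definition_score == 0.0


def two_concept_kb(delta_engineered=False):
    kb = make_kb([])
    g = kb.graph
    concept_node(g, EX.aspirin, "aspirin", "salicylate analgesic platelet drug")
    if delta_engineered:
        # definition bags of 8 and 9 stems sharing 7: Jaccard 7/10 = 0.70
        concept_node(
            g, EX.headache,
            "headache", "pain head pressure tension episode onset nausea chronic",
        )
        concept_node(
            g, EX.target,
            "cephalalgia", "pain head pressure tension episode onset nausea dull mild",
        )
        g.add((EX.aspirin, REL.relievesSign, EX.target))
    else:
        concept_node(g, EX.headache, "headache", "pain head pressure")
        g.add((EX.aspirin, REL.treats, EX.headache))
    return kb


class TestExtractTriples:
    def test_direct_edge_yields_one_candidate(self):
        kb = two_concept_kb()
        concepts = [enriched(kb, "aspirin", [EX.aspirin]),
                    enriched(kb, "headache", [EX.headache])]
        out = extract_triples(concepts, kb, gamma=5, delta=0.70)
        assert len(out) == 1
        cand = out[0]
        assert cand.predicate == REL.treats
        assert cand.subject.surface == "aspirin"
        assert cand.object.surface == "headache"
        assert cand.provenance == "graph_mined"
        assert cand.score.combined >= 0.70

    def test_threshold_boundary_at_engineered_relatedness(self):
        kb = two_concept_kb(delta_engineered=True)
        concepts = [enriched(kb, "aspirin", [EX.aspirin]),
                    enriched(kb, "headache", [EX.headache])]
        at = extract_triples(concepts, kb, gamma=5, delta=0.70)
        above = extract_triples(concepts, kb, gamma=5, delta=0.71)
        assert [c.predicate for c in at] == [REL.relievesSign]
        assert at[0].score.combined == pytest.approx(0.70)
        assert above == []

    def test_planted_cross_edges_recovered_exactly_at_delta_zero(self):
        kb, lexicon, truth = generate_fixture_kb(
            n_concepts=12, hierarchy_depth=0, cross_edge_rate=0.15,
            ambiguity_rate=0.0, seed=31,
        )
        concepts = [
            enriched(kb, s, [truth.concept_iris[s]], lexicon)
            for s in sorted(truth.concept_surfaces)
        ]
        out = extract_triples(concepts, kb, gamma=5, delta=0.0)
        _, non_tax = split_candidates(out)
        got = {
            (c.subject.surface_key, c.predicate, c.object.surface_key)
            for c in non_tax
        }
        expected = {
            (s, URIRef(p), o) for s, p, o in truth.cross_surface_triples()
        }
        assert got == expected
        assert len(non_tax) == len(truth.cross_edges)

    def test_taxonomic_candidates_routed_and_normalized(self):
        kb = make_kb([])
        concept_node(kb.graph, EX.child, "gastric ulcer", "stomach lesion mucosa")
        concept_node(kb.graph, EX.parent, "ulcer", "lesion erosion tissue")
        kb.graph.add((EX.parent, SKOS.narrower, EX.child))
        concepts = [enriched(kb, "gastric ulcer", [EX.child]),
                    enriched(kb, "ulcer", [EX.parent])]
        out = extract_triples(concepts, kb, gamma=2, delta=0.7)
        tax, non = split_candidates(out)
        assert non == []
        assert len(tax) == 1
        child, parent = hierarchy_pair(tax[0])
        assert child.surface == "gastric ulcer"
        assert parent.surface == "ulcer"

    def test_no_self_relations(self, standard_fixture):
        kb, lexicon, truth = standard_fixture
        concepts = [
            enriched(kb, s, [truth.concept_iris[s]], lexicon)
            for s in sorted(truth.concept_surfaces)
        ]
        for delta in (0.0, 0.7):
            for cand in extract_triples(concepts, kb, gamma=3, delta=delta):
                assert cand.subject.primary_iri != cand.object.primary_iri

    def test_antitone_in_delta_monotone_in_gamma(self, standard_fixture):
        kb, lexicon, truth = standard_fixture
        concepts = [
            enriched(kb, s, [truth.concept_iris[s]], lexicon)
            for s in sorted(truth.concept_surfaces)[:10]
        ]

        def keys(cands):
            return {
                (c.subject.surface_key, c.predicate, c.object.surface_key)
                for c in cands
            }

        previous = None
        for delta in (0.0, 0.5, 0.7, 0.9):
            current = keys(extract_triples(concepts, kb, gamma=3, delta=delta))
            if previous is not None:
                assert current <= previous
            previous = current

        previous = None
        for gamma in range(1, 5):
            current = keys(extract_triples(concepts, kb, gamma=gamma, delta=0.7))
            if previous is not None:
                assert previous <= current
            previous = current

    def test_gamma_bounds(self):
        kb = two_concept_kb()
        concepts = [enriched(kb, "aspirin", [EX.aspirin]),
                    enriched(kb, "headache", [EX.headache])]
        with pytest.raises(ValueError):
            extract_triples(concepts, kb, gamma=0)
        with pytest.raises(ValueError):
            extract_triples(concepts, kb, gamma=9)
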