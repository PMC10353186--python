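"""Provenance knowledge-graph tests: extract loading, deterministic graph
construction, Turtle round-trips, and the three competency queries."""

import pytest

from semcds import fixtures, provenance
from semcds.errors import NotFoundError, ValidationError, VocabularyError


def small_bundle(n=10, seed=7):
    return fixtures.gen_guideline_extract(n, seed=seed)


def make_extract(rec_id="r1", guideline_id="g1", year=2018, grade="A",
                 sentences=(), chapter="Pharmacologic Approaches"):
    return provenance.GuidelineExtract(
        guideline_id=guideline_id,
        guideline_title=f"Guideline {guideline_id}",
        publication_year=year,
        chapter=chapter,
        recommendation_id=rec_id,
        recommendation_text=f"Text of {rec_id}",
        grade=grade,
        disease_label="type 2 diabetes",
        disease_code="DOID:9352",
        evidence_sentences=tuple(sentences),
    )


def sentence(index, *keys):
    return provenance.EvidenceSentence(index, f"Sentence {index}.", tuple(keys))


def citation(key, authors=("Adams J",), year=2001):
    return provenance.Citation(
        citation_key=key, title=f"Trial {key}", authors=tuple(authors),
        venue="Diabetes Care", year=year, external_id=f"pmid-{key}",
    )


class TestLoadExtract:
    def test_round_trip_through_csv_bundle(self, tmp_path):
        bundle = small_bundle(n=25, seed=1)
        bundle.write(tmp_path)
        extracts, citations = provenance.load_extract(tmp_path)
        assert len(extracts) == 25 == bundle.tallies["n_recommendations"]
        assert len(citations) == bundle.tallies["n_citations"]
        assert sum(len(e.evidence_sentences) for e in extracts) == \
            bundle.tallies["n_sentences"]

    def test_dangling_citation_names_the_key(self, tmp_path):
        bundle = small_bundle(n=2)
        bundle.write(tmp_path)
        sent = tmp_path / "sentences.csv"
        sent.write_text(
            "recommendation_id,sentence_index,sentence_text,citation_keys\n"
            "rec-000,0,Bad sentence.,c99\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match="c99"):
            provenance.load_extract(tmp_path)

    def test_duplicate_recommendation_id_rejected(self, tmp_path):
        bundle = small_bundle(n=1)
        bundle.write(tmp_path)
        recs = tmp_path / "recommendations.csv"
        text = recs.read_text(encoding="utf-8")
        recs.write_text(text + text.splitlines()[1] + "\n", encoding="utf-8")
        with pytest.raises(ValidationError, match="duplicate recommendation_id"):
            provenance.load_extract(tmp_path)

    def test_missing_column_is_parse_error(self, tmp_path):
        bundle = small_bundle(n=1)
        bundle.write(tmp_path)
        (tmp_path / "citations.csv").write_text("citation_key\nc000\n", encoding="utf-8")
        with pytest.raises(ValidationError, match="missing required column"):
            provenance.load_extract(tmp_path)

    def test_citation_requires_an_author(self):
        with pytest.raises(ValidationError, match="at least one author"):
            provenance.Citation("c1", "Title", authors=())


class TestBuildGraph:
    def test_minimal_counting_contract(self):
        cits = [citation("c1"), citation("c2", authors=("Baker L",))]
        ext = make_extract(sentences=[sentence(0, "c1", "c2")])
        link = provenance.FormalRuleLink("rule-1", "r1", note="maps r1")
        graph = provenance.build_graph([ext], cits, [link])
        counts = graph.node_counts()
        assert counts["Recommendation"] == 1
        assert counts["EvidenceSentence"] == 1
        assert counts["Citation"] == 2
        assert counts["Grade"] == 1
        assert counts["FormalRule"] == 1
        assert graph.arc_count(provenance.PROV.wasDerivedFrom) == 1

    def test_empty_inputs_serialize_to_valid_prefix_only_turtle(self):
        graph = provenance.build_graph([], [])
        assert len(graph) == 0
        text = graph.serialize()
        reparsed = provenance.ProvenanceGraph()
        reparsed.graph.parse(data=text, format="turtle")
        assert len(reparsed.graph) == 0

    def test_triple_count_matches_closed_form(self):
        bundle = small_bundle(n=20, seed=7)
        graph = provenance.build_graph(bundle.extracts, bundle.citations,
                                       bundle.rule_links)
        expected = provenance.expected_counts(bundle.extracts, bundle.citations,
                                              bundle.rule_links)
        assert len(graph) == expected["triples"]
        counts = graph.node_counts()
        for cls in ("Guideline", "Recommendation", "FormalRule", "EvidenceSentence",
                    "Citation", "Grade", "DiseaseManagement", "Author"):
            assert counts[cls] == expected[cls], cls
        assert graph.arc_count(provenance.PROV.wasDerivedFrom) == \
            expected["wasDerivedFrom_arcs"]

    def test_unresolved_rule_link_rejected(self):
        with pytest.raises(ValidationError, match="unknown recommendation"):
            provenance.build_graph(
                [make_extract()], [], [provenance.FormalRuleLink("rule-1", "nope")]
            )

    def test_turtle_round_trip_is_isomorphic(self, tmp_path):
        bundle = small_bundle(n=15, seed=3)
        graph = provenance.build_graph(bundle.extracts, bundle.citations,
                                       bundle.rule_links)
        path = tmp_path / "graph.ttl"
        graph.serialize(path)
        assert graph.isomorphic_to(provenance.ProvenanceGraph.parse(path))

    def test_repeated_builds_are_byte_identical(self):
        bundle = small_bundle(n=8, seed=5)
        first = provenance.build_graph(bundle.extracts, bundle.citations,
                                       bundle.rule_links).serialize()
        second = provenance.build_graph(bundle.extracts, bundle.citations,
                                        bundle.rule_links).serialize()
        assert first == second

    def test_adding_an_extract_never_removes_triples(self):
        ext_a = make_extract("rA", guideline_id="gA")
        ext_b = make_extract("rB", guideline_id="gB")
        graph_a = provenance.build_graph([ext_a], [])
        graph_ab = provenance.build_graph([ext_a, ext_b], [])
        assert all(t in graph_ab.graph for t in graph_a.graph)


class TestQueries:
    def test_source_of_returns_linked_recommendation(self):
        ext = make_extract(chapter="Pharmacologic Approaches")
        graph = provenance.build_graph(
            [ext], [], [provenance.FormalRuleLink("rule-1", "r1")]
        )
        answers = provenance.query_source_of(graph, "rule-1")
        assert answers == [{
            "recommendation_id": "r1",
            "recommendation_text": "Text of r1",
            "chapter": "Pharmacologic Approaches",
            "guideline_title": "Guideline g1",
            "explanation_type": "trace-based",
        }]

    def test_rule_with_two_links_returns_both_order_stable(self):
        exts = [make_extract("r1"), make_extract("r2")]
        links = [provenance.FormalRuleLink("rule-1", "r2"),
                 provenance.FormalRuleLink("rule-1", "r1")]
        graph = provenance.build_graph(exts, [], links)
        ids = [a["recommendation_id"] for a in provenance.query_source_of(graph, "rule-1")]
        assert ids == ["r1", "r2"]

    def test_unknown_rule_id_not_found(self):
        graph = provenance.build_graph([make_extract()], [])
        with pytest.raises(NotFoundError):
            provenance.query_source_of(graph, "ghost")

    def test_evidence_deduplicates_shared_citation(self):
        cits = [citation("c1")]
        ext = make_extract(sentences=[sentence(0, "c1"), sentence(1, "c1")])
        graph = provenance.build_graph([ext], cits)
        answer = provenance.query_evidence_for(graph, "r1")
        assert [c["citation_key"] for c in answer["citations"]] == ["c1"]
        assert answer["grade"] == "A"
        assert answer["explanation_type"] == "scientific"

    def test_recommendation_without_sentences_keeps_grade(self):
        graph = provenance.build_graph([make_extract(grade="B")], [])
        answer = provenance.query_evidence_for(graph, "r1")
        assert answer["citations"] == [] and answer["grade"] == "B"

    def test_query_equals_bruteforce_scan_over_extract_tables(self):
        bundle = small_bundle(n=30, seed=9)
        graph = provenance.build_graph(bundle.extracts, bundle.citations,
                                       bundle.rule_links)
        for ext in bundle.extracts:
            expected_keys = sorted(
                {k for s in ext.evidence_sentences for k in s.citations}
            )
            answer = provenance.query_evidence_for(graph, ext.recommendation_id)
            assert [c["citation_key"] for c in answer["citations"]] == expected_keys
            assert answer["grade"] == ext.grade
        for link in bundle.rule_links:
            expected = sorted(
                l.recommendation_id for l in bundle.rule_links
                if l.rule_id == link.rule_id
            )
            got = [a["recommendation_id"]
                   for a in provenance.query_source_of(graph, link.rule_id)]
            assert got == expected

    def test_recency_single_and_multi_edition(self):
        exts = [make_extract("r1", guideline_id="g2018", year=2018),
                make_extract("r1", guideline_id="g2019", year=2019)]
        graph = provenance.build_graph(exts, [])
        answer = provenance.query_recency(graph, "r1")
        assert answer["years"] == [2019, 2018]
        assert answer["recency"] == 2019

    def test_missing_year_yields_unknown_marker(self):
        graph = provenance.build_graph([make_extract(year=None)], [])
        assert provenance.query_recency(graph, "r1")["recency"] == "unknown"


class TestExplanationLabels:
    def test_contrastive_label_stored_and_retrievable(self):
        graph = provenance.build_graph([make_extract()], [])
        provenance.tag_explanation(graph, "r1", "contrastive", "vs usual care")
        assert provenance.explanations_of(graph, "r1") == ["contrastive"]

    def test_label_outside_nine_value_vocabulary_rejected(self):
        graph = provenance.build_graph([make_extract()], [])
        with pytest.raises(VocabularyError):
            provenance.tag_explanation(graph, "r1", "causal")

    def test_staging_trace_auto_tags_trace_based(self, bcs7):
        from semcds import staging

        result = staging.infer_stage(staging.TnmCategory("T1", "N0", "M0"), bcs7)
        label = provenance.explanation_for_result(result)
        assert label.label == "trace-based"
        assert label.subject_id == result.rule_id
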