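"""IRI minting and RDF instance-graph conversion."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdflib import BNode
from rdflib.namespace import RDF

import biodivlink as b
from biodivlink.ontology import REL, TERM

from conftest import DEFAULT_SPEC

BASE = "https://example.org/data/"


class TestMintIri:
    def test_deterministic(self):
        assert b.mint_iri(BASE, "sample", "s1") == b.mint_iri(BASE, "sample", "s1")

    def test_distinct_kinds_distinct_iris(self):
        assert b.mint_iri(BASE, "sample", "s1") != b.mint_iri(BASE, "extract", "s1")

    def test_reserved_characters_encoded(self):
        iri = b.mint_iri(BASE, "sample", "sample A/1")
        local = str(iri)[len(BASE) + len("sample/") :]
        assert " " not in local and "/" not in local
        assert local == "sample%20A%2F1"

    def test_empty_name_rejected(self):
        with pytest.raises(b.ConversionError):
            b.mint_iri(BASE, "sample", "")

    @given(
        name=st.text(min_size=1, max_size=30),
        other=st.text(min_size=1, max_size=30),
    )
    @settings(max_examples=100, derandomize=True)
    def test_injective_on_names(self, name, other):
        a = b.mint_iri(BASE, "k", name)
        c = b.mint_iri(BASE, "k", other)
        assert (a == c) == (name == other)


class TestConvertWorkflow:
    def test_survey_achieves_biodiversity_objective(self, default_graph):
        table = b.run_sparql(
            default_graph,
            """
            PREFIX rel: <https://w3id.org/biodivlink/relation/>
            PREFIX term: <https://w3id.org/biodivlink/term/>
            ASK {
              ?a rel:achieves_planned_objective ?o .
              ?o a term:biodiversity-assessment-objective .
            }
            """,
        )
        assert table.rows == [("true",)]

    def test_three_samples_make_three_library_preparations(self, default_graph, vocab):
        counts = default_graph.count_individuals_by_class(vocab)
        assert counts["library preparation"] == 3

    def test_empty_graph_is_an_error(self):
        empty = b.WorkflowGraph({}, [], "assay", [], 0)
        with pytest.raises(b.ConversionError, match="nothing to convert"):
            b.convert_workflow(empty)

    def test_strict_mode_names_unmapped_protocol(self):
        text = (
            "Sample Name\tProtocol REF\tRaw Data File\n"
            "s1\tarcane ritual\tf1\n"
        )
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        with pytest.raises(b.ConversionError, match="arcane ritual"):
            b.convert_workflow(graph, config=b.ConversionConfig(strict=True))

    def test_lenient_mode_warns_and_leaves_untyped(self, vocab):
        text = "Sample Name\tProtocol REF\tRaw Data File\ns1\tarcane ritual\tf1\n"
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        with pytest.warns(UserWarning, match="arcane ritual"):
            out = b.convert_workflow(graph)
        process_types = {
            o
            for s, o in out.graph.subject_objects(RDF.type)
            if "process" in str(s)
        }
        assert process_types == set()

    def test_unsplittable_primer_value_warns(self):
        text = (
            "Sample Name\tProtocol REF\tParameter Value[pcr_primers]\tRaw Data File\n"
            "s1\tpolymerase chain reaction\t27F/1492R\tf1\n"
        )
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        with pytest.warns(UserWarning, match="unsplittable"):
            out = b.convert_workflow(graph)
        primers = [s for s in out.graph.subjects() if "/primer/" in str(s)]
        assert len(set(primers)) == 1

    def test_no_blank_nodes(self, default_graph):
        for triple in default_graph:
            assert not any(isinstance(t, BNode) for t in triple)

    def test_all_types_resolve_in_vocabulary(self, default_graph, vocab):
        known = {t.iri for t in vocab.terms.values()}
        for _, o in default_graph.graph.subject_objects(RDF.type):
            assert str(o) in known

    def test_primers_only_reachable_as_process_inputs(self, conversion_factory, vocab):
        graph = conversion_factory(b.FixtureSpec(3, 2, multiplexed=True, seed=42)).graph
        primer_classes = {vocab.term_iri("forward pcr primer"), vocab.term_iri("reverse pcr primer")}
        primers = {s for s, o in graph.subject_objects(RDF.type) if o in primer_classes}
        assert primers
        for primer in primers:
            incoming = set(graph.predicates(None, primer))
            assert incoming == {REL["has_specified_input"]}
            for process in graph.subjects(REL["has_specified_input"], primer):
                assert (process, RDF.type, vocab.term_iri("polymerase chain reaction")) in graph

    def test_precedes_is_strict_partial_order(self, default_graph):
        import networkx as nx

        g = nx.DiGraph(
            (s, o) for s, _, o in default_graph.graph.triples((None, REL["precedes"], None))
        )
        assert nx.is_directed_acyclic_graph(g)

    def test_per_row_precedes_total_order(self, workflow_factory, conversion_factory):
        # along each row, every adjacent process pair is ordered
        spec = DEFAULT_SPEC
        graph = conversion_factory(spec).graph
        wf = workflow_factory(spec)
        n_precedes = len(list(graph.triples((None, REL["precedes"], None))))
        # 6 protocols per row -> 5 adjacent pairs; pairs dedup across merged tails
        assert n_precedes >= 5

    def test_mid_attached_to_library_preparation_not_sample(self, default_graph, vocab):
        graph = default_graph.graph
        mids = set(graph.subjects(RDF.type, vocab.term_iri("multiplex identifier sequence")))
        assert len(mids) == 3
        for mid in mids:
            for process in graph.subjects(REL["has_specified_input"], mid):
                assert (process, RDF.type, vocab.term_iri("library preparation")) in graph


class TestEmitGraph:
    @pytest.mark.parametrize("fmt", ["turtle", "ntriples"])
    def test_round_trip_statement_sets_equal(self, default_graph, fmt):
        doc = b.emit_graph(default_graph, fmt)
        reparsed = b.parse_graph(doc, fmt)
        assert set(reparsed.graph) == set(default_graph.graph)

    def test_empty_graph_serializes_with_prefixes(self):
        doc = b.emit_graph(b.InstanceGraph(), "turtle")
        assert "prefix" in doc.lower() or doc.strip() == ""

    def test_unsupported_format(self, default_graph):
        with pytest.raises(b.UnsupportedFormatError, match="ntriples"):
            b.emit_graph(default_graph, "xlsx")


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg_file = tmp_path / "config.yaml"
        cfg_file.write_text(
            "base_iri: https://example.org/x/\n"
            "strict: true\n"
            "otu_pattern: matrix\n"
            "protocol_map:\n  arcane ritual: DNA sequencing\n",
            "utf-8",
        )
        cfg = b.ConversionConfig.from_yaml(cfg_file)
        assert cfg.strict
        assert cfg.base_iri == "https://example.org/x/"
        assert cfg.resolve_protocol("Arcane Ritual") == "DNA sequencing"

    def test_otu_pattern_controls_matrix_typing(self, archive_factory, vocab):
        archive = b.read_archive(archive_factory(DEFAULT_SPEC))
        wf = b.build_workflow_graph(archive.assay_tables[0])
        no_match = b.convert_workflow(wf, config=b.ConversionConfig(otu_pattern="zzz"))
        counts = no_match.count_individuals_by_class(vocab)
        assert "OTU matrix" not in counts
        assert counts["data item"] == 1
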