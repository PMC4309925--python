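"""ISA-Tab parsing, workflow reconstruction and validation."""

import io
import zipfile

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biodivlink as b
from biodivlink.isatab import ProcessEdge, WorkflowGraph, WorkflowNode

from conftest import DEFAULT_SPEC

MINIMAL = "Sample Name\tProtocol REF\tRaw Data File\ns1\tseq\tf1.fastq\n"


class TestParseTable:
    def test_minimal_table(self):
        table = b.parse_table(MINIMAL, "assay")
        assert table.headers == ("Sample Name", "Protocol REF", "Raw Data File")
        assert table.rows == (("s1", "seq", "f1.fastq"),)

    def test_cells_verbatim_including_trailing_empties(self):
        table = b.parse_table("A\tB\tC\nx\t y \t\n", "assay")
        assert table.rows == (("x", " y ", ""),)

    def test_ragged_row_reports_line_number(self):
        with pytest.raises(b.IsaParseError, match="line 2"):
            b.parse_table("A\tB\tC\nx\ty\n", "assay")

    def test_empty_file(self):
        with pytest.raises(b.IsaParseError):
            b.parse_table("", "assay")

    def test_fixture_row_count(self, archive_factory):
        archive = b.read_archive(archive_factory(DEFAULT_SPEC))
        table = archive.assay_tables[0]
        assert len(table.rows) == DEFAULT_SPEC.n_samples * DEFAULT_SPEC.genes_per_sample

    @given(
        names=st.lists(
            st.text(
                alphabet=st.characters(blacklist_characters="\t\n\r", min_codepoint=32),
                min_size=1,
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_cell_values_preserved(self, names):
        text = "Sample Name\n" + "\n".join(names) + "\n"
        table = b.parse_table(text, "study")
        assert [r[0] for r in table.rows] == names


class TestBuildWorkflowGraph:
    def test_minimal_chain(self):
        text = (
            "Sample Name\tProtocol REF\tExtract Name\tProtocol REF\tRaw Data File\n"
            "s1\textract\te1\tseq\tf1.fastq\n"
        )
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        assert len(graph.nodes) == 3
        assert len(graph.edges) == 2
        kinds = [graph.nodes[n].node_kind for n in graph.row_chains[0]]
        assert kinds == ["material", "material", "data"]

    def test_shared_sample_has_out_degree_two(self):
        text = (
            "Sample Name\tProtocol REF\tExtract Name\n"
            "s1\textract\te1\n"
            "s1\textract\te2\n"
        )
        graph = b.build_workflow_graph(b.parse_table(text, "study"))
        samples = [n for n in graph.nodes.values() if n.name == "s1"]
        assert len(samples) == 1
        assert graph.out_degree(samples[0].node_id) == 2

    def test_parameter_lands_on_process(self):
        text = (
            "Sample Name\tProtocol REF\tParameter Value[pcr_cond]\tRaw Data File\n"
            "s1\tpcr\t35 cycles\tf1\n"
        )
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        assert graph.edges[0].parameters == (("pcr_cond", "35 cycles"),)

    def test_characteristic_lands_on_node(self):
        text = (
            "Sample Name\tCharacteristics[organism]\tProtocol REF\tRaw Data File\n"
            "s1\tE. coli\tseq\tf1\n"
        )
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        sample = next(n for n in graph.nodes.values() if n.name == "s1")
        assert sample.attributes == {"organism": "E. coli"}

    def test_no_node_column_is_error(self):
        with pytest.raises(b.WorkflowStructureError, match="no node column"):
            b.build_workflow_graph(
                b.parse_table("Protocol REF\tComment[x]\np\tc\n", "assay")
            )

    def test_trailing_protocol_ref_is_error(self):
        with pytest.raises(b.WorkflowStructureError, match="output node"):
            b.build_workflow_graph(
                b.parse_table("Sample Name\tProtocol REF\ns1\tseq\n", "assay")
            )

    def test_determinism(self, archive_factory):
        path = archive_factory(DEFAULT_SPEC)
        archive = b.read_archive(path)
        g1 = b.build_workflow_graph(archive.assay_tables[0])
        g2 = b.build_workflow_graph(b.read_archive(path).assay_tables[0])
        assert [n.node_id for n in g1.nodes.values()] == [n.node_id for n in g2.nodes.values()]
        assert [(e.edge_id, e.inputs, e.outputs) for e in g1.edges] == [
            (e.edge_id, e.inputs, e.outputs) for e in g2.edges
        ]

    def test_protocol_applications_equal_rows_times_columns(self, workflow_factory):
        graph = workflow_factory(DEFAULT_SPEC)
        rows = DEFAULT_SPEC.n_samples * DEFAULT_SPEC.genes_per_sample
        assert graph.n_protocol_applications() == rows * graph.n_protocol_columns

    def test_merging_preserves_protocol_parameter_multiset(self, archive_factory):
        # oracle: single-row tables cannot merge anything across rows
        path = archive_factory(b.FixtureSpec(3, 2, multiplexed=True, seed=42))
        table = b.read_archive(path).assay_tables[0]
        merged = b.build_workflow_graph(table)
        got = sorted(
            (e.protocol_ref, e.parameters) for e in merged.edges for _ in e.row_indices
        )
        want = []
        header = "\t".join(table.headers)
        for row in table.rows:
            single = b.build_workflow_graph(
                b.parse_table(header + "\n" + "\t".join(row) + "\n", "assay")
            )
            want += [(e.protocol_ref, e.parameters) for e in single.edges]
        assert got == sorted(want)


class TestValidateWorkflow:
    def test_minimal_valid_chain(self):
        graph = b.build_workflow_graph(b.parse_table(MINIMAL, "assay"))
        assert b.validate_workflow(graph).is_valid

    def test_rightmost_material_violation(self):
        text = "Sample Name\tProtocol REF\tExtract Name\ns1\textract\te1\n"
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        assert "rightmost-node-not-data" in b.validate_workflow(graph).codes()

    def test_leftmost_data_violation(self):
        text = "Raw Data File\tProtocol REF\tDerived Data File\nf1\ttransform\td1\n"
        graph = b.build_workflow_graph(b.parse_table(text, "assay"))
        assert "leftmost-node-not-material" in b.validate_workflow(graph).codes()

    def test_study_table_may_end_in_material(self):
        text = "Source Name\tProtocol REF\tSample Name\nsubj1\tcollect\ts1\n"
        graph = b.build_workflow_graph(b.parse_table(text, "study"))
        assert b.validate_workflow(graph).is_valid

    def test_cycle_detected_in_hand_built_graph(self):
        nodes = {
            "n0": WorkflowNode("n0", "a", "material", "Sample Name"),
            "n1": WorkflowNode("n1", "b", "material", "Extract Name"),
        }
        edges = [
            ProcessEdge("e0", "p1", (), ("n0",), ("n1",), (0,), 0, 1),
            ProcessEdge("e1", "p2", (), ("n1",), ("n0",), (1,), 0, 1),
        ]
        graph = WorkflowGraph(nodes, edges, "study", [["n0", "n1"]], 1)
        assert "cycle" in b.validate_workflow(graph).codes()


class TestReadArchive:
    def test_reads_directory(self, archive_factory):
        archive = b.read_archive(archive_factory(DEFAULT_SPEC))
        assert archive.archive_id == DEFAULT_SPEC.archive_id
        assert len(archive.study_tables) == 1
        assert len(archive.assay_tables) == 1

    def test_reads_zip(self, archive_factory, tmp_path):
        src = archive_factory(DEFAULT_SPEC)
        zpath = tmp_path / "archive.zip"
        with zipfile.ZipFile(zpath, "w") as zf:
            for f in src.iterdir():
                zf.writestr(f.name, f.read_text("utf-8"))
        archive = b.read_archive(zpath)
        assert archive.archive_id == DEFAULT_SPEC.archive_id

    def test_missing_investigation(self, tmp_path):
        with pytest.raises(b.IsaParseError, match="i_"):
            b.read_archive(tmp_path)
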