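"""ISA-Tab reading and workflow-graph reconstruction.

An ISA assay table encodes an experimental workflow: node columns (materials
such as 'Sample Name' or 'Extract Name', data such as 'Raw Data File') are
interspersed with 'Protocol REF' columns that represent processes, and the
left-to-right column order is the order of execution. This module parses the
tab-separated tables verbatim, rebuilds that workflow as a directed acyclic
graph, and checks the structural contract an assay workflow must satisfy:
each row's chain starts at a material node and ends at a data node.

Qualifier columns ('Characteristics[...]', 'Parameter Value[...]',
'Comment[...]', 'Unit', 'Term Source REF'/'Term Accession Number', ...)
attach to the closest node or process column to their left, per ISA-Tab
convention. Nodes with identical (column label, name) within one table are
merged; edges identical in (protocol, parameters, output) across rows merge
their inputs, which is what turns per-sample library rows into one pooled
sequencing run.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import networkx as nx

from .errors import IsaParseError, WorkflowStructureError

MATERIAL_NODE_COLUMNS = frozenset(
    {"Source Name", "Sample Name", "Extract Name", "Labeled Extract Name"}
)
DATA_NODE_COLUMNS = frozenset(
    {
        "Raw Data File",
        "Derived Data File",
        "Array Data File",
        "Image File",
        "Raw Spectral Data File",
        "Derived Spectral Data File",
    }
)
PROTOCOL_COLUMN = "Protocol REF"

_QUALIFIER_PREFIXES = ("Characteristics[", "Parameter Value[", "Comment[", "Factor Value[")
_PAIR_QUALIFIERS = frozenset({"Term Source REF", "Term Accession Number", "Unit"})


@dataclass(frozen=True)
class TableModel:
    """One parsed ISA table: verbatim cells, no type coercion."""

    headers: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    table_kind: str  # study | assay
    source: str = "<stream>"


@dataclass
class WorkflowNode:
    node_id: str
    name: str
    node_kind: str  # material | data
    node_type_label: str  # e.g. 'Sample Name'
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class ProcessEdge:
    edge_id: str
    protocol_ref: str
    parameters: tuple[tuple[str, str], ...]
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    row_indices: tuple[int, ...]
    order_index: int  # position among the row's process columns, left to right
    column_index: int


@dataclass
class WorkflowGraph:
    nodes: dict[str, WorkflowNode]
    edges: list[ProcessEdge]
    table_kind: str
    row_chains: list[list[str]]  # per row, node ids in column order
    n_protocol_columns: int

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, name=node.name, kind=node.node_kind)
        for e in self.edges:
            for i in e.inputs:
                for o in e.outputs:
                    g.add_edge(i, o, key=e.edge_id, protocol_ref=e.protocol_ref)
        return g

    def out_degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if node_id in e.inputs)

    def n_protocol_applications(self) -> int:
        """Total protocol applications across rows (pre-merge multiplicity)."""
        return sum(len(e.row_indices) for e in self.edges)


@dataclass
class ValidationReport:
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def codes(self) -> list[str]:
        return [c for c, _ in self.violations]


def parse_table(stream: IO[str] | str, table_kind: str) -> TableModel:
    """Parse a tab-separated ISA table. Cells are preserved verbatim,
    including empty trailing cells; a ragged row raises
    :class:`IsaParseError` with the line number."""
    if table_kind not in ("study", "assay"):
        raise IsaParseError(f"table_kind must be 'study' or 'assay', got {table_kind!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    source = getattr(stream, "name", "<stream>")
    lines = stream.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines or not lines[0].strip():
        raise IsaParseError(f"{source}: empty table")
    headers = tuple(h.strip('"') for h in lines[0].rstrip("\r").split("\t"))
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = tuple(line.rstrip("\r").split("\t"))
        if len(cells) != len(headers):
            raise IsaParseError(
                f"{source}: ragged row at line {lineno}: "
                f"{len(cells)} cells under {len(headers)} headers"
            )
        rows.append(cells)
    return TableModel(headers, tuple(rows), table_kind, str(source))


def _classify_columns(headers: tuple[str, ...]) -> list[str]:
    """Classify each header as material / data / process / qualifier."""
    kinds = []
    for h in headers:
        if h in MATERIAL_NODE_COLUMNS:
            kinds.append("material")
        elif h in DATA_NODE_COLUMNS:
            kinds.append("data")
        elif h == PROTOCOL_COLUMN:
            kinds.append("process")
        else:
            # Characteristics/Parameter Value/Comment/Unit/Term Source REF and
            # anything else ISA-dialect-specific qualifies the column to its left.
            kinds.append("qualifier")
    return kinds


def qualifier_label(header: str) -> str:
    """'Parameter Value[pcr_cond]' -> 'pcr_cond'; plain labels pass through."""
    for prefix in _QUALIFIER_PREFIXES:
        if header.startswith(prefix) and header.endswith("]"):
            return header[len(prefix) : -1]
    return header


def build_workflow_graph(table: TableModel) -> WorkflowGraph:
    """Rebuild the experimental workflow encoded by one ISA table.

    One process edge is created per ('Protocol REF' column x row); its input
    and output are the nearest non-empty node cells to the left and right.
    Raises :class:`WorkflowStructureError` for headers with no node column or
    with a 'Protocol REF' in a position that leaves a process without an
    input or output node column.
    """
    kinds = _classify_columns(table.headers)
    node_cols = [i for i, k in enumerate(kinds) if k in ("material", "data")]
    process_cols = [i for i, k in enumerate(kinds) if k == "process"]
    if not node_cols:
        raise WorkflowStructureError(f"{table.source}: header has no node column")
    for p in process_cols:
        if not any(i < p for i in node_cols):
            raise WorkflowStructureError(
                f"{table.source}: 'Protocol REF' at column {p + 1} has no input node column"
            )
        if not any(i > p for i in node_cols):
            raise WorkflowStructureError(
                f"{table.source}: 'Protocol REF' at column {p + 1} has no output node column"
            )

    # Qualifier columns attach to the closest node/process column to the left;
    # 'Term Source REF'/'Term Accession Number'/'Unit' conceptually qualify the
    # preceding qualifier but are recorded on the same owner for traceability.
    owner_of: dict[int, int] = {}
    last_owner = None
    for i, k in enumerate(kinds):
        if k in ("material", "data", "process"):
            last_owner = i
        elif last_owner is not None:
            owner_of[i] = last_owner
    qualifiers_of: dict[int, list[int]] = {}
    for q, owner in owner_of.items():
        qualifiers_of.setdefault(owner, []).append(q)

    nodes: dict[tuple[str, str], WorkflowNode] = {}
    raw_edges: dict[tuple, dict] = {}
    row_chains: list[list[str]] = []

    def node_for(col: int, row: tuple[str, ...]) -> WorkflowNode | None:
        name = row[col]
        if not name:
            return None
        key = (table.headers[col], name)
        if key not in nodes:
            nodes[key] = WorkflowNode(
                node_id=f"n{len(nodes)}",
                name=name,
                node_kind=kinds[col],
                node_type_label=table.headers[col],
            )
        node = nodes[key]
        for q in qualifiers_of.get(col, ()):
            if row[q] and qualifier_label(table.headers[q]) not in node.attributes:
                node.attributes[qualifier_label(table.headers[q])] = row[q]
        return node

    for row_index, row in enumerate(table.rows):
        chain: list[str] = []
        row_nodes: dict[int, str | None] = {}
        for col in node_cols:
            node = node_for(col, row)
            row_nodes[col] = node.node_id if node else None
            if node:
                chain.append(node.node_id)
        row_chains.append(chain)
        for order, pcol in enumerate(process_cols):
            protocol = row[pcol]
            if not protocol:
                continue
            inp = next(
                (row_nodes[c] for c in reversed(node_cols) if c < pcol and row_nodes[c]), None
            )
            out = next((row_nodes[c] for c in node_cols if c > pcol and row_nodes[c]), None)
            if inp is None or out is None:
                continue  # row-level gap: no material to connect
            params = tuple(
                (qualifier_label(table.headers[q]), row[q])
                for q in qualifiers_of.get(pcol, ())
                if row[q]
            )
            key = (pcol, protocol, params, out)
            entry = raw_edges.setdefault(
                key,
                {
                    "protocol_ref": protocol,
                    "parameters": params,
                    "inputs": [],
                    "outputs": [out],
                    "rows": [],
                    "order_index": order,
                    "column_index": pcol,
                },
            )
            if inp not in entry["inputs"]:
                entry["inputs"].append(inp)
            entry["rows"].append(row_index)

    edges = [
        ProcessEdge(
            edge_id=f"e{i}",
            protocol_ref=e["protocol_ref"],
            parameters=e["parameters"],
            inputs=tuple(e["inputs"]),
            outputs=tuple(e["outputs"]),
            row_indices=tuple(e["rows"]),
            order_index=e["order_index"],
            column_index=e["column_index"],
        )
        for i, e in enumerate(raw_edges.values())
    ]
    return WorkflowGraph(
        nodes={n.node_id: n for n in nodes.values()},
        edges=edges,
        table_kind=table.table_kind,
        row_chains=row_chains,
        n_protocol_columns=len(process_cols),
    )


def validate_workflow(graph: WorkflowGraph) -> ValidationReport:
    """Check the workflow contract. Violations are report entries, never
    exceptions: leftmost node material, rightmost node data (assay tables),
    acyclicity, and edge connectivity."""
    report = ValidationReport()
    for row_index, chain in enumerate(graph.row_chains):
        if not chain:
            continue
        first, last = graph.nodes[chain[0]], graph.nodes[chain[-1]]
        if first.node_kind != "material":
            report.violations.append(
                (
                    "leftmost-node-not-material",
                    f"row {row_index + 1}: chain starts at {first.node_type_label!r}"
                    f" ({first.name!r}), a {first.node_kind} node",
                )
            )
        if graph.table_kind == "assay" and last.node_kind != "data":
            report.violations.append(
                (
                    "rightmost-node-not-data",
                    f"row {row_index + 1}: chain ends at {last.node_type_label!r}"
                    f" ({last.name!r}), a {last.node_kind} node",
                )
            )
    for e in graph.edges:
        if not e.inputs or not e.outputs:
            report.violations.append(
                ("edge-disconnected", f"process {e.protocol_ref!r} lacks an input or output")
            )
    nxg = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(nxg):
        cycle = nx.find_cycle(nxg)
        names = " -> ".join(graph.nodes[u].name for u, _, _ in cycle)
        report.violations.append(("cycle", f"workflow contains a cycle: {names}"))
    return report


# --------------------------------------------------------------------------
# Archive discovery (investigation parsing is limited to file discovery and
# identifiers; full investigation metadata is out of scope).


@dataclass
class SurveyArchive:
    archive_id: str
    investigation_file: str
    study_tables: list[TableModel]
    assay_tables: list[TableModel]


def _investigation_fields(text: str) -> dict[str, list[str]]:
    fields: dict[str, list[str]] = {}
    for line in text.splitlines():
        cells = line.rstrip("\r").split("\t")
        if len(cells) >= 2 and cells[0] and cells[1]:
            fields.setdefault(cells[0], []).extend(c.strip('"') for c in cells[1:] if c)
    return fields


def read_archive(path: str | Path) -> SurveyArchive:
    """Read an ISA-Tab archive (directory or zip): locate the ``i_*.txt``
    investigation file, then load the study and assay tables it names."""
    path = Path(path)
    if path.suffix == ".zip" and path.is_file():
        with zipfile.ZipFile(path) as zf:
            names = sorted(zf.namelist())
            reader = {n: zf.read(n).decode("utf-8") for n in names}
    elif path.is_dir():
        names = sorted(p.name for p in path.iterdir() if p.is_file())
        reader = {n: (path / n).read_text("utf-8") for n in names}
    else:
        raise IsaParseError(f"not an ISA-Tab archive (directory or zip): {path}")

    inv = [n for n in names if Path(n).name.startswith("i_") and n.endswith(".txt")]
    if not inv:
        raise IsaParseError(f"{path}: no investigation file (i_*.txt) found")
    inv_name = inv[0]
    fields = _investigation_fields(reader[inv_name])
    archive_id = (
        (fields.get("Investigation Identifier") or fields.get("Study Identifier") or [path.stem])
    )[0]

    def load(filenames: Iterable[str], kind: str) -> list[TableModel]:
        tables = []
        for fn in filenames:
            if fn not in reader:
                raise IsaParseError(f"{path}: investigation names missing file {fn!r}")
            stream = io.StringIO(reader[fn])
            stream.name = fn  # type: ignore[attr-defined]
            tables.append(parse_table(stream, kind))
        return tables

    return SurveyArchive(
        archive_id=archive_id,
        investigation_file=inv_name,
        study_tables=load(fields.get("Study File Name", []), "study"),
        assay_tables=load(fields.get("Study Assay File Name", []), "assay"),
    )
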