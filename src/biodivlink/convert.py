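"""Conversion of ISA workflow graphs into OBI-patterned RDF instance graphs.

The instance pattern mirrors the class-level axioms in :mod:`.ontology`: one
individual per assay table is typed 'targeted gene survey' and linked via
achieves_planned_objective to a 'biodiversity assessment objective'
individual; protocol applications become process individuals (library
preparation, PCR, DNA sequencing, library sequence deconvolution, sequence
analysis data transformation) ordered by 'precedes'; primers and multiplex
identifiers are specified *inputs of processes*, never properties of samples;
and the class-level property chain 'realizes o concretizes' is witnessed by
minting an intermediate plan individual between each PCR process and its
'PCR program' specification. The terminal analysis output is a 'data item'
that is_about a 'population quality' individual — the community diversity the
survey was run to estimate — and is additionally typed 'OTU matrix' when its
name matches a configurable pattern.

All individuals are minted IRIs (no blank nodes), deterministic functions of
(archive id, entity kind, entity name), so conversions are reproducible and
merged graphs from different archives never collide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable
from urllib.parse import quote

import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from .errors import ConversionError, UnsupportedFormatError
from .isatab import ProcessEdge, SurveyArchive, WorkflowGraph, build_workflow_graph, read_archive
from .mixs import ComplianceReport, normalize_tag
from .ontology import ANN, REL, TERM, Vocabulary, load_core_terms

DEFAULT_BASE_IRI = "https://w3id.org/biodivlink/data/"

GRAPH_FORMATS = ("turtle", "ntriples")

#: Protocol labels (lowercased) mapped to vocabulary class labels.
DEFAULT_PROTOCOL_MAP: dict[str, str] = {
    "polymerase chain reaction": "polymerase chain reaction",
    "pcr": "polymerase chain reaction",
    "pcr amplification": "polymerase chain reaction",
    "library preparation": "library preparation",
    "library construction": "library preparation",
    "dna sequencing": "DNA sequencing",
    "nucleic acid sequencing": "DNA sequencing",
    "sequencing": "DNA sequencing",
    "pyrosequencing": "DNA sequencing",
    "library sequence deconvolution": "library sequence deconvolution",
    "sequence deconvolution": "library sequence deconvolution",
    "deconvolution": "library sequence deconvolution",
    "sequence analysis": "sequence analysis data transformation",
    "sequence analysis data transformation": "sequence analysis data transformation",
    "nucleic acid extraction": "nucleic acid extraction",
    "dna extraction": "nucleic acid extraction",
}

#: ISA node columns whose individuals carry a vocabulary type.
MATERIAL_TYPE_MAP: dict[str, str] = {"Extract Name": "DNA extract"}

_PART_TYPES = frozenset(
    {
        "library preparation",
        "DNA sequencing",
        "library sequence deconvolution",
        "sequence analysis data transformation",
    }
)


@dataclass
class ConversionConfig:
    base_iri: str = DEFAULT_BASE_IRI
    strict: bool = False
    protocol_map: dict[str, str] = field(default_factory=dict)
    otu_pattern: str = "otu"

    def resolve_protocol(self, protocol_ref: str) -> str | None:
        key = protocol_ref.strip().lower()
        if key in self.protocol_map:
            return self.protocol_map[key] or None
        return DEFAULT_PROTOCOL_MAP.get(key)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConversionConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        return cls(
            base_iri=data.get("base_iri", DEFAULT_BASE_IRI),
            strict=bool(data.get("strict", False)),
            protocol_map={str(k).lower(): str(v) for k, v in (data.get("protocol_map") or {}).items()},
            otu_pattern=data.get("otu_pattern", "otu"),
        )


def mint_iri(base: str, kind: str, name: str) -> URIRef:
    """Mint a deterministic individual IRI ``<base><kind>/<name>`` with the
    name percent-encoded (no raw spaces, slashes or non-ASCII)."""
    if not name:
        raise ConversionError("cannot mint an IRI for an empty name")
    if not base.endswith(("/", "#")):
        base += "/"
    return URIRef(f"{base}{quote(kind, safe='')}/{quote(name, safe='')}")


class InstanceGraph:
    """An RDF instance graph (rdflib-backed, blank-node free)."""

    def __init__(self, graph: Graph | None = None):
        self.graph = graph if graph is not None else Graph()
        for prefix, ns in (("term", TERM), ("rel", REL), ("ann", ANN), ("rdfs", RDFS)):
            self.graph.bind(prefix, ns)

    def add(self, triple) -> None:
        self.graph.add(triple)

    def __len__(self) -> int:
        return len(self.graph)

    def __iter__(self):
        return iter(self.graph)

    def __contains__(self, triple) -> bool:
        return triple in self.graph

    def merge(self, other: "InstanceGraph") -> "InstanceGraph":
        merged = InstanceGraph()
        for t in self.graph:
            merged.add(t)
        for t in other.graph:
            merged.add(t)
        return merged

    def count_individuals_by_class(self, vocab: Vocabulary | None = None) -> dict[str, int]:
        """Count distinct typed individuals per vocabulary class label."""
        vocab = vocab or _default_vocab()
        by_iri = {t.iri: t.label for t in vocab.terms.values()}
        counts: dict[str, set] = {}
        for s, o in self.graph.subject_objects(RDF.type):
            label = by_iri.get(str(o))
            if label is not None:
                counts.setdefault(label, set()).add(s)
        return {label: len(inds) for label, inds in counts.items()}


@lru_cache(maxsize=1)
def _default_vocab() -> Vocabulary:
    return load_core_terms()


def split_primers(value: str) -> tuple[str, str] | None:
    """Split a MIxS pcr_primers value of the form ``FWD:<seq>;REV:<seq>``.
    Returns None when the free-text value does not follow that shape."""
    parts = [p.strip() for p in value.split(";") if p.strip()]
    fwd = rev = None
    for p in parts:
        head, _, seq = p.partition(":")
        if head.strip().upper() == "FWD" and seq.strip():
            fwd = seq.strip()
        elif head.strip().upper() == "REV" and seq.strip():
            rev = seq.strip()
    if fwd and rev:
        return fwd, rev
    return None


def convert_workflow(
    graph: WorkflowGraph,
    checklist_report: ComplianceReport | None = None,
    config: ConversionConfig | None = None,
    *,
    vocab: Vocabulary | None = None,
    archive_id: str = "survey",
) -> InstanceGraph:
    """Convert a validated workflow graph into an OBI-patterned instance graph.

    In strict mode an unmapped 'Protocol REF' label raises
    :class:`ConversionError`; otherwise it yields a warning and an untyped
    process individual.
    """
    if not graph.nodes and not graph.edges:
        raise ConversionError("nothing to convert: empty workflow graph")
    config = config or ConversionConfig()
    vocab = vocab or _default_vocab()
    base = f"{config.base_iri if config.base_iri.endswith('/') else config.base_iri + '/'}" + quote(
        archive_id, safe=""
    )
    out = InstanceGraph()
    g = out.graph

    def cls(label: str) -> URIRef:
        return vocab.term_iri(label)

    def rel(label: str) -> URIRef:
        return vocab.relation_iri(label)

    # --- survey individual and its objective -------------------------------
    survey = mint_iri(base, "survey", "survey-1")
    objective = mint_iri(base, "objective", "biodiversity-assessment")
    g.add((survey, RDF.type, cls("targeted gene survey")))
    g.add((survey, RDFS.label, Literal(f"targeted gene survey ({archive_id})")))
    g.add((survey, rel("achieves_planned_objective"), objective))
    g.add((objective, RDF.type, cls("biodiversity assessment objective")))
    g.add((objective, RDFS.label, Literal("biodiversity assessment objective")))

    # --- material and data individuals -------------------------------------
    node_iri: dict[str, URIRef] = {}
    for node in graph.nodes.values():
        iri = mint_iri(base, _slug(node.node_type_label), node.name)
        node_iri[node.node_id] = iri
        g.add((iri, RDFS.label, Literal(node.name)))
        if node.node_type_label in MATERIAL_TYPE_MAP:
            g.add((iri, RDF.type, cls(MATERIAL_TYPE_MAP[node.node_type_label])))
        for label, value in node.attributes.items():
            g.add((iri, ANN[normalize_tag(label)], Literal(value)))

    # --- process individuals ------------------------------------------------
    proc_iri: dict[str, URIRef] = {}
    mapped_type: dict[str, str | None] = {}
    unmapped: list[str] = []
    for edge in graph.edges:
        mapped = config.resolve_protocol(edge.protocol_ref)
        mapped_type[edge.edge_id] = mapped
        if mapped is None and edge.protocol_ref not in unmapped:
            unmapped.append(edge.protocol_ref)
        proc = mint_iri(base, "process", f"{edge.edge_id}-{_slug(edge.protocol_ref)}")
        proc_iri[edge.edge_id] = proc
        g.add((proc, RDFS.label, Literal(edge.protocol_ref)))
        if mapped is not None:
            g.add((proc, RDF.type, cls(mapped)))
        if mapped in _PART_TYPES:
            g.add((survey, rel("has_part"), proc))
        for label, value in edge.parameters:
            g.add((proc, ANN[normalize_tag(label)], Literal(value)))
    if unmapped:
        if config.strict:
            raise ConversionError(
                "unmapped protocol labels (strict mode): " + ", ".join(repr(p) for p in unmapped)
            )
        warnings.warn(
            "untyped process individuals for unmapped protocols: "
            + ", ".join(repr(p) for p in unmapped),
            stacklevel=2,
        )

    # --- per-row structure: extracts, IO, pattern augmentations -------------
    row_edges: dict[int, list[ProcessEdge]] = {}
    for edge in graph.edges:
        for r in edge.row_indices:
            row_edges.setdefault(r, []).append(edge)
    for edges in row_edges.values():
        edges.sort(key=lambda e: e.order_index)

    row_extract: dict[int, str | None] = {}
    for r, chain in enumerate(graph.row_chains):
        row_extract[r] = next(
            (nid for nid in chain if graph.nodes[nid].node_type_label in MATERIAL_TYPE_MAP), None
        )

    library_of_row: dict[int, URIRef] = {}

    for edge in graph.edges:
        proc = proc_iri[edge.edge_id]
        mapped = mapped_type[edge.edge_id]

        if mapped == "library preparation":
            # The assay table has no explicit library node; the material the
            # preparation outputs is minted, one single fragment library per
            # preparation, rather than typing the downstream data file.
            for nid in edge.inputs:
                g.add((proc, rel("has_specified_input"), node_iri[nid]))
            lib = mint_iri(base, "library", f"lib-{edge.edge_id}")
            g.add((lib, RDF.type, cls("single fragment library")))
            g.add((lib, RDFS.label, Literal(f"single fragment library ({edge.edge_id})")))
            g.add((proc, rel("has_specified_output"), lib))
            for r in edge.row_indices:
                library_of_row[r] = lib
                if row_extract[r] is not None:
                    g.add((proc, rel("has_specified_input"), node_iri[row_extract[r]]))
            mid_value = next(
                (v for k, v in edge.parameters if normalize_tag(k) == "mid"), None
            )
            if mid_value is not None:
                mid = mint_iri(base, "mid", mid_value)
                g.add((mid, RDF.type, cls("multiplex identifier sequence")))
                g.add((mid, RDFS.label, Literal(mid_value)))
                g.add((mid, ANN["sequence"], Literal(mid_value)))
                g.add((proc, rel("has_specified_input"), mid))
            continue

        for nid in edge.inputs:
            g.add((proc, rel("has_specified_input"), node_iri[nid]))
        for nid in edge.outputs:
            g.add((proc, rel("has_specified_output"), node_iri[nid]))

        if mapped == "polymerase chain reaction":
            primer_value = next(
                (v for k, v in edge.parameters if normalize_tag(k) == "pcr_primers"), None
            )
            if primer_value is not None:
                pair = split_primers(primer_value)
                if pair is None:
                    warnings.warn(
                        f"unsplittable pcr_primers value {primer_value!r}; "
                        "minting one generic primer individual",
                        stacklevel=2,
                    )
                    generic = mint_iri(base, "primer", primer_value)
                    g.add((generic, RDFS.label, Literal(primer_value)))
                    g.add((proc, rel("has_specified_input"), generic))
                else:
                    for direction, seq, label in (
                        ("fwd", pair[0], "forward pcr primer"),
                        ("rev", pair[1], "reverse pcr primer"),
                    ):
                        primer = mint_iri(base, "primer", f"{direction}:{seq}")
                        g.add((primer, RDF.type, cls(label)))
                        g.add((primer, RDFS.label, Literal(f"{label} {seq}")))
                        g.add((primer, ANN["sequence"], Literal(seq)))
                        g.add((proc, rel("has_specified_input"), primer))
            # Chain expansion: process realizes a plan which concretizes the
            # 'PCR program' plan specification (realizes o concretizes).
            plan = mint_iri(base, "plan", f"plan-{edge.edge_id}")
            program = mint_iri(base, "plan-specification", f"pcr-program-{edge.edge_id}")
            g.add((plan, RDFS.label, Literal(f"PCR plan ({edge.edge_id})")))
            g.add((proc, rel("realizes"), plan))
            g.add((plan, rel("concretizes"), program))
            g.add((program, RDF.type, cls("PCR program")))
            g.add((program, RDFS.label, Literal(f"PCR program ({edge.edge_id})")))

    # --- library preparation has_part PCR, per row --------------------------
    for edges in row_edges.values():
        pcr = next((e for e in edges if mapped_type[e.edge_id] == "polymerase chain reaction"), None)
        lib = next((e for e in edges if mapped_type[e.edge_id] == "library preparation"), None)
        if pcr is not None and lib is not None:
            g.add((proc_iri[lib.edge_id], rel("has_part"), proc_iri[pcr.edge_id]))

    # --- temporal order ------------------------------------------------------
    for edges in row_edges.values():
        for a, b in zip(edges, edges[1:]):
            g.add((proc_iri[a.edge_id], rel("precedes"), proc_iri[b.edge_id]))

    # --- multiplexing: pooled sequencing runs -------------------------------
    for edge in graph.edges:
        if mapped_type[edge.edge_id] == "DNA sequencing" and len(edge.row_indices) >= 2:
            mux = mint_iri(base, "process", f"mux-{edge.edge_id}")
            g.add((mux, RDF.type, cls("multiplexing")))
            g.add((mux, RDFS.label, Literal(f"multiplexing ({edge.edge_id})")))
            g.add((survey, rel("has_part"), mux))
            g.add((mux, rel("precedes"), proc_iri[edge.edge_id]))
            for r in edge.row_indices:
                if r in library_of_row:
                    g.add((mux, rel("has_specified_input"), library_of_row[r]))

    # --- terminal data item --------------------------------------------------
    analysis_outputs = {
        nid
        for edge in graph.edges
        if mapped_type[edge.edge_id] == "sequence analysis data transformation"
        for nid in edge.outputs
    }
    if analysis_outputs:
        quality = mint_iri(base, "quality", "population-quality")
        g.add((quality, RDF.type, cls("population quality")))
        g.add((quality, RDFS.label, Literal("population quality")))
        for nid in sorted(analysis_outputs):
            iri = node_iri[nid]
            g.add((iri, RDF.type, cls("data item")))
            g.add((iri, rel("is_about"), quality))
            if config.otu_pattern and config.otu_pattern.lower() in graph.nodes[nid].name.lower():
                g.add((iri, RDF.type, cls("OTU matrix")))

    return out


def convert_archive(
    archive: SurveyArchive | str | Path,
    config: ConversionConfig | None = None,
    *,
    vocab: Vocabulary | None = None,
) -> InstanceGraph:
    """Convert every assay table of an ISA-Tab archive into one instance
    graph (one 'targeted gene survey' individual per assay table)."""
    if not isinstance(archive, SurveyArchive):
        archive = read_archive(archive)
    if not archive.assay_tables:
        raise ConversionError(f"archive {archive.archive_id!r} has no assay tables")
    merged = InstanceGraph()
    for i, table in enumerate(archive.assay_tables):
        wf = build_workflow_graph(table)
        suffix = f"/{i}" if len(archive.assay_tables) > 1 else ""
        part = convert_workflow(
            wf, config=config, vocab=vocab, archive_id=f"{archive.archive_id}{suffix}"
        )
        merged = merged.merge(part)
    return merged


def emit_graph(instance_graph: InstanceGraph, format: str) -> str:
    """Serialize an instance graph as Turtle or N-Triples."""
    if format == "turtle":
        return instance_graph.graph.serialize(format="turtle")
    if format == "ntriples":
        return instance_graph.graph.serialize(format="nt")
    raise UnsupportedFormatError(
        f"unsupported graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}"
    )


def parse_graph(document: str, format: str) -> InstanceGraph:
    """Parse a document emitted by :func:`emit_graph` back into an
    :class:`InstanceGraph`."""
    if format not in GRAPH_FORMATS:
        raise UnsupportedFormatError(
            f"unsupported graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}"
        )
    g = Graph()
    g.parse(data=document, format="turtle" if format == "turtle" else "nt")
    return InstanceGraph(g)


def _slug(text: str) -> str:
    return text.strip().lower().replace(" ", "-")
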