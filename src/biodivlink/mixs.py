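"""MIxS descriptor subset for environmental gene surveys, and compliance
checking of ISA workflows against it.

The Minimum Information about any (x) Sequence (MIxS) checklists itemize what
to report about samples, sample processing and data acquisition. The bundled
registry is a curated, user-editable subset covering the descriptors a
targeted gene survey hinges on — target gene and subfragment, PCR primers and
conditions, the multiplex identifier (the tag the standard promotes over the
ambiguous 'barcode') — plus common optional survey fields. Matching is by
normalized label, not column position: a descriptor counts as present
wherever a node attribute or process parameter label normalizes to its tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .errors import RegistryError, TermNotFoundError
from .isatab import WorkflowGraph

REQUIREMENT_LEVELS = ("mandatory", "conditional", "optional")
ATTACHMENT_POINTS = (
    "sample",
    "dna_extraction",
    "pcr",
    "library_preparation",
    "sequencing",
    "analysis",
)


@dataclass(frozen=True)
class MixsDescriptor:
    tag: str
    requirement: str
    attachment: str
    mapped_term_label: str = ""


@dataclass
class ComplianceReport:
    missing_mandatory: list[str] = field(default_factory=list)
    present: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    unrecognized: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "missing_mandatory": self.missing_mandatory,
                "present": {
                    tag: [{"value": v, "location": loc} for v, loc in occ]
                    for tag, occ in self.present.items()
                },
                "unrecognized": self.unrecognized,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = ["MIxS compliance report", "======================"]
        if self.missing_mandatory:
            lines.append("Missing mandatory descriptors:")
            lines += [f"  - {t}" for t in self.missing_mandatory]
        else:
            lines.append("All mandatory descriptors present.")
        for tag, occ in self.present.items():
            lines.append(f"{tag}: {len(occ)} occurrence(s), e.g. {occ[0][0]!r} at {occ[0][1]}")
        if self.unrecognized:
            lines.append("Unrecognized annotation labels: " + ", ".join(self.unrecognized))
        return "\n".join(lines)


def normalize_tag(label: str) -> str:
    """Normalize an annotation label to MIxS tag form: lowercase, spaces and
    hyphens to underscores. Idempotent."""
    return label.strip().lower().replace(" ", "_").replace("-", "_")


class Checklist:
    """A loaded descriptor registry with tag lookup."""

    def __init__(self, descriptors: list[MixsDescriptor]):
        self.descriptors: dict[str, MixsDescriptor] = {}
        for d in descriptors:
            if d.tag in self.descriptors:
                raise RegistryError(f"duplicate registry tag: {d.tag!r}")
            self.descriptors[d.tag] = d

    def __contains__(self, tag: str) -> bool:
        return tag in self.descriptors

    def __iter__(self):
        return iter(self.descriptors.values())

    def lookup(self, tag: str) -> MixsDescriptor:
        try:
            return self.descriptors[tag]
        except KeyError:
            raise TermNotFoundError(f"no such MIxS descriptor: {tag!r}") from None

    @property
    def mandatory(self) -> list[str]:
        return [d.tag for d in self.descriptors.values() if d.requirement == "mandatory"]


def load_checklist() -> Checklist:
    """Load the bundled MIxS descriptor registry."""
    text = resources.files("biodivlink.data").joinpath("mixs_registry.tsv").read_text("utf-8")
    lines = text.splitlines()
    if not lines:
        raise RegistryError("mixs_registry.tsv: empty file")
    descriptors = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) not in (3, 4):
            raise RegistryError(f"mixs_registry.tsv: malformed row at line {lineno}")
        tag, requirement, attachment = cells[0], cells[1], cells[2]
        mapped = cells[3] if len(cells) == 4 else ""
        if requirement not in REQUIREMENT_LEVELS:
            raise RegistryError(
                f"mixs_registry.tsv: line {lineno}: bad requirement {requirement!r}"
            )
        if attachment not in ATTACHMENT_POINTS:
            raise RegistryError(
                f"mixs_registry.tsv: line {lineno}: bad attachment {attachment!r}"
            )
        norm = normalize_tag(tag)
        if norm != tag:
            raise RegistryError(
                f"mixs_registry.tsv: line {lineno}: tag {tag!r} is not normalized ({norm!r})"
            )
        descriptors.append(MixsDescriptor(tag, requirement, attachment, mapped))
    return Checklist(descriptors)


def check_compliance(graph: WorkflowGraph, checklist: Checklist) -> ComplianceReport:
    """Check which checklist descriptors a workflow carries.

    A tag is present iff some node attribute or process parameter label
    normalizes to it; values are reported byte-identical to the source cells,
    with the owning node/process as the attachment location.
    """
    report = ComplianceReport()
    seen_unrecognized: set[str] = set()

    def record(label: str, value: str, location: str) -> None:
        tag = normalize_tag(label)
        if tag in checklist:
            report.present.setdefault(tag, []).append((value, location))
        elif label not in seen_unrecognized:
            seen_unrecognized.add(label)
            report.unrecognized.append(label)

    for node in graph.nodes.values():
        for label, value in node.attributes.items():
            record(label, value, f"node:{node.node_type_label}:{node.name}")
    for edge in graph.edges:
        for label, value in edge.parameters:
            record(label, value, f"process:{edge.protocol_ref}")

    report.missing_mandatory = [t for t in checklist.mandatory if t not in report.present]
    return report
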