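"""Core vocabulary for targeted gene surveys and its OWL serialization.

This module houses the small ontology module the converter relies on: the
eight community-survey classes requested from OBI and PCO (targeted gene
survey, multiplexing, library sequence deconvolution, PCR program, multiplex
identifier sequence, OTU matrix, target gene, target subfragment), the
supporting classes they are axiomatized against, the object properties of the
assay design pattern, and the existential restrictions that make up that
pattern: an assay has a specified input of type Material, a specified output
of type Data, and achieves a specific objective — here, a biodiversity
assessment objective rather than the generic sequence-analysis one.

Class IRIs are minted in an artifact namespace; a sidecar override table maps
labels to canonical OBO PURLs where those exist, so released identifiers can
be substituted without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS

from .errors import TermNotFoundError, TermTableError, UnsupportedFormatError

TERM = Namespace("https://w3id.org/biodivlink/term/")
REL = Namespace("https://w3id.org/biodivlink/relation/")
ANN = Namespace("https://w3id.org/biodivlink/annotation/")
ONTOLOGY_IRI = URIRef("https://w3id.org/biodivlink/ontology")

#: IAO 'definition' annotation property (textual definition of a class).
DEFINITION = URIRef("http://purl.obolibrary.org/obo/IAO_0000115")

ONTOLOGY_FORMATS = ("turtle", "rdfxml", "functional-owl-subset")

#: Printed label variants mapped onto the canonical labels used throughout.
LABEL_ALIASES: Mapping[str, str] = {
    "achieves_objective": "achieves_planned_objective",
    "achieves planned objective": "achieves_planned_objective",
    "has part": "has_part",
    "is about": "is_about",
    "realizes o concretizes": "realizes_o_concretizes",
    "multiplexing sequence identifier": "multiplex identifier sequence",
}


@dataclass(frozen=True)
class TermDefinition:
    """One class of the vocabulary with its textual definition."""

    label: str
    definition: str
    target_ontology: str  # OBI | PCO | supporting
    status: str  # released | requested | supporting
    iri: str
    as_printed: bool = False


@dataclass(frozen=True)
class RelationTerm:
    """An object property (or property chain) of the assay pattern."""

    label: str
    iri: str
    kind: str = "object_property"  # object_property | property_chain
    chain: tuple[str, ...] = ()


@dataclass(frozen=True)
class Filler:
    """A class expression: a named class, optionally intersected with
    nested existential restrictions (``head and (rel some filler) and ...``)."""

    head: str
    nested: tuple["Restriction", ...] = ()

    def canonical(self) -> str:
        if not self.nested:
            return self.head
        inner = ", ".join(r.canonical() for r in self.nested)
        return f"and({self.head}, {inner})"

    def labels(self) -> Iterator[str]:
        yield self.head
        for r in self.nested:
            yield from r.filler.labels()


@dataclass(frozen=True)
class Restriction:
    relation: str
    filler: Filler

    def canonical(self) -> str:
        return f"{self.relation} some({self.filler.canonical()})"


@dataclass(frozen=True)
class AxiomRestriction:
    """One ``subject SubClassOf relation some filler`` line of the pattern."""

    subject: str
    relation: str
    filler: Filler

    def canonical(self) -> str:
        return f"{self.subject} | {self.relation} | some({self.filler.canonical()})"

    def n_restrictions(self) -> int:
        """Number of existential restrictions, counting nested ones."""

        def count(f: Filler) -> int:
            return sum(1 + count(r.filler) for r in f.nested)

        return 1 + count(self.filler)


_RELATIONS: tuple[RelationTerm, ...] = tuple(
    RelationTerm(label, str(REL[label]))
    for label in (
        "achieves_planned_objective",
        "has_part",
        "has_specified_input",
        "has_specified_output",
        "precedes",
        "follows",
        "is_about",
        "realizes",
        "concretizes",
    )
) + (
    RelationTerm(
        "realizes_o_concretizes",
        str(REL["realizes_o_concretizes"]),
        kind="property_chain",
        chain=("realizes", "concretizes"),
    ),
)


class Vocabulary:
    """Loaded term set + relation set with alias-aware lookup."""

    def __init__(
        self,
        terms: Iterable[TermDefinition],
        relations: Iterable[RelationTerm],
        validate: bool = True,
    ):
        self.terms: dict[str, TermDefinition] = {}
        for t in terms:
            if not t.label:
                raise TermTableError("term with empty label")
            if t.label in self.terms:
                raise TermTableError(f"duplicate term label: {t.label!r}")
            self.terms[t.label] = t
        iris = [t.iri for t in self.terms.values()]
        if len(set(iris)) != len(iris):
            raise TermTableError("duplicate term IRI in term table")
        self.relations: dict[str, RelationTerm] = {r.label: r for r in relations}
        if validate:
            self._check_term_request_shape()

    def _check_term_request_shape(self) -> None:
        rows = [
            t
            for t in self.terms.values()
            if t.target_ontology in ("OBI", "PCO") and t.status in ("released", "requested")
        ]
        if len(rows) != 8:
            raise TermTableError(
                f"expected exactly 8 OBI/PCO term-request rows, found {len(rows)}"
            )
        pco = [t for t in rows if t.target_ontology == "PCO"]
        if len(pco) != 1 or pco[0].label != "OTU matrix":
            raise TermTableError("expected exactly one PCO row ('OTU matrix')")

    def lookup(self, label: str) -> TermDefinition:
        key = LABEL_ALIASES.get(label, label)
        try:
            return self.terms[key]
        except KeyError:
            raise TermNotFoundError(f"no such term: {label!r}") from None

    def relation(self, label: str) -> RelationTerm:
        key = LABEL_ALIASES.get(label, label)
        try:
            return self.relations[key]
        except KeyError:
            raise TermNotFoundError(f"no such relation: {label!r}") from None

    def term_iri(self, label: str) -> URIRef:
        return URIRef(self.lookup(label).iri)

    def relation_iri(self, label: str) -> URIRef:
        return URIRef(self.relation(label).iri)

    @property
    def term_requests(self) -> list[TermDefinition]:
        return [
            t
            for t in self.terms.values()
            if t.target_ontology in ("OBI", "PCO") and t.status in ("released", "requested")
        ]


def _read_tsv_rows(text: str, source: str) -> Iterator[tuple[int, list[str]]]:
    lines = text.splitlines()
    if not lines:
        raise TermTableError(f"{source}: empty file")
    header = lines[0].split("\t")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TermTableError(
                f"{source}: row at line {lineno} has {len(cells)} cells, expected {len(header)}"
            )
        yield lineno, cells


def load_core_terms() -> Vocabulary:
    """Load the bundled term table and the pattern relations.

    Raises :class:`TermTableError` naming the offending row if the bundled
    table is malformed.
    """
    text = resources.files("biodivlink.data").joinpath("core_terms.tsv").read_text("utf-8")
    terms = []
    for lineno, cells in _read_tsv_rows(text, "core_terms.tsv"):
        label, definition, target, status, iri, as_printed = cells
        if target not in ("OBI", "PCO", "supporting"):
            raise TermTableError(
                f"core_terms.tsv: line {lineno}: bad target_ontology {target!r}"
            )
        if status not in ("released", "requested", "supporting"):
            raise TermTableError(f"core_terms.tsv: line {lineno}: bad status {status!r}")
        terms.append(
            TermDefinition(label, definition, target, status, iri, as_printed == "true")
        )
    return Vocabulary(terms, _RELATIONS)


def _r(relation: str, head: str, *nested: Restriction) -> Restriction:
    return Restriction(relation, Filler(head, tuple(nested)))


#: The assay-pattern axiom block: subject class → existential restrictions.
_AXIOM_SPECS: tuple[tuple[str, Restriction], ...] = (
    ("targeted gene survey", _r("achieves_planned_objective", "biodiversity assessment objective")),
    ("targeted gene survey", _r("has_part", "library preparation")),
    ("targeted gene survey", _r("has_part", "DNA sequencing")),
    (
        "targeted gene survey",
        _r(
            "has_part",
            "library sequence deconvolution",
            _r(
                "precedes",
                "sequence analysis data transformation",
                _r(
                    "has_specified_output",
                    "data item",
                    _r("is_about", "population quality"),
                ),
            ),
        ),
    ),
    ("library preparation", _r("has_part", "polymerase chain reaction")),
    ("library preparation", _r("has_specified_input", "DNA extract")),
    ("library preparation", _r("has_specified_input", "multiplex identifier sequence")),
    ("library preparation", _r("precedes", "DNA sequencing")),
    ("library preparation", _r("has_specified_output", "single fragment library")),
    ("polymerase chain reaction", _r("has_specified_input", "forward pcr primer")),
    ("polymerase chain reaction", _r("has_specified_input", "reverse pcr primer")),
    ("polymerase chain reaction", _r("realizes_o_concretizes", "PCR program")),
)


def build_axioms(vocab: Vocabulary) -> list[AxiomRestriction]:
    """Build the assay-pattern axiom set, resolving every label in *vocab*.

    Raises :class:`TermNotFoundError` naming any unresolvable label.
    """
    axioms = []
    for subject, restriction in _AXIOM_SPECS:
        vocab.lookup(subject)
        vocab.relation(restriction.relation)
        _resolve_filler(vocab, restriction.filler)
        axioms.append(AxiomRestriction(subject, restriction.relation, restriction.filler))
    return axioms


def _resolve_filler(vocab: Vocabulary, filler: Filler) -> None:
    vocab.lookup(filler.head)
    for r in filler.nested:
        vocab.relation(r.relation)
        _resolve_filler(vocab, r.filler)


def axioms_for_subject(axioms: Iterable[AxiomRestriction], subject: str) -> list[AxiomRestriction]:
    return [a for a in axioms if a.subject == subject]


# --------------------------------------------------------------------------
# OWL emission


def _filler_node(g: Graph, vocab: Vocabulary, filler: Filler) -> URIRef | BNode:
    if not filler.nested:
        return vocab.term_iri(filler.head)
    node = BNode()
    g.add((node, RDF.type, OWL.Class))
    members = [vocab.term_iri(filler.head)]
    for r in filler.nested:
        members.append(_restriction_node(g, vocab, r))
    lst = BNode()
    Collection(g, lst, members)
    g.add((node, OWL.intersectionOf, lst))
    return node


def _restriction_node(g: Graph, vocab: Vocabulary, r: Restriction) -> BNode:
    node = BNode()
    g.add((node, RDF.type, OWL.Restriction))
    g.add((node, OWL.onProperty, vocab.relation_iri(r.relation)))
    g.add((node, OWL.someValuesFrom, _filler_node(g, vocab, r.filler)))
    return node


def ontology_graph(vocab: Vocabulary, axioms: Iterable[AxiomRestriction]) -> Graph:
    """Assemble the ontology as an rdflib graph (standard OWL-to-RDF mapping)."""
    g = Graph()
    g.bind("owl", OWL)
    g.bind("term", TERM)
    g.bind("rel", REL)
    g.add((ONTOLOGY_IRI, RDF.type, OWL.Ontology))
    g.add((DEFINITION, RDF.type, OWL.AnnotationProperty))
    for t in vocab.terms.values():
        iri = URIRef(t.iri)
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(t.label)))
        g.add((iri, DEFINITION, Literal(t.definition)))
    for rel in vocab.relations.values():
        iri = URIRef(rel.iri)
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.label, Literal(rel.label)))
        if rel.kind == "property_chain":
            lst = BNode()
            Collection(g, lst, [vocab.relation_iri(x) for x in rel.chain])
            g.add((iri, OWL.propertyChainAxiom, lst))
    for ax in axioms:
        g.add(
            (
                vocab.term_iri(ax.subject),
                RDFS.subClassOf,
                _restriction_node(g, vocab, Restriction(ax.relation, ax.filler)),
            )
        )
    return g


def _fss_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _fss_filler(vocab: Vocabulary, filler: Filler) -> str:
    if not filler.nested:
        return f"<{vocab.term_iri(filler.head)}>"
    parts = [f"<{vocab.term_iri(filler.head)}>"]
    parts += [_fss_restriction(vocab, r) for r in filler.nested]
    return "ObjectIntersectionOf(" + " ".join(parts) + ")"


def _fss_restriction(vocab: Vocabulary, r: Restriction) -> str:
    return (
        f"ObjectSomeValuesFrom(<{vocab.relation_iri(r.relation)}> "
        f"{_fss_filler(vocab, r.filler)})"
    )


def _emit_functional(vocab: Vocabulary, axioms: Iterable[AxiomRestriction]) -> str:
    lines = [
        "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
        "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
        f"Ontology(<{ONTOLOGY_IRI}>",
        f"Declaration(AnnotationProperty(<{DEFINITION}>))",
    ]
    for t in vocab.terms.values():
        lines.append(f"Declaration(Class(<{t.iri}>))")
        lines.append(f'AnnotationAssertion(rdfs:label <{t.iri}> "{_fss_escape(t.label)}")')
        lines.append(
            f'AnnotationAssertion(<{DEFINITION}> <{t.iri}> "{_fss_escape(t.definition)}")'
        )
    for rel in vocab.relations.values():
        lines.append(f"Declaration(ObjectProperty(<{rel.iri}>))")
        lines.append(f'AnnotationAssertion(rdfs:label <{rel.iri}> "{_fss_escape(rel.label)}")')
        if rel.kind == "property_chain":
            chain = " ".join(f"<{vocab.relation_iri(x)}>" for x in rel.chain)
            lines.append(f"SubObjectPropertyOf(ObjectPropertyChain({chain}) <{rel.iri}>)")
    for ax in axioms:
        lines.append(
            f"SubClassOf(<{vocab.term_iri(ax.subject)}> "
            f"{_fss_restriction(vocab, Restriction(ax.relation, ax.filler))})"
        )
    lines.append(")")
    return "\n".join(lines) + "\n"


def emit_ontology(vocab: Vocabulary, axioms: Iterable[AxiomRestriction], format: str) -> str:
    """Serialize the ontology. Supported formats: turtle, rdfxml,
    functional-owl-subset."""
    axioms = list(axioms)
    if format == "turtle":
        return ontology_graph(vocab, axioms).serialize(format="turtle")
    if format == "rdfxml":
        return ontology_graph(vocab, axioms).serialize(format="xml")
    if format == "functional-owl-subset":
        return _emit_functional(vocab, axioms)
    raise UnsupportedFormatError(
        f"unsupported ontology format {format!r}; supported: {', '.join(ONTOLOGY_FORMATS)}"
    )


@dataclass(frozen=True)
class OntologySummary:
    """Structural fingerprint of an ontology document, for round-trip checks."""

    n_classes: int
    n_restrictions: int
    labels: frozenset[str] = field(default_factory=frozenset)
    definitions: frozenset[str] = field(default_factory=frozenset)


def summarize_ontology(document: str, format: str) -> OntologySummary:
    """Re-parse an emitted ontology document and count its named classes,
    existential restrictions, labels and definition strings."""
    if format in ("turtle", "rdfxml"):
        g = Graph()
        g.parse(data=document, format="turtle" if format == "turtle" else "xml")
        classes = [s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)]
        restrictions = list(g.subjects(RDF.type, OWL.Restriction))
        labels = frozenset(str(o) for o in g.objects(None, RDFS.label))
        defs = frozenset(str(o) for o in g.objects(None, DEFINITION))
        return OntologySummary(len(classes), len(restrictions), labels, defs)
    if format == "functional-owl-subset":
        n_classes = document.count("Declaration(Class(")
        n_restrictions = document.count("ObjectSomeValuesFrom(")
        labels = frozenset(
            m.group(1).replace('\\"', '"').replace("\\\\", "\\")
            for m in re.finditer(r'AnnotationAssertion\(rdfs:label <[^>]+> "((?:[^"\\]|\\.)*)"\)', document)
        )
        defs = frozenset(
            m.group(1).replace('\\"', '"').replace("\\\\", "\\")
            for m in re.finditer(
                r'AnnotationAssertion\(<[^>]*IAO_0000115> <[^>]+> "((?:[^"\\]|\\.)*)"\)', document
            )
        )
        return OntologySummary(n_classes, n_restrictions, labels, defs)
    raise UnsupportedFormatError(
        f"unsupported ontology format {format!r}; supported: {', '.join(ONTOLOGY_FORMATS)}"
    )


def expected_summary(vocab: Vocabulary, axioms: Iterable[AxiomRestriction]) -> OntologySummary:
    """Structural fingerprint computed directly from the in-memory objects."""
    axioms = list(axioms)
    labels = frozenset(t.label for t in vocab.terms.values()) | frozenset(
        r.label for r in vocab.relations.values()
    )
    return OntologySummary(
        n_classes=len(vocab.terms),
        n_restrictions=sum(a.n_restrictions() for a in axioms),
        labels=labels,
        definitions=frozenset(t.definition for t in vocab.terms.values()),
    )
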