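"""Competency queries and pattern-conformance checking.

An ontology is fit for purpose when its instance graphs answer the questions
it was designed for. Two such questions drive this module: "What assays can
be used to study biodiversity?" and "Which PCR primers can be used to study
biodiversity?" — shipped as standard SPARQL rewrites of the informal printed
queries. :func:`verify_pattern` performs the converse check: every individual
typed with a pattern class must witness, at the instance level, each
existential restriction its class carries (chain-aware for the
realizes∘concretizes axiom and recursive for nested intersections).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from rdflib import URIRef
from rdflib.namespace import RDF
from rdflib.plugins.sparql import prepareQuery  # noqa: F401  (early syntax check)

from .convert import InstanceGraph
from .ontology import AxiomRestriction, Filler, Vocabulary, load_core_terms

BUILTIN_QUERIES = ("biodiversity-assays", "primers")


@dataclass
class QueryResultTable:
    variables: tuple[str, ...]
    rows: list[tuple[str, ...]]

    def to_tsv(self) -> str:
        lines = ["\t".join(self.variables)]
        lines += ["\t".join(row) for row in self.rows]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {"variables": list(self.variables), "rows": [list(r) for r in self.rows]},
            indent=2,
        )

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PatternReport:
    checked: int = 0
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def conforms(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            {
                "checked": self.checked,
                "violations": [
                    {"individual": iri, "missing": desc} for iri, desc in self.violations
                ],
            },
            indent=2,
        )


def load_query(name: str) -> str:
    filename = {"biodiversity-assays": "biodiversity_assays.rq", "primers": "primers.rq"}.get(name)
    if filename is None:
        raise KeyError(f"no builtin query {name!r}; available: {', '.join(BUILTIN_QUERIES)}")
    return resources.files("biodivlink.data.queries").joinpath(filename).read_text("utf-8")


def run_sparql(instance_graph: InstanceGraph, query_text: str) -> QueryResultTable:
    """Run a SPARQL SELECT or ASK query with standard semantics. Results are
    deduplicated and sorted so they are insensitive to statement order."""
    result = instance_graph.graph.query(query_text)
    if result.type == "ASK":
        return QueryResultTable(("ask",), [(str(bool(result.askAnswer)).lower(),)])
    variables = tuple(str(v) for v in result.vars)
    rows = sorted(
        {
            tuple("" if b is None else str(b) for b in binding)
            for binding in result
        }
    )
    return QueryResultTable(variables, rows)


def query_biodiversity_assays(instance_graph: InstanceGraph) -> QueryResultTable:
    """All individuals achieving a 'biodiversity assessment objective'."""
    return run_sparql(instance_graph, load_query("biodiversity-assays"))


def query_primers(instance_graph: InstanceGraph) -> QueryResultTable:
    """(survey, primer) pairs where the primer is a specified input of a
    process that is part of the survey."""
    return run_sparql(instance_graph, load_query("primers"))


# --------------------------------------------------------------------------
# Pattern conformance


def _filler_derivations(g, vocab: Vocabulary, obj, filler: Filler) -> list[frozenset]:
    """All derivations showing *obj* satisfies *filler*; each derivation is
    the frozenset of statements it relies on."""
    cls = vocab.term_iri(filler.head)
    typing = (obj, RDF.type, cls)
    if typing not in g:
        return []
    derivs = [frozenset({typing})]
    for r in filler.nested:
        extended = []
        sub = _restriction_derivations(g, vocab, obj, r.relation, r.filler)
        if not sub:
            return []
        for d in derivs:
            for s in sub:
                extended.append(d | s)
        derivs = extended
    return derivs


def _restriction_derivations(
    g, vocab: Vocabulary, ind, relation: str, filler: Filler
) -> list[frozenset]:
    rel = vocab.relation(relation)
    derivs = []
    if rel.kind == "property_chain":
        first, second = (vocab.relation_iri(x) for x in rel.chain)
        for middle in g.objects(ind, first):
            for obj in g.objects(middle, second):
                for fd in _filler_derivations(g, vocab, obj, filler):
                    derivs.append(frozenset({(ind, first, middle), (middle, second, obj)}) | fd)
    else:
        pred = URIRef(rel.iri)
        for obj in g.objects(ind, pred):
            for fd in _filler_derivations(g, vocab, obj, filler):
                derivs.append(frozenset({(ind, pred, obj)}) | fd)
    return derivs


def verify_pattern(
    instance_graph: InstanceGraph,
    axioms: list[AxiomRestriction],
    vocab: Vocabulary | None = None,
) -> PatternReport:
    """Check that every individual typed with an axiom subject class
    witnesses each of that class's existential restrictions."""
    vocab = vocab or load_core_terms()
    g = instance_graph.graph
    report = PatternReport()
    for subject in sorted({a.subject for a in axioms}):
        subject_axioms = [a for a in axioms if a.subject == subject]
        for ind in sorted(g.subjects(RDF.type, vocab.term_iri(subject))):
            report.checked += 1
            for ax in subject_axioms:
                if not _restriction_derivations(g, vocab, ind, ax.relation, ax.filler):
                    report.violations.append(
                        (
                            str(ind),
                            f"{subject}: no witness for "
                            f"{ax.relation} some({ax.filler.canonical()})",
                        )
                    )
    return report


def breaking_witness_statements(
    instance_graph: InstanceGraph,
    axioms: list[AxiomRestriction],
    vocab: Vocabulary | None = None,
) -> set[tuple]:
    """Statements whose single deletion breaks at least one witnessed
    restriction: for each (individual, restriction), the intersection of all
    its witness derivations."""
    vocab = vocab or load_core_terms()
    g = instance_graph.graph
    breaking: set[tuple] = set()
    for ax in axioms:
        for ind in g.subjects(RDF.type, vocab.term_iri(ax.subject)):
            derivs = _restriction_derivations(g, vocab, ind, ax.relation, ax.filler)
            if derivs:
                essential = frozenset.intersection(*derivs)
                breaking.update(essential)
    return breaking
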