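"""Instance layer: individuals, typed assertions and row-level provenance.

The store is a deliberately simple in-memory RDF-style graph with set
semantics: adding the same assertion twice is a no-op (the same peptide
legitimately arrives from several source files).  Every individual gets a
stable IRI — no blank nodes — so serialization round trips reduce to plain
set comparisons, and sorted N-Triples output is byte-reproducible.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from rdflib import Graph, Literal, RDF, RDFS, URIRef, XSD

from . import schema as schema_mod
from .naming import INSTANCE_NS, instance_iri
from .schema import SchemaModel, register_punned_class

log = logging.getLogger(__name__)

TABLE_ROLES = (
    "peptide_clusters", "pswm_annotation", "closed_search", "denovo_search",
    "open_search", "mutations", "epitope_contigs", "peptide_library",
    "id_mappings", "study_metadata",
)

_DT_TO_XSD = {
    "text": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.decimal,
    "boolean": XSD.boolean,
}
_XSD_TO_DT = {str(v): k for k, v in _DT_TO_XSD.items()}


class IntegrityError(ValueError):
    """An assertion references an unknown individual or class."""


def canonical_lexical(value, datatype: str) -> str:
    """Shortest round-trip lexical form for a literal (byte-stable output)."""
    if datatype == "boolean":
        return "true" if value else "false"
    if datatype == "integer":
        return str(int(value))
    if datatype == "decimal":
        return repr(float(value))
    return str(value)


def parse_lexical(lexical: str, datatype: str):
    if datatype == "boolean":
        return lexical.strip().lower() in ("true", "1")
    if datatype == "integer":
        return int(lexical)
    if datatype == "decimal":
        return float(lexical)
    return lexical


@dataclass(frozen=True)
class SourceRef:
    """Where an assertion came from: (file role, 1-based data row, column)."""

    file_role: str
    row_number: int
    column: str

    def __post_init__(self):
        if self.file_role not in TABLE_ROLES:
            raise ValueError(f"unknown file role {self.file_role!r}")
        if self.row_number < 1:
            raise ValueError("row_number is 1-based (header excluded)")


@dataclass
class Individual:
    iri: str
    types: set[str]
    label: str = ""

    def __post_init__(self):
        if not self.types:
            raise IntegrityError(f"individual {self.iri} needs >= 1 type")


@dataclass(frozen=True)
class Assertion:
    """One object- or data-property assertion.

    Exactly one of ``object`` / ``value`` is set.  Provenance is carried
    alongside but excluded from identity (set semantics collapse the same
    statement arriving from different files).
    """

    subject: str
    predicate: str
    object: str | None = None
    value: object | None = None
    datatype: str | None = None
    provenance: SourceRef | None = field(default=None, compare=False)

    def __post_init__(self):
        if (self.object is None) == (self.value is None):
            raise ValueError(
                "exactly one of object-identifier / literal must be set")
        if self.value is not None and self.datatype not in _DT_TO_XSD:
            raise ValueError(f"datatype must be one of {tuple(_DT_TO_XSD)}")

    @property
    def is_object(self) -> bool:
        return self.object is not None


class InstanceGraph:
    """Individuals plus assertions, indexed by subject/predicate/object."""

    def __init__(self, schema: SchemaModel | None = None,
                 instance_namespace: str = INSTANCE_NS):
        self.schema = schema
        self.instance_namespace = instance_namespace
        self.individuals: dict[str, Individual] = {}
        self.assertions: set[Assertion] = set()
        self._fwd: dict[str, dict[str, set[str]]] = defaultdict(
            lambda: defaultdict(set))
        self._rev: dict[str, dict[str, set[str]]] = defaultdict(
            lambda: defaultdict(set))
        self._data: dict[str, dict[str, set]] = defaultdict(
            lambda: defaultdict(set))
        self._by_type: dict[str, set[str]] = defaultdict(set)
        self._provenance: dict[Assertion, SourceRef] = {}

    # -- construction ------------------------------------------------------

    def mint_individual(self, class_iri: str, local_name: str,
                        label: str | None = None,
                        punned: bool = False) -> Individual:
        """Add (or fetch) an individual with a deterministic IRI.

        Idempotent: re-minting the same local name returns the existing
        individual, adding the class to its type set if new.  With
        ``punned=True`` the IRI is also registered as a class facet
        (subclass of ``class_iri``) in the governing schema.
        """
        if self.schema is not None and class_iri not in self.schema.classes:
            raise IntegrityError(f"unknown class {class_iri}")
        iri = instance_iri(local_name, self.instance_namespace)
        ind = self.individuals.get(iri)
        if ind is None:
            ind = Individual(iri, {class_iri}, label or str(local_name))
            self.individuals[iri] = ind
            self._by_type[class_iri].add(iri)
        elif class_iri not in ind.types:
            ind.types.add(class_iri)
            self._by_type[class_iri].add(iri)
        if punned and self.schema is not None:
            from .naming import slug
            register_punned_class(self.schema, iri, slug(local_name),
                                  class_iri)
        return ind

    def add_individual(self, ind: Individual) -> Individual:
        self.individuals[ind.iri] = ind
        for t in ind.types:
            self._by_type[t].add(ind.iri)
        return ind

    def add_assertion(self, assertion: Assertion) -> "InstanceGraph":
        """Store an assertion once; duplicates are ignored with a notice."""
        if assertion.subject not in self.individuals:
            raise IntegrityError(
                f"dangling subject {assertion.subject} in assertion")
        if assertion.is_object and assertion.object not in self.individuals:
            raise IntegrityError(
                f"dangling object {assertion.object} in assertion")
        if assertion in self.assertions:
            log.debug("duplicate assertion ignored: %s %s",
                      assertion.subject, assertion.predicate)
            return self
        self._index(assertion)
        return self

    def _index(self, assertion: Assertion) -> None:
        """Index without integrity checks (used by violation injection)."""
        self.assertions.add(assertion)
        if assertion.is_object:
            self._fwd[assertion.predicate][assertion.subject].add(
                assertion.object)
            self._rev[assertion.predicate][assertion.object].add(
                assertion.subject)
        else:
            self._data[assertion.predicate][assertion.subject].add(
                (assertion.value, assertion.datatype))
        if assertion.provenance is not None:
            self._provenance[assertion] = assertion.provenance

    def discard(self, assertion: Assertion) -> None:
        if assertion not in self.assertions:
            return
        self.assertions.discard(assertion)
        if assertion.is_object:
            self._fwd[assertion.predicate][assertion.subject].discard(
                assertion.object)
            self._rev[assertion.predicate][assertion.object].discard(
                assertion.subject)
        else:
            self._data[assertion.predicate][assertion.subject].discard(
                (assertion.value, assertion.datatype))
        self._provenance.pop(assertion, None)

    # -- lookups -----------------------------------------------------------

    def objects(self, subject: str, predicate: str) -> set[str]:
        return set(self._fwd[predicate].get(subject, ()))

    def subjects(self, predicate: str, object: str) -> set[str]:
        return set(self._rev[predicate].get(object, ()))

    def values(self, subject: str, predicate: str) -> set:
        return {v for v, _ in self._data[predicate].get(subject, ())}

    def of_type(self, class_iri: str) -> set[str]:
        return set(self._by_type.get(class_iri, ()))

    def provenance_of(self, assertion: Assertion) -> SourceRef | None:
        return self._provenance.get(assertion)

    # -- statistics / equality ---------------------------------------------

    def statistics(self) -> dict:
        per_class: dict[str, int] = defaultdict(int)
        for ind in self.individuals.values():
            for t in ind.types:
                per_class[t] += 1
        return {
            "individuals": len(self.individuals),
            "object_assertions": sum(
                1 for a in self.assertions if a.is_object),
            "data_assertions": sum(
                1 for a in self.assertions if not a.is_object),
            "per_class": dict(per_class),
        }

    def _key(self):
        inds = frozenset(
            (i.iri, frozenset(i.types), i.label)
            for i in self.individuals.values())
        return inds, frozenset(self.assertions)

    def __eq__(self, other) -> bool:
        return isinstance(other, InstanceGraph) and self._key() == other._key()

    def __hash__(self):  # pragma: no cover
        return hash(self._key())

    # -- serialization -----------------------------------------------------

    def to_rdflib(self) -> Graph:
        g = Graph()
        g.bind("impo", schema_mod.SCHEMA_NS)
        g.bind("inst", self.instance_namespace)
        for ind in self.individuals.values():
            node = URIRef(ind.iri)
            for t in sorted(ind.types):
                g.add((node, RDF.type, URIRef(t)))
            if ind.label:
                g.add((node, RDFS.label, Literal(ind.label)))
        for a in self.assertions:
            s = URIRef(a.subject)
            p = URIRef(a.predicate)
            if a.is_object:
                g.add((s, p, URIRef(a.object)))
            else:
                g.add((s, p, Literal(
                    canonical_lexical(a.value, a.datatype),
                    datatype=_DT_TO_XSD[a.datatype])))
        return g

    def serialize(self, format: str = "turtle") -> str:
        """Serialize as Turtle or (sorted, byte-stable) N-Triples."""
        if format in ("turtle", "ttl"):
            return self.to_rdflib().serialize(format="turtle")
        if format in ("nt", "ntriples", "nt11"):
            lines = self.to_rdflib().serialize(format="nt11").splitlines()
            return "\n".join(sorted(l for l in lines if l.strip())) + "\n"
        raise ValueError(f"unknown format {format!r}")


def parse(document: str, schema: SchemaModel | None = None,
          format: str = "turtle") -> InstanceGraph:
    """Parse a Turtle / N-Triples document back into an InstanceGraph.

    ``parse(g.serialize(fmt))`` equals ``g`` (identical individual and
    assertion sets; in-memory provenance is not serialized).
    """
    rg = Graph()
    try:
        rg.parse(data=document, format=format)
    except Exception as exc:
        raise ValueError(f"malformed instance document: {exc}") from exc
    g = InstanceGraph(schema=schema)
    for s, _, o in rg.triples((None, RDF.type, None)):
        if not isinstance(s, URIRef) or not isinstance(o, URIRef):
            continue
        iri = str(s)
        ind = g.individuals.get(iri)
        if ind is None:
            g.add_individual(Individual(iri, {str(o)}))
        else:
            ind.types.add(str(o))
            g._by_type[str(o)].add(iri)
    for s, p, o in rg:
        if p in (RDF.type, RDFS.label):
            if p == RDFS.label and str(s) in g.individuals:
                g.individuals[str(s)].label = str(o)
            continue
        if not isinstance(s, URIRef):
            continue
        if isinstance(o, URIRef):
            a = Assertion(str(s), str(p), object=str(o))
        elif isinstance(o, Literal):
            dt = _XSD_TO_DT.get(str(o.datatype), "text")
            a = Assertion(str(s), str(p),
                          value=parse_lexical(str(o), dt), datatype=dt)
        else:
            continue
        if a not in g.assertions:
            g._index(a)
    return g


# -- module-level operation aliases (spec surface) --------------------------

def mint_individual(graph: InstanceGraph, class_iri: str, local_name: str,
                    label: str | None = None,
                    punned: bool = False) -> Individual:
    return graph.mint_individual(class_iri, local_name, label=label,
                                 punned=punned)


def add_assertion(graph: InstanceGraph, assertion: Assertion) -> InstanceGraph:
    return graph.add_assertion(assertion)


def serialize(graph: InstanceGraph, format: str = "turtle") -> str:
    return graph.serialize(format=format)


def graph_statistics(graph: InstanceGraph) -> dict:
    return graph.statistics()
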