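"""Terminological layer: classes, properties, restrictions and their checks.

The semantic model mirrors how immunopeptidomics experiments are reported:
an *assay* (mass spectrometry) performed on a *sample* has *assay results*
(spectra), and *assignments* record the inferred relations between results
and *analytes* (peptides, proteins, genes, mutations, HLAs, motifs, epitope
contigs, ...).  Genes are metamodelled by punning — one IRI may denote both
a class facet (``MET_gene`` as a subclass of ``gene``) and an individual
facet (the reference-genome gene).

The module holds an in-memory :class:`SchemaModel`, a builder for the
normative core schema, RDF (de)serialization via rdflib, descriptive
statistics, an OWL 2 DL profile check for the one rule that bites in this
domain (cardinality restrictions on transitive properties) and a scanner
for five common structural design pitfalls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef, XSD

from .naming import SCHEMA_NS, class_iri, label_to_local, local_name

OBO_IN_OWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")
DCTERMS = Namespace("http://purl.org/dc/terms/")
IMPO_META = Namespace("https://w3id.org/impo/meta#")

#: The four supported literal kinds and their XSD counterparts.
DATATYPES = ("text", "integer", "decimal", "boolean")
_DT_TO_XSD = {
    "text": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.decimal,
    "boolean": XSD.boolean,
}
_XSD_TO_DT = {str(v): k for k, v in _DT_TO_XSD.items()}

RESTRICTION_KINDS = ("some", "only", "exactly", "min", "max")
_CARDINALITY_KINDS = ("exactly", "min", "max")

DEFAULT_LICENSE = "https://creativecommons.org/licenses/by/4.0/"


class SchemaError(ValueError):
    """A schema invariant is violated (the message names the invariant)."""


class SchemaLoadError(SchemaError):
    """An RDF document could not be parsed into a SchemaModel."""


@dataclass(frozen=True)
class ClassDef:
    iri: str
    label: str
    definition: str = ""
    parents: frozenset[str] = frozenset()
    disjoint_with: frozenset[str] = frozenset()
    punned: bool = False
    cross_references: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ObjectPropertyDef:
    iri: str
    label: str
    domain: frozenset[str] = frozenset()
    range: frozenset[str] = frozenset()
    inverse: str | None = None
    transitive: bool = False
    #: deliberately unrestricted domain/range (exempt from pitfall P11)
    broad_scope: bool = False
    #: an inverse is not expected at the data level (exempt from P13)
    inverse_exempt: bool = False


@dataclass(frozen=True)
class DataPropertyDef:
    iri: str
    label: str
    domain: frozenset[str] = frozenset()
    range_datatype: str = "text"


@dataclass(frozen=True)
class Restriction:
    """An anonymous superclass ``on_class ⊑ (property kind filler/card)``."""

    on_class: str
    property: str
    kind: str
    filler: str | None = None
    cardinality: int | None = None


@dataclass
class EntityCounts:
    classes: int = 0
    object_properties: int = 0
    data_properties: int = 0
    punned_entities: int = 0
    cross_references: int = 0


@dataclass(frozen=True)
class ProfileViolation:
    property: str
    restriction: Restriction
    message: str


@dataclass(frozen=True)
class PitfallFinding:
    code: str
    severity: str  # minor | important | critical
    message: str
    entities: tuple[str, ...] = ()


@dataclass
class PitfallReport:
    findings: dict[str, list[PitfallFinding]] = field(default_factory=dict)

    def add(self, finding: PitfallFinding) -> None:
        self.findings.setdefault(finding.code, []).append(finding)

    def __getitem__(self, code: str) -> list[PitfallFinding]:
        return self.findings.get(code, [])

    def all_findings(self) -> list[PitfallFinding]:
        return [f for fs in self.findings.values() for f in fs]

    @property
    def has_critical(self) -> bool:
        return any(f.severity == "critical" for f in self.all_findings())


#: Severity assigned to each implemented pitfall check.
PITFALL_SEVERITY = {
    "P02": "critical",
    "P10": "important",
    "P11": "important",
    "P13": "minor",
    "P41": "important",
}


class SchemaModel:
    """Collections of class/property/restriction definitions with indexes."""

    def __init__(self, namespace: str = SCHEMA_NS, license: str | None = None):
        self.namespace = namespace
        self.classes: dict[str, ClassDef] = {}
        self.object_properties: dict[str, ObjectPropertyDef] = {}
        self.data_properties: dict[str, DataPropertyDef] = {}
        self.restrictions: list[Restriction] = []
        #: pairs of named classes declared equivalent (pitfall P02 feed)
        self.equivalences: set[frozenset[str]] = set()
        self.license = license
        #: non-fatal notes collected while loading an RDF document
        self.load_warnings: list[str] = []

    # -- construction -----------------------------------------------------

    def add_class(self, cdef: ClassDef) -> ClassDef:
        existing = self.classes.get(cdef.iri)
        if existing is not None and not (existing.punned or cdef.punned):
            raise SchemaError(f"duplicate class iri (no punning): {cdef.iri}")
        self.classes[cdef.iri] = cdef
        return cdef

    def add_object_property(self, pdef: ObjectPropertyDef) -> ObjectPropertyDef:
        self.object_properties[pdef.iri] = pdef
        return pdef

    def add_data_property(self, pdef: DataPropertyDef) -> DataPropertyDef:
        self.data_properties[pdef.iri] = pdef
        return pdef

    def add_restriction(self, r: Restriction) -> Restriction:
        if r not in self.restrictions:
            self.restrictions.append(r)
        return r

    # -- indexes -----------------------------------------------------------

    def by_label(self, label: str) -> ClassDef | ObjectPropertyDef | DataPropertyDef:
        for coll in (self.classes, self.object_properties, self.data_properties):
            for e in coll.values():
                if e.label == label:
                    return e
        raise KeyError(label)

    def cls(self, local: str) -> ClassDef:
        """Look up a class by its local name in the schema namespace."""
        return self.classes[class_iri(local, self.namespace)]

    def prop(self, local: str) -> str:
        """IRI of an (object or data) property given its local name."""
        iri = class_iri(local, self.namespace)
        if iri not in self.object_properties and iri not in self.data_properties:
            raise KeyError(local)
        return iri

    def is_property(self, iri: str) -> bool:
        return iri in self.object_properties or iri in self.data_properties

    def ancestors(self, iri: str) -> frozenset[str]:
        """Reflexive-transitive subclass closure upward (punning-safe:
        only class facets participate)."""
        seen: set[str] = set()
        stack = [iri]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            cdef = self.classes.get(cur)
            if cdef is not None:
                stack.extend(cdef.parents)
        return frozenset(seen)

    def descendants(self, iri: str) -> frozenset[str]:
        down: set[str] = {iri}
        changed = True
        while changed:
            changed = False
            for c in self.classes.values():
                if c.iri not in down and c.parents & down:
                    down.add(c.iri)
                    changed = True
        return frozenset(down)

    def disjoint_closure(self) -> set[frozenset[str]]:
        """Every unordered class pair whose members (or ancestors) are
        declared disjoint."""
        pairs: set[frozenset[str]] = set()
        declared = [
            (c.iri, d) for c in self.classes.values() for d in c.disjoint_with
        ]
        for a, b in declared:
            for da in self.descendants(a):
                for db in self.descendants(b):
                    if da != db:
                        pairs.add(frozenset((da, db)))
        return pairs

    # -- invariants --------------------------------------------------------

    def check_invariants(self) -> list[str]:
        """Return violated-invariant descriptions (empty when valid)."""
        problems: list[str] = []
        known = set(self.classes)

        for c in self.classes.values():
            if label_to_local(c.label) != local_name(c.iri):
                problems.append(
                    f"naming convention: local name {local_name(c.iri)!r} "
                    f"!= label {c.label!r} with underscores"
                )
            for p in c.parents:
                if p not in known:
                    problems.append(f"unresolved parent {p} of {c.iri}")
            for d in c.disjoint_with:
                if d not in known:
                    problems.append(f"unresolved disjoint class {d} of {c.iri}")
                elif c.iri not in self.classes[d].disjoint_with:
                    problems.append(
                        f"disjointness not symmetric: {c.iri} / {d}"
                    )

        # subclass acyclicity (punned facets are ordinary nodes here)
        state: dict[str, int] = {}

        def visit(iri: str) -> bool:
            state[iri] = 1
            for p in self.classes.get(iri, ClassDef(iri, "")).parents:
                st = state.get(p)
                if st == 1:
                    return False
                if st is None and not visit(p):
                    return False
            state[iri] = 2
            return True

        for iri in self.classes:
            if state.get(iri) is None and not visit(iri):
                problems.append(f"subclass cycle through {iri}")
                break

        for p in self.object_properties.values():
            for ref in itertools.chain(p.domain, p.range):
                if ref not in known:
                    problems.append(f"unresolved domain/range {ref} of {p.iri}")
            if p.inverse is not None:
                q = self.object_properties.get(p.inverse)
                if q is None:
                    problems.append(f"unresolved inverse {p.inverse} of {p.iri}")
                elif q.inverse != p.iri:
                    problems.append(f"inverse not mutual: {p.iri} / {p.inverse}")

        for dp in self.data_properties.values():
            if dp.range_datatype not in DATATYPES:
                problems.append(
                    f"range_datatype of {dp.iri} must be one of {DATATYPES}"
                )
            for ref in dp.domain:
                if ref not in known:
                    problems.append(f"unresolved domain {ref} of {dp.iri}")

        for r in self.restrictions:
            if r.kind not in RESTRICTION_KINDS:
                problems.append(f"unknown restriction kind {r.kind}")
                continue
            if (r.cardinality is not None) != (r.kind in _CARDINALITY_KINDS):
                problems.append(
                    f"cardinality present iff kind in {_CARDINALITY_KINDS}: {r}"
                )
            if r.cardinality is not None and r.cardinality < 0:
                problems.append(f"negative cardinality: {r}")
            if r.on_class not in known:
                problems.append(f"unresolved restricted class {r.on_class}")
            if not self.is_property(r.property):
                problems.append(f"unresolved restricted property {r.property}")
            if (
                r.filler is not None
                and r.filler not in known
                and r.filler not in DATATYPES
            ):
                problems.append(f"unresolved filler {r.filler}")

        for pair in self.equivalences:
            for e in pair:
                if e not in known:
                    problems.append(f"unresolved equivalent class {e}")
        return problems

    def validate(self) -> None:
        problems = self.check_invariants()
        if problems:
            raise SchemaError("; ".join(problems))

    # -- equality ----------------------------------------------------------

    def _key(self):
        return (
            frozenset(self.classes.values()),
            frozenset(self.object_properties.values()),
            frozenset(self.data_properties.values()),
            frozenset(self.restrictions),
            frozenset(self.equivalences),
            self.license,
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, SchemaModel) and self._key() == other._key()

    def __hash__(self):  # pragma: no cover - models are rarely hashed
        return hash(self._key())


# ---------------------------------------------------------------------------
# Normative core schema


_TOP_LEVEL = [
    ("analyte", "a molecular entity identified or characterized by an assay"),
    ("assay", "an experimental procedure applied to a sample"),
    ("assay result", "an output produced by an assay"),
    ("assignment", "an inferred relation between an assay result and an "
     "analyte, or between two analytes"),
    ("sample", "biological material analyzed in a study"),
    ("study", "a registered investigation contributing data"),
    ("cancer", "a disease of uncontrolled cellular growth driven by "
     "mutations"),
    ("ms instrument", "a mass-spectrometry instrument model"),
    ("tissue", "the tissue of origin of a sample"),
    ("cell line", "a cultured cell line of origin of a sample"),
    ("organ", "the organ of origin of a sample"),
    ("patient", "the person a sample derives from"),
]

_ANALYTE_SUBS = [
    ("gene", "a unit of heredity on the reference genome"),
    ("transcript", "an RNA product of a gene"),
    ("protein", "a polypeptide translated from a transcript"),
    ("peptide", "a short amino-acid sequence, here typically an HLA-"
     "presented ligand of 8-12 residues"),
    ("mutation", "a somatic variant over the reference genome"),
    ("post translational modification", "a chemical modification of a "
     "peptide characterized by position and mass shift"),
    ("human leukocyte antigen", "an HLA molecule presenting peptides on "
     "the cell surface"),
    ("motif", "a position-specific weight-matrix cluster of peptides used "
     "to infer the presenting HLA allele"),
    ("epitope contig", "a proposed region on the human genome surveyed by "
     "the immune system at a high frequency"),
    ("reference genome", "the reference assembly genes are placed on"),
    ("genomic region", "a chromosomal interval"),
]

_CANCER_SUBS = [
    "melanoma", "leukemia", "carcinoma", "colon cancer", "breast cancer",
    "brain cancer", "lung cancer", "lymphoma", "neuroblastoma", "bone cancer",
]

# (label, domain locals, range locals, inverse label, transitive,
#  broad_scope, inverse_exempt)
_OBJECT_PROPS = [
    ("has output", ["assay"], ["assay result"], "output of", False, False, False),
    ("has source", ["assignment"], ["assay result", "analyte"],
     "source of", False, False, False),
    ("has target", ["assignment"], ["analyte"], "target of", False, False, False),
    ("part of", [], [], "has part", True, True, False),
    ("member of", [], [], "has member", False, True, False),
    ("performed on", ["assay"], ["sample"], "analyzed by", False, False, False),
    ("uses instrument", ["mass spectrometry"], ["ms instrument"],
     "instrument of", False, False, False),
    ("transcribed to", ["gene"], ["transcript"], "transcribed from",
     False, False, False),
    ("translated to", ["transcript"], ["protein"], "translated from",
     False, False, False),
    ("has motif", ["human leukocyte antigen"], ["motif"], "motif of",
     False, False, False),
    ("derived from", ["motif"], ["peptide"], "derives", False, False, False),
    ("observed in", ["human leukocyte antigen"], ["sample"], "has hla",
     False, False, False),
    ("has cancer", ["sample"], ["cancer"], "cancer of", False, False, False),
    ("contains peptide", ["epitope contig"], ["peptide"], "contained in",
     False, False, False),
    ("located in", ["mutation"], ["epitope contig"], "contains mutation",
     False, False, False),
    ("modifies", ["post translational modification"], ["peptide"],
     "modified by", False, False, False),
    ("overlaps mutation", ["peptide genome assignment"], ["mutation"],
     "mutation overlapped by", False, False, False),
    ("has reference genome", ["gene"], ["reference genome"], None,
     False, False, True),
]

# (label, domain locals, datatype)
_DATA_PROPS = [
    ("has score", ["spectrum peptide identification"], "decimal"),
    ("has start position",
     ["peptide protein assignment", "peptide genome assignment",
      "mutation", "epitope contig"], "integer"),
    ("has end position",
     ["peptide protein assignment", "peptide genome assignment",
      "mutation", "epitope contig"], "integer"),
    ("has probability", ["peptide protein assignment"], "decimal"),
    ("has chromosome",
     ["mutation", "epitope contig", "peptide genome assignment"], "text"),
    ("has strand", ["mutation", "epitope contig"], "text"),
    ("expression", ["epitope contig"], "decimal"),
    ("population coverage", ["epitope contig"], "decimal"),
    ("immune score", ["epitope contig"], "decimal"),
    ("gene mutational ratio", ["epitope contig"], "decimal"),
    ("overlap score", ["epitope contig"], "decimal"),
    ("has mass shift", ["post translational modification"], "decimal"),
    ("has modification position", ["post translational modification"],
     "integer"),
    ("has modification type", ["post translational modification"], "text"),
    ("has sequence", ["peptide"], "text"),
    ("has ms strategy", ["spectrum peptide identification"], "text"),
    ("has tag", ["peptide genome assignment"], "text"),
    ("has pswm group", ["motif"], "text"),
    ("has component 1", ["motif"], "decimal"),
    ("has component 2", ["motif"], "decimal"),
    ("has inferred allele", ["human leukocyte antigen"], "text"),
    ("has treatment", ["sample"], "text"),
    ("has sample type", ["sample"], "text"),
    ("has instrument model", ["ms instrument"], "text"),
    ("has mutation id", ["mutation"], "text"),
    ("has gene name", ["gene"], "text"),
    ("has gene id", ["gene"], "text"),
    ("has transcript id", ["transcript"], "text"),
    ("has protein id", ["protein"], "text"),
]


def build_core_schema(namespace: str = SCHEMA_NS) -> SchemaModel:
    """Build the normative 38-class core schema.

    Twelve top-level classes (pairwise disjoint), eleven analyte subclasses,
    ``mass_spectrometry`` under ``assay``, ``spectrum`` under
    ``assay_result``, three assignment subclasses and ten cancer subclasses.
    ``part_of`` is transitive with deliberately empty domain/range; every
    object property except ``has_reference_genome`` declares an inverse.
    """
    m = SchemaModel(namespace=namespace, license=DEFAULT_LICENSE)

    def iri(label: str) -> str:
        return class_iri(label_to_local(label), namespace)

    top_labels = [lbl for lbl, _ in _TOP_LEVEL]
    for lbl, definition in _TOP_LEVEL:
        others = frozenset(iri(o) for o in top_labels if o != lbl)
        m.add_class(ClassDef(iri(lbl), lbl, definition, disjoint_with=others))

    for lbl, definition in _ANALYTE_SUBS:
        m.add_class(ClassDef(iri(lbl), lbl, definition,
                             parents=frozenset({iri("analyte")})))

    m.add_class(ClassDef(iri("mass spectrometry"), "mass spectrometry",
                         "an assay eluting and detecting HLA-presented "
                         "peptides", parents=frozenset({iri("assay")})))
    m.add_class(ClassDef(iri("spectrum"), "spectrum",
                         "a mass spectrum output by a mass-spectrometry run",
                         parents=frozenset({iri("assay result")})))
    for lbl, definition in [
        ("spectrum peptide identification",
         "a peptide-spectrum match with a search score"),
        ("peptide protein assignment",
         "a placement of a peptide within a protein"),
        ("peptide genome assignment",
         "a placement of a peptide on the reference genome"),
    ]:
        m.add_class(ClassDef(iri(lbl), lbl, definition,
                             parents=frozenset({iri("assignment")})))
    for lbl in _CANCER_SUBS:
        m.add_class(ClassDef(iri(lbl), lbl, f"{lbl} as a cancer indication",
                             parents=frozenset({iri("cancer")})))

    for lbl, dom, rng, inv, trans, broad, exempt in _OBJECT_PROPS:
        p_iri = iri(lbl)
        inv_iri = iri(inv) if inv else None
        m.add_object_property(ObjectPropertyDef(
            p_iri, lbl,
            domain=frozenset(iri(d) for d in dom),
            range=frozenset(iri(r) for r in rng),
            inverse=inv_iri, transitive=trans,
            broad_scope=broad, inverse_exempt=exempt,
        ))
        if inv_iri:
            m.add_object_property(ObjectPropertyDef(
                inv_iri, inv,
                domain=frozenset(iri(r) for r in rng),
                range=frozenset(iri(d) for d in dom),
                inverse=p_iri, transitive=trans, broad_scope=broad,
            ))

    for lbl, dom, dt in _DATA_PROPS:
        m.add_data_property(DataPropertyDef(
            iri(lbl), lbl,
            domain=frozenset(iri(d) for d in dom), range_datatype=dt,
        ))

    # participation (existential) restrictions on the assignment classes
    for cls, prop, filler in [
        ("spectrum peptide identification", "has source", "spectrum"),
        ("spectrum peptide identification", "has target", "peptide"),
        ("peptide protein assignment", "has source", "peptide"),
        ("peptide protein assignment", "has target", "protein"),
        ("peptide genome assignment", "has source", "peptide"),
    ]:
        m.add_restriction(Restriction(iri(cls), iri(prop), "some", iri(filler)))

    m.validate()
    return m


def register_punned_class(
    schema: SchemaModel, iri: str, label: str, parent: str
) -> ClassDef:
    """Register the class facet of a punned entity (e.g. a concrete gene)."""
    existing = schema.classes.get(iri)
    if existing is not None:
        if not existing.punned:
            schema.classes[iri] = replace(existing, punned=True)
        return schema.classes[iri]
    return schema.add_class(ClassDef(
        iri, label, parents=frozenset({parent}), punned=True))


# ---------------------------------------------------------------------------
# Serialization


def write_ontology(schema: SchemaModel, format: str = "turtle") -> str:
    """Serialize a SchemaModel as RDF (default Turtle).

    Refuses invalid schemas, naming the violated invariant.
    ``load_ontology(write_ontology(m)) == m`` for every valid model.
    """
    schema.validate()
    g = Graph()
    g.bind("impo", schema.namespace)
    g.bind("owl", OWL)
    g.bind("oboInOwl", OBO_IN_OWL)
    g.bind("dcterms", DCTERMS)
    g.bind("impometa", IMPO_META)

    onto = URIRef(schema.namespace.rstrip("#/"))
    g.add((onto, RDF.type, OWL.Ontology))
    if schema.license:
        g.add((onto, DCTERMS.license, Literal(schema.license)))

    for c in schema.classes.values():
        node = URIRef(c.iri)
        g.add((node, RDF.type, OWL.Class))
        g.add((node, RDFS.label, Literal(c.label)))
        if c.punned:
            g.add((node, RDF.type, OWL.NamedIndividual))
        if c.definition:
            g.add((node, RDFS.comment, Literal(c.definition)))
        for p in sorted(c.parents):
            g.add((node, RDFS.subClassOf, URIRef(p)))
        for d in sorted(c.disjoint_with):
            if c.iri < d:  # one direction; loading symmetrizes
                g.add((node, OWL.disjointWith, URIRef(d)))
        for x in sorted(c.cross_references):
            g.add((node, OBO_IN_OWL.hasDbXref, Literal(x)))

    for pair in schema.equivalences:
        a, b = sorted(pair)
        g.add((URIRef(a), OWL.equivalentClass, URIRef(b)))

    for p in schema.object_properties.values():
        node = URIRef(p.iri)
        g.add((node, RDF.type, OWL.ObjectProperty))
        g.add((node, RDFS.label, Literal(p.label)))
        if p.transitive:
            g.add((node, RDF.type, OWL.TransitiveProperty))
        for d in sorted(p.domain):
            g.add((node, RDFS.domain, URIRef(d)))
        for r in sorted(p.range):
            g.add((node, RDFS.range, URIRef(r)))
        if p.inverse and p.iri < p.inverse:
            g.add((node, OWL.inverseOf, URIRef(p.inverse)))
        if p.broad_scope:
            g.add((node, IMPO_META.broadScope, Literal(True)))
        if p.inverse_exempt:
            g.add((node, IMPO_META.inverseExempt, Literal(True)))

    for dp in schema.data_properties.values():
        node = URIRef(dp.iri)
        g.add((node, RDF.type, OWL.DatatypeProperty))
        g.add((node, RDFS.label, Literal(dp.label)))
        for d in sorted(dp.domain):
            g.add((node, RDFS.domain, URIRef(d)))
        g.add((node, RDFS.range, _DT_TO_XSD[dp.range_datatype]))

    for r in schema.restrictions:
        b = BNode()
        g.add((URIRef(r.on_class), RDFS.subClassOf, b))
        g.add((b, RDF.type, OWL.Restriction))
        g.add((b, OWL.onProperty, URIRef(r.property)))
        filler_node = None
        if r.filler is not None:
            filler_node = (
                _DT_TO_XSD[r.filler] if r.filler in DATATYPES
                else URIRef(r.filler)
            )
        if r.kind == "some":
            g.add((b, OWL.someValuesFrom, filler_node))
        elif r.kind == "only":
            g.add((b, OWL.allValuesFrom, filler_node))
        else:
            card = Literal(r.cardinality, datatype=XSD.nonNegativeInteger)
            if filler_node is not None:
                qual = {
                    "exactly": OWL.qualifiedCardinality,
                    "min": OWL.minQualifiedCardinality,
                    "max": OWL.maxQualifiedCardinality,
                }[r.kind]
                g.add((b, qual, card))
                g.add((b, OWL.onClass, filler_node))
            else:
                plain = {
                    "exactly": OWL.cardinality,
                    "min": OWL.minCardinality,
                    "max": OWL.maxCardinality,
                }[r.kind]
                g.add((b, plain, card))

    return g.serialize(format=format)


def load_ontology(document: str, format: str | None = None) -> SchemaModel:
    """Parse an RDF document (Turtle / RDF-XML / N-Triples) into a model.

    Unresolvable references are kept and reported as non-fatal warnings on
    ``model.load_warnings``; entities declared both class and named
    individual come back with ``punned=True``.
    """
    g = Graph()
    formats = [format] if format else ["turtle", "xml", "nt"]
    err: Exception | None = None
    for fmt in formats:
        try:
            g.parse(data=document, format=fmt)
            err = None
            break
        except Exception as exc:  # rdflib raises several parser errors
            err = exc
            g = Graph()
    if err is not None:
        raise SchemaLoadError(f"malformed RDF document: {err}") from err

    # locate a namespace: prefer the ontology IRI, else the schema default
    ns = SCHEMA_NS
    onto = next(g.subjects(RDF.type, OWL.Ontology), None)
    if onto is not None:
        base = str(onto)
        ns = base if base.endswith(("#", "/")) else base + "#"
    m = SchemaModel(namespace=ns)
    lic = next(g.objects(onto, DCTERMS.license), None) if onto is not None \
        else None
    m.license = str(lic) if lic is not None else None

    def first_literal(node, pred):
        for o in g.objects(node, pred):
            if isinstance(o, Literal):
                return str(o)
        return None

    class_nodes = [s for s in g.subjects(RDF.type, OWL.Class)
                   if isinstance(s, URIRef)]
    individuals = set(g.subjects(RDF.type, OWL.NamedIndividual))

    restriction_bnodes: dict[BNode, None] = {}

    for node in sorted(class_nodes):
        iri = str(node)
        label = first_literal(node, RDFS.label) or local_name(iri)
        parents: set[str] = set()
        for sup in g.objects(node, RDFS.subClassOf):
            if isinstance(sup, URIRef):
                parents.add(str(sup))
            elif isinstance(sup, BNode) and (sup, RDF.type, OWL.Restriction) in g:
                restriction_bnodes[sup] = None
        disjoint = {str(o) for o in g.objects(node, OWL.disjointWith)
                    if isinstance(o, URIRef)}
        disjoint |= {str(s) for s in g.subjects(OWL.disjointWith, node)
                     if isinstance(s, URIRef)}
        xrefs = {str(o) for o in g.objects(node, OBO_IN_OWL.hasDbXref)}
        m.add_class(ClassDef(
            iri, label,
            definition=first_literal(node, RDFS.comment) or "",
            parents=frozenset(parents),
            disjoint_with=frozenset(disjoint),
            punned=node in individuals,
            cross_references=frozenset(xrefs),
        ))

    for s, _, o in g.triples((None, OWL.equivalentClass, None)):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            m.equivalences.add(frozenset({str(s), str(o)}))

    transitive = set(g.subjects(RDF.type, OWL.TransitiveProperty))
    inverse_of: dict[str, str] = {}
    for s, _, o in g.triples((None, OWL.inverseOf, None)):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            inverse_of[str(s)] = str(o)
            inverse_of[str(o)] = str(s)

    def flag(node, pred) -> bool:
        v = next(g.objects(node, pred), None)
        return isinstance(v, Literal) and bool(v.toPython())

    for node in sorted(g.subjects(RDF.type, OWL.ObjectProperty)):
        if not isinstance(node, URIRef):
            continue
        iri = str(node)
        m.add_object_property(ObjectPropertyDef(
            iri, first_literal(node, RDFS.label) or local_name(iri),
            domain=frozenset(str(d) for d in g.objects(node, RDFS.domain)
                             if isinstance(d, URIRef)),
            range=frozenset(str(r) for r in g.objects(node, RDFS.range)
                            if isinstance(r, URIRef)),
            inverse=inverse_of.get(iri),
            transitive=node in transitive,
            broad_scope=flag(node, IMPO_META.broadScope),
            inverse_exempt=flag(node, IMPO_META.inverseExempt),
        ))

    for node in sorted(g.subjects(RDF.type, OWL.DatatypeProperty)):
        if not isinstance(node, URIRef):
            continue
        iri = str(node)
        rng = next((str(r) for r in g.objects(node, RDFS.range)), None)
        dt = _XSD_TO_DT.get(rng or "", "text")
        if rng is not None and rng not in _XSD_TO_DT:
            m.load_warnings.append(
                f"datatype {rng} of {iri} mapped to 'text'")
        m.add_data_property(DataPropertyDef(
            iri, first_literal(node, RDFS.label) or local_name(iri),
            domain=frozenset(str(d) for d in g.objects(node, RDFS.domain)
                             if isinstance(d, URIRef)),
            range_datatype=dt,
        ))

    for b in restriction_bnodes:
        prop = next((str(p) for p in g.objects(b, OWL.onProperty)), None)
        for on_cls in g.subjects(RDFS.subClassOf, b):
            if not isinstance(on_cls, URIRef) or prop is None:
                continue
            r = _read_restriction(g, b, str(on_cls), prop)
            if r is not None:
                m.add_restriction(r)

    # dangling-identifier warnings (non-fatal)
    known = set(m.classes)
    for c in m.classes.values():
        for ref in itertools.chain(c.parents, c.disjoint_with):
            if ref not in known:
                m.load_warnings.append(
                    f"dangling identifier {ref} referenced by {c.iri}")
    for p in m.object_properties.values():
        for ref in itertools.chain(p.domain, p.range):
            if ref not in known:
                m.load_warnings.append(
                    f"dangling identifier {ref} referenced by {p.iri}")
    return m


def _read_restriction(
    g: Graph, b: BNode, on_class: str, prop: str
) -> Restriction | None:
    def filler_of(node) -> str | None:
        if node is None:
            return None
        return _XSD_TO_DT.get(str(node), str(node))

    some = next(g.objects(b, OWL.someValuesFrom), None)
    if some is not None:
        return Restriction(on_class, prop, "some", filler_of(some))
    only = next(g.objects(b, OWL.allValuesFrom), None)
    if only is not None:
        return Restriction(on_class, prop, "only", filler_of(only))
    for kind, plain, qual in [
        ("exactly", OWL.cardinality, OWL.qualifiedCardinality),
        ("min", OWL.minCardinality, OWL.minQualifiedCardinality),
        ("max", OWL.maxCardinality, OWL.maxQualifiedCardinality),
    ]:
        card = next(g.objects(b, plain), None)
        if card is not None:
            return Restriction(on_class, prop, kind, None, int(card))
        card = next(g.objects(b, qual), None)
        if card is not None:
            on_cls = next(g.objects(b, OWL.onClass), None)
            return Restriction(on_class, prop, kind, filler_of(on_cls),
                               int(card))
    return None


# ---------------------------------------------------------------------------
# Checks


def schema_statistics(schema: SchemaModel) -> EntityCounts:
    """Descriptive entity counts of the terminological layer."""
    return EntityCounts(
        classes=len(schema.classes),
        object_properties=len(schema.object_properties),
        data_properties=len(schema.data_properties),
        punned_entities=sum(1 for c in schema.classes.values() if c.punned),
        cross_references=sum(
            len(c.cross_references) for c in schema.classes.values()),
    )


def check_dl_profile(schema: SchemaModel) -> list[ProfileViolation]:
    """OWL 2 DL rule: no cardinality restriction on a transitive property.

    Returns one violation per (transitive property, cardinality restriction)
    pair; sound and complete for this single rule by exhaustive scan.
    """
    violations = []
    for r in schema.restrictions:
        if r.kind not in _CARDINALITY_KINDS:
            continue
        p = schema.object_properties.get(r.property)
        if p is not None and p.transitive:
            violations.append(ProfileViolation(
                p.iri, r,
                f"cardinality restriction ({r.kind} {r.cardinality}) on "
                f"transitive object property {p.label!r} breaks OWL 2 DL",
            ))
    return violations


def check_structural_pitfalls(schema: SchemaModel) -> PitfallReport:
    """Scan for five structural design pitfalls.

    P02 equivalent named classes (synonyms as classes); P10 no disjointness
    declared anywhere; P11 properties lacking domain or range (broad-scope
    flagged properties exempt); P13 object properties lacking an inverse
    (declared exceptions exempt); P41 no license.
    """
    report = PitfallReport()
    for pair in sorted(schema.equivalences, key=sorted):
        a, b = sorted(pair)
        report.add(PitfallFinding(
            "P02", PITFALL_SEVERITY["P02"],
            f"named classes declared equivalent: {local_name(a)} == "
            f"{local_name(b)} (synonyms as classes)", (a, b)))

    if schema.classes and not any(
            c.disjoint_with for c in schema.classes.values()):
        report.add(PitfallFinding(
            "P10", PITFALL_SEVERITY["P10"],
            "no classes are declared disjoint anywhere in the schema"))

    for p in sorted(schema.object_properties.values(), key=lambda x: x.iri):
        if p.broad_scope:
            continue
        missing = [w for w, s in (("domain", p.domain), ("range", p.range))
                   if not s]
        if missing:
            report.add(PitfallFinding(
                "P11", PITFALL_SEVERITY["P11"],
                f"object property {p.label!r} lacks {' and '.join(missing)}",
                (p.iri,)))
    for dp in sorted(schema.data_properties.values(), key=lambda x: x.iri):
        if not dp.domain:
            report.add(PitfallFinding(
                "P11", PITFALL_SEVERITY["P11"],
                f"data property {dp.label!r} lacks domain", (dp.iri,)))

    for p in sorted(schema.object_properties.values(), key=lambda x: x.iri):
        if p.inverse is None and not p.inverse_exempt:
            report.add(PitfallFinding(
                "P13", PITFALL_SEVERITY["P13"],
                f"object property {p.label!r} has no declared inverse",
                (p.iri,)))

    if not schema.license:
        report.add(PitfallFinding(
            "P41", PITFALL_SEVERITY["P41"], "no license declared"))
    return report
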