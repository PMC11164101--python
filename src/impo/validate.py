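"""Closed-world constraint validation of an instance graph.

The validator re-creates, as data QC, the error classes a DL reasoner
surfaces during ontology population — assertions incompatible with
property domains or ranges, literals of the wrong datatype, individuals
typed by disjoint classes — plus explicit cardinality counting and
dangling-reference detection.  Checking is deliberately *closed-world*:
an individual missing a ``min 1`` filler is reported, which is the
opposite of open-world OWL entailment, because the artifact's job is to
localize problems to source rows, not to infer unstated facts.  Empty
domains/ranges mean "unconstrained" (the broad-scope ``part_of`` case),
and punned IRIs never trip disjointness between their two facets.

``inject_violations`` plants a controlled, seeded set of corruptions into
a clean graph and returns a manifest, so validator completeness can be
measured as recall of the manifest.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .naming import instance_iri
from .schema import SchemaModel
from .store import Assertion, Individual, InstanceGraph

VIOLATION_KINDS = (
    "domain", "range", "datatype", "cardinality_min", "cardinality_max",
    "cardinality_exact", "disjointness", "dangling",
)

_KIND_TO_RESTRICTION = {
    "cardinality_min": "min",
    "cardinality_max": "max",
    "cardinality_exact": "exactly",
}


class InjectionError(ValueError):
    """The requested corruption plan is infeasible on this graph."""


@dataclass(frozen=True)
class Violation:
    kind: str
    subject: str
    predicate: str | None = None
    detail: str = ""
    severity: str = "error"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in VIOLATION_KINDS}
        for v in self.violations:
            out[v.kind] = out.get(v.kind, 0) + 1
        return out

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def clean(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "clean": self.clean,
            "counts": {k: n for k, n in self.counts.items() if n},
            "violations": [
                {"kind": v.kind, "subject": v.subject,
                 "predicate": v.predicate, "detail": v.detail,
                 "severity": v.severity}
                for v in self.violations
            ],
        }


@dataclass(frozen=True)
class InjectionEntry:
    kind: str
    subject: str
    predicate: str | None
    mutation: str


@dataclass
class InjectionManifest:
    seed: int
    entries: list[InjectionEntry] = field(default_factory=list)


def _types_satisfy(graph: InstanceGraph, schema: SchemaModel, iri: str,
                   allowed: frozenset[str]) -> bool:
    """True when some type of the individual is (a subclass of) an allowed
    class.  An empty ``allowed`` set means unconstrained."""
    if not allowed:
        return True
    ind = graph.individuals.get(iri)
    if ind is None:
        return False
    return any(allowed & schema.ancestors(t) for t in ind.types)


def validate_instances(graph: InstanceGraph,
                       schema: SchemaModel) -> ValidationReport:
    """Check every assertion and individual against the schema constraints.

    Domain/range use the subclass closure; datatypes must match the data
    property's declared range; ``exactly``/``min``/``max`` restrictions are
    counted per individual typed by the restricted class or a subclass;
    no individual may be typed by two disjoint classes (inherited
    disjointness included); dangling references are reported.  Problems
    are report content, never exceptions.
    """
    report = ValidationReport()

    for a in sorted(graph.assertions,
                    key=lambda x: (x.subject, x.predicate,
                                   str(x.object), str(x.value))):
        if a.subject not in graph.individuals:
            report.violations.append(Violation(
                "dangling", a.subject, a.predicate,
                "assertion subject is not an individual"))
            continue
        if a.is_object:
            pdef = schema.object_properties.get(a.predicate)
            if pdef is None:
                report.violations.append(Violation(
                    "dangling", a.subject, a.predicate,
                    "unknown object property"))
                continue
            if not _types_satisfy(graph, schema, a.subject, pdef.domain):
                report.violations.append(Violation(
                    "domain", a.subject, a.predicate,
                    f"subject types incompatible with domain of "
                    f"{pdef.label!r}"))
            if a.object not in graph.individuals:
                report.violations.append(Violation(
                    "dangling", a.subject, a.predicate,
                    f"object {a.object} is not an individual"))
            elif not _types_satisfy(graph, schema, a.object, pdef.range):
                report.violations.append(Violation(
                    "range", a.subject, a.predicate,
                    f"object types incompatible with range of "
                    f"{pdef.label!r}"))
        else:
            pdef = schema.data_properties.get(a.predicate)
            if pdef is None:
                report.violations.append(Violation(
                    "dangling", a.subject, a.predicate,
                    "unknown data property"))
                continue
            if not _types_satisfy(graph, schema, a.subject, pdef.domain):
                report.violations.append(Violation(
                    "domain", a.subject, a.predicate,
                    f"subject types incompatible with domain of "
                    f"{pdef.label!r}"))
            if a.datatype != pdef.range_datatype:
                report.violations.append(Violation(
                    "datatype", a.subject, a.predicate,
                    f"literal datatype {a.datatype!r} != declared "
                    f"{pdef.range_datatype!r}"))

    # cardinality restrictions, counted closed-world
    for r in schema.restrictions:
        if r.kind not in ("exactly", "min", "max"):
            continue
        restricted = schema.descendants(r.on_class)
        filler_classes = (schema.descendants(r.filler)
                          if r.filler in schema.classes else None)
        for iri in sorted(graph.individuals):
            ind = graph.individuals[iri]
            if not (ind.types & restricted):
                continue
            if r.property in schema.object_properties:
                objs = graph.objects(iri, r.property)
                if filler_classes is not None:
                    objs = {o for o in objs
                            if (graph.individuals.get(o)
                                and graph.individuals[o].types
                                & filler_classes)}
                n = len(objs)
            else:
                n = len(graph.values(iri, r.property))
            kind = {"exactly": "cardinality_exact", "min": "cardinality_min",
                    "max": "cardinality_max"}[r.kind]
            bad = ((r.kind == "exactly" and n != r.cardinality)
                   or (r.kind == "min" and n < r.cardinality)
                   or (r.kind == "max" and n > r.cardinality))
            if bad:
                report.violations.append(Violation(
                    kind, iri, r.property,
                    f"{n} filler(s), restriction requires {r.kind} "
                    f"{r.cardinality}"))

    # disjointness (inherited; punned facets are distinct nodes by design)
    disjoint = schema.disjoint_closure()
    for iri in sorted(graph.individuals):
        types = sorted(graph.individuals[iri].types)
        for i, t1 in enumerate(types):
            for t2 in types[i + 1:]:
                if frozenset((t1, t2)) in disjoint:
                    report.violations.append(Violation(
                        "disjointness", iri, None,
                        f"typed by disjoint classes {t1} and {t2}"))
    return report


# ---------------------------------------------------------------------------
# Controlled corruption


def _clone(graph: InstanceGraph) -> InstanceGraph:
    g = InstanceGraph(schema=graph.schema,
                      instance_namespace=graph.instance_namespace)
    for ind in graph.individuals.values():
        g.add_individual(Individual(ind.iri, set(ind.types), ind.label))
    for a in graph.assertions:
        g._index(a)
    return g


def inject_violations(graph: InstanceGraph, schema: SchemaModel,
                      plan: dict[str, int], seed: int = 0
                      ) -> tuple[InstanceGraph, InjectionManifest]:
    """Return a corrupted copy of a clean graph plus its manifest.

    Each planned corruption produces exactly one violation of the planned
    kind; choices are deterministic under the seed.  Raises
    :class:`InjectionError` when not enough candidates exist.
    """
    base = validate_instances(graph, schema)
    if not base.clean:
        raise InjectionError("graph must be clean before injection")
    for kind in plan:
        if kind not in VIOLATION_KINDS:
            raise InjectionError(f"unknown violation kind {kind!r}")

    g = _clone(graph)
    rng = random.Random(seed)
    manifest = InjectionManifest(seed=seed)
    ghost_counter = 0

    def data_assertions():
        return sorted((a for a in g.assertions if not a.is_object),
                      key=lambda a: (a.subject, a.predicate, str(a.value)))

    def object_assertions():
        return sorted((a for a in g.assertions if a.is_object),
                      key=lambda a: (a.subject, a.predicate, a.object))

    for kind in sorted(plan):
        for _ in range(plan[kind]):
            if kind == "domain":
                entry = _inject_domain(g, schema, rng)
            elif kind == "range":
                entry = _inject_range(g, schema, rng, object_assertions())
            elif kind == "datatype":
                entry = _inject_datatype(g, schema, rng, data_assertions())
            elif kind == "disjointness":
                entry = _inject_disjointness(g, schema, rng)
            elif kind == "dangling":
                ghost_counter += 1
                entry = _inject_dangling(g, schema, rng, ghost_counter)
            else:
                entry = _inject_cardinality(g, schema, rng,
                                            _KIND_TO_RESTRICTION[kind], kind)
            manifest.entries.append(entry)
    return g, manifest


def _inject_domain(g: InstanceGraph, schema: SchemaModel,
                   rng: random.Random) -> InjectionEntry:
    candidates = sorted(
        (a for a in g.assertions
         if not a.is_object
         and schema.data_properties.get(a.predicate) is not None
         and schema.data_properties[a.predicate].domain),
        key=lambda a: (a.subject, a.predicate, str(a.value)))
    rng.shuffle(candidates)
    for a in candidates:
        dom = schema.data_properties[a.predicate].domain
        hosts = sorted(
            iri for iri in g.individuals
            if not _types_satisfy(g, schema, iri, dom))
        rng.shuffle(hosts)
        for host in hosts:
            bad = Assertion(host, a.predicate, value=a.value,
                            datatype=a.datatype)
            if bad not in g.assertions:
                g._index(bad)
                return InjectionEntry(
                    "domain", host, a.predicate,
                    f"moved literal {a.value!r} onto out-of-domain subject")
    raise InjectionError("no candidate assertion for a domain violation")


def _inject_range(g: InstanceGraph, schema: SchemaModel, rng: random.Random,
                  candidates: list[Assertion]) -> InjectionEntry:
    candidates = [a for a in candidates
                  if schema.object_properties.get(a.predicate) is not None
                  and schema.object_properties[a.predicate].range]
    rng.shuffle(candidates)
    for a in candidates:
        pdef = schema.object_properties[a.predicate]
        bad_objects = sorted(
            iri for iri in g.individuals
            if not _types_satisfy(g, schema, iri, pdef.range)
            # keep the subject side clean: the bad object must not create
            # a second violation through an unexpected domain mismatch
            and iri != a.subject)
        rng.shuffle(bad_objects)
        for obj in bad_objects:
            bad = Assertion(a.subject, a.predicate, object=obj)
            if bad not in g.assertions:
                g._index(bad)
                return InjectionEntry(
                    "range", a.subject, a.predicate,
                    f"re-targeted {a.predicate} to out-of-range {obj}")
    raise InjectionError("no candidate assertion for a range violation")


def _inject_datatype(g: InstanceGraph, schema: SchemaModel,
                     rng: random.Random,
                     candidates: list[Assertion]) -> InjectionEntry:
    candidates = [a for a in candidates
                  if schema.data_properties.get(a.predicate) is not None]
    rng.shuffle(candidates)
    for a in candidates:
        declared = schema.data_properties[a.predicate].range_datatype
        wrong = "text" if declared != "text" else "integer"
        value = str(a.value) if wrong == "text" else 0
        bad = Assertion(a.subject, a.predicate, value=value, datatype=wrong)
        if bad not in g.assertions:
            g.discard(a)
            g._index(bad)
            return InjectionEntry(
                "datatype", a.subject, a.predicate,
                f"literal datatype flipped {a.datatype!r} -> {wrong!r}")
    raise InjectionError("no candidate assertion for a datatype violation")


def _inject_disjointness(g: InstanceGraph, schema: SchemaModel,
                         rng: random.Random) -> InjectionEntry:
    disjoint = schema.disjoint_closure()
    individuals = sorted(g.individuals)
    rng.shuffle(individuals)
    for iri in individuals:
        ind = g.individuals[iri]
        for t in sorted(ind.types):
            foes = sorted(
                c for c in schema.classes
                if c not in ind.types and frozenset((t, c)) in disjoint)
            if foes:
                foe = rng.choice(foes)
                ind.types.add(foe)
                g._by_type[foe].add(iri)
                return InjectionEntry(
                    "disjointness", iri, None,
                    f"added type {foe} disjoint with {t}")
    raise InjectionError("no candidate individual for a disjointness "
                         "violation")


def _inject_dangling(g: InstanceGraph, schema: SchemaModel,
                     rng: random.Random, n: int) -> InjectionEntry:
    # use a broad-scope property so the only violation is the dangling ref
    broad = sorted(p.iri for p in schema.object_properties.values()
                   if not p.domain and not p.range)
    if not broad or not g.individuals:
        raise InjectionError("no broad-scope property or no individuals "
                             "for a dangling violation")
    prop = broad[0]
    subject = rng.choice(sorted(g.individuals))
    ghost = instance_iri(f"ghost_{n}", g.instance_namespace)
    g._index(Assertion(subject, prop, object=ghost))
    return InjectionEntry("dangling", subject, prop,
                          f"object reference to nonexistent {ghost}")


def _inject_cardinality(g: InstanceGraph, schema: SchemaModel,
                        rng: random.Random, restriction_kind: str,
                        violation_kind: str) -> InjectionEntry:
    restrictions = [r for r in schema.restrictions
                    if r.kind == restriction_kind]
    rng.shuffle(restrictions)
    for r in restrictions:
        if restriction_kind in ("min", "exactly") and r.cardinality >= 1:
            # a fresh individual of the restricted class with no fillers
            local = f"cardinality_probe_{len(g.individuals)}"
            ind = g.mint_individual(r.on_class, local)
            return InjectionEntry(
                violation_kind, ind.iri, r.property,
                f"minted {r.on_class} individual with 0 fillers "
                f"({restriction_kind} {r.cardinality})")
        if restriction_kind == "max":
            hosts = sorted(iri for iri in g.individuals
                           if g.individuals[iri].types
                           & schema.descendants(r.on_class))
            rng.shuffle(hosts)
            for host in hosts:
                needed = r.cardinality + 1 - len(g.objects(host, r.property))
                if needed <= 0:
                    continue
                # extra fillers must still satisfy the property's range so
                # that the only new violation is the cardinality overflow
                pdef = schema.object_properties.get(r.property)
                if r.filler in schema.classes:
                    filler_cls = r.filler
                elif pdef is not None and pdef.range:
                    filler_cls = sorted(pdef.range)[0]
                else:
                    filler_cls = r.on_class
                for i in range(needed):
                    extra = g.mint_individual(
                        filler_cls, f"cardinality_extra_{host[-8:]}_{i}")
                    g._index(Assertion(host, r.property, object=extra.iri))
                return InjectionEntry(
                    violation_kind, host, r.property,
                    f"added {needed} extra filler(s) over max "
                    f"{r.cardinality}")
    raise InjectionError(
        f"no {restriction_kind} restriction available for a "
        f"{violation_kind} violation")
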