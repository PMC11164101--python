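"""Closed-world validator: soundness on clean graphs, completeness on
injected corruptions, agreement with a naive re-implementation."""

import pytest

from impo.naming import class_iri
from impo.schema import Restriction, build_core_schema
from impo.store import Assertion, InstanceGraph
from impo.validate import (
    InjectionError, inject_violations, validate_instances,
)


def naive_validate(graph, schema):
    """Independent all-pairs re-implementation; returns (kind, subject,
    predicate) triples."""
    found = set()

    def ok(iri, allowed):
        if not allowed:
            return True
        ind = graph.individuals.get(iri)
        return ind is not None and any(
            allowed & schema.ancestors(t) for t in ind.types)

    for a in graph.assertions:
        if a.subject not in graph.individuals:
            found.add(("dangling", a.subject, a.predicate))
            continue
        if a.is_object:
            p = schema.object_properties.get(a.predicate)
            if p is None:
                found.add(("dangling", a.subject, a.predicate))
                continue
            if not ok(a.subject, p.domain):
                found.add(("domain", a.subject, a.predicate))
            if a.object not in graph.individuals:
                found.add(("dangling", a.subject, a.predicate))
            elif not ok(a.object, p.range):
                found.add(("range", a.subject, a.predicate))
        else:
            p = schema.data_properties.get(a.predicate)
            if p is None:
                found.add(("dangling", a.subject, a.predicate))
                continue
            if not ok(a.subject, p.domain):
                found.add(("domain", a.subject, a.predicate))
            if a.datatype != p.range_datatype:
                found.add(("datatype", a.subject, a.predicate))
    for r in schema.restrictions:
        if r.kind not in ("exactly", "min", "max"):
            continue
        kind = {"exactly": "cardinality_exact", "min": "cardinality_min",
                "max": "cardinality_max"}[r.kind]
        for iri, ind in graph.individuals.items():
            if not any(r.on_class in schema.ancestors(t)
                       for t in ind.types):
                continue
            if r.property in schema.object_properties:
                objs = [a.object for a in graph.assertions
                        if a.is_object and a.subject == iri
                        and a.predicate == r.property]
                if r.filler in schema.classes:
                    objs = [o for o in objs
                            if graph.individuals.get(o) is not None
                            and any(r.filler in schema.ancestors(t)
                                    for t in graph.individuals[o].types)]
                n = len(set(objs))
            else:
                n = len({a.value for a in graph.assertions
                         if not a.is_object and a.subject == iri
                         and a.predicate == r.property})
            if ((r.kind == "exactly" and n != r.cardinality)
                    or (r.kind == "min" and n < r.cardinality)
                    or (r.kind == "max" and n > r.cardinality)):
                found.add((kind, iri, r.property))
    pairs = schema.disjoint_closure()
    for iri, ind in graph.individuals.items():
        ts = sorted(ind.types)
        for i, t1 in enumerate(ts):
            for t2 in ts[i + 1:]:
                if frozenset((t1, t2)) in pairs:
                    found.add(("disjointness", iri, None))
    return found


def small_graph():
    schema = build_core_schema()
    g = InstanceGraph(schema=schema)
    sample = g.mint_individual(class_iri("sample"), "sample_S01")
    pep = g.mint_individual(class_iri("peptide"), "peptide_SIINFEKL")
    psm = g.mint_individual(
        class_iri("spectrum_peptide_identification"), "psm_1")
    sp = g.mint_individual(class_iri("spectrum"), "spectrum_1")
    g.add_assertion(Assertion(psm.iri, schema.prop("has_source"),
                              object=sp.iri))
    g.add_assertion(Assertion(psm.iri, schema.prop("has_target"),
                              object=pep.iri))
    g.add_assertion(Assertion(psm.iri, schema.prop("has_score"),
                              value=87.5, datatype="decimal"))
    g.add_assertion(Assertion(pep.iri, schema.prop("has_sequence"),
                              value="SIINFEKL", datatype="text"))
    return schema, g, sample, pep, psm


class TestValidator:
    def test_clean_synthetic_graph_has_zero_errors(self, default_graph):
        report = validate_instances(default_graph, default_graph.schema)
        assert report.clean and not report.errors

    def test_score_on_a_peptide_is_a_domain_violation(self):
        schema, g, _sample, pep, _psm = small_graph()
        g._index(Assertion(pep.iri, schema.prop("has_score"),
                           value=12.3, datatype="decimal"))
        report = validate_instances(g, schema)
        assert [v.kind for v in report.errors] == ["domain"]
        assert report.errors[0].subject == pep.iri

    def test_disjoint_sibling_types_are_flagged(self):
        schema, g, sample, _pep, _psm = small_graph()
        g.individuals[sample.iri].types.add(class_iri("study"))
        report = validate_instances(g, schema)
        assert [v.kind for v in report.errors] == ["disjointness"]

    def test_wrong_literal_datatype_is_flagged(self):
        schema, g, _sample, _pep, psm = small_graph()
        g._index(Assertion(psm.iri, schema.prop("has_score"),
                           value="eighty", datatype="text"))
        report = validate_instances(g, schema)
        assert [v.kind for v in report.errors] == ["datatype"]

    def test_missing_min_filler_is_reported_closed_world(self):
        # the deliberate deviation from open-world OWL: an individual
        # missing a required filler is itself the violation
        schema, g, _sample, _pep, _psm = small_graph()
        schema.add_restriction(Restriction(
            class_iri("mass_spectrometry"), schema.prop("performed_on"),
            "min", None, 1))
        g.mint_individual(class_iri("mass_spectrometry"), "ms_lonely")
        report = validate_instances(g, schema)
        assert [v.kind for v in report.errors] == ["cardinality_min"]

    def test_exact_and_max_cardinality_are_counted(self):
        schema, g, sample, _pep, _psm = small_graph()
        schema.add_restriction(Restriction(
            class_iri("sample"), schema.prop("has_cancer"),
            "max", class_iri("cancer"), 1))
        c1 = g.mint_individual(class_iri("melanoma"), "cancer_a")
        c2 = g.mint_individual(class_iri("leukemia"), "cancer_b")
        g.add_assertion(Assertion(sample.iri, schema.prop("has_cancer"),
                                  object=c1.iri))
        assert validate_instances(g, schema).clean
        g.add_assertion(Assertion(sample.iri, schema.prop("has_cancer"),
                                  object=c2.iri))
        report = validate_instances(g, schema)
        assert [v.kind for v in report.errors] == ["cardinality_max"]

    def test_dangling_object_is_reported_not_raised(self):
        schema, g, sample, _pep, _psm = small_graph()
        g._index(Assertion(sample.iri, schema.prop("part_of"),
                           object="https://w3id.org/impo/instance/ghost"))
        report = validate_instances(g, schema)
        assert [v.kind for v in report.errors] == ["dangling"]

    def test_report_serializes_with_per_kind_counts(self):
        schema, g, _sample, pep, _psm = small_graph()
        g._index(Assertion(pep.iri, schema.prop("has_score"),
                           value=1.0, datatype="decimal"))
        d = validate_instances(g, schema).to_dict()
        assert d["clean"] is False and d["counts"] == {"domain": 1}


MIXED_PLAN = {"domain": 4, "range": 3, "datatype": 3, "disjointness": 2,
              "dangling": 2}


class TestInjection:
    def test_empty_plan_changes_nothing(self, default_graph):
        g2, manifest = inject_violations(default_graph,
                                         default_graph.schema, {}, seed=1)
        assert g2 == default_graph and manifest.entries == []

    def test_manifest_is_deterministic_under_seed(self, default_graph):
        _, m1 = inject_violations(default_graph, default_graph.schema,
                                  {"datatype": 3}, seed=5)
        _, m2 = inject_violations(default_graph, default_graph.schema,
                                  {"datatype": 3}, seed=5)
        assert m1.entries == m2.entries

    def test_mixed_plan_recovered_with_perfect_precision_recall(
            self, default_graph):
        g2, manifest = inject_violations(default_graph,
                                         default_graph.schema, MIXED_PLAN,
                                         seed=11)
        report = validate_instances(g2, default_graph.schema)
        planted = {(e.kind, e.subject) for e in manifest.entries}
        reported = {(v.kind, v.subject) for v in report.errors}
        assert planted == reported
        assert len(manifest.entries) == sum(MIXED_PLAN.values())
        assert len(report.errors) == sum(MIXED_PLAN.values())

    def test_injection_requires_a_clean_graph(self, default_graph):
        g2, _ = inject_violations(default_graph, default_graph.schema,
                                  {"domain": 1}, seed=1)
        with pytest.raises(InjectionError, match="clean"):
            inject_violations(g2, default_graph.schema, {"domain": 1},
                              seed=1)

    def test_infeasible_plan_raises(self):
        schema, g, *_ = small_graph()
        with pytest.raises(InjectionError):
            inject_violations(g, schema, {"cardinality_max": 1}, seed=1)

    def test_cardinality_injections_on_a_restricted_schema(self):
        schema, g, sample, _pep, _psm = small_graph()
        schema.add_restriction(Restriction(
            class_iri("mass_spectrometry"), schema.prop("performed_on"),
            "min", None, 1))
        schema.add_restriction(Restriction(
            class_iri("sample"), schema.prop("has_cancer"), "max", None, 0))
        g2, manifest = inject_violations(
            g, schema, {"cardinality_min": 1, "cardinality_max": 1}, seed=3)
        report = validate_instances(g2, schema)
        assert {(e.kind, e.subject) for e in manifest.entries} \
            == {(v.kind, v.subject) for v in report.errors}


class TestBruteForceAgreement:
    def test_agrees_on_clean_small_graph(self):
        schema, g, *_ = small_graph()
        report = validate_instances(g, schema)
        assert {(v.kind, v.subject, v.predicate)
                for v in report.errors} == naive_validate(g, schema)
        assert report.clean

    def test_agrees_on_an_injected_graph(self, default_graph):
        schema = default_graph.schema
        g2, _ = inject_violations(default_graph, schema, MIXED_PLAN,
                                  seed=23)
        got = {(v.kind, v.subject, v.predicate)
               for v in validate_instances(g2, schema).errors}
        assert got == naive_validate(g2, schema)
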