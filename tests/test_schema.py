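"""Terminological layer: core schema, round trips, profile and pitfalls."""

import pytest

from impo.naming import class_iri, label_to_local, local_name
from impo.schema import (
    ClassDef, Restriction, SchemaModel, build_core_schema, check_dl_profile,
    check_structural_pitfalls, load_ontology, schema_statistics,
    write_ontology, SchemaError, SchemaLoadError,
)
from impo.schema import register_punned_class


class TestCoreSchema:
    def test_has_exactly_38_classes(self, core_schema):
        assert len(core_schema.classes) == 38

    def test_peptide_is_an_analyte(self, core_schema):
        pep = core_schema.cls("peptide")
        assert pep.parents == {class_iri("analyte")}

    def test_has_output_links_assay_to_result(self, core_schema):
        p = core_schema.object_properties[core_schema.prop("has_output")]
        assert p.domain == {class_iri("assay")}
        assert p.range == {class_iri("assay_result")}

    def test_part_of_is_transitive_and_unrestricted(self, core_schema):
        p = core_schema.object_properties[core_schema.prop("part_of")]
        assert p.transitive and not p.domain and not p.range

    def test_cancer_subclasses_cover_the_indications(self, core_schema):
        for label in ("melanoma", "colon cancer", "neuroblastoma"):
            c = core_schema.by_label(label)
            assert class_iri("cancer") in c.parents

    def test_top_level_classes_pairwise_disjoint(self, core_schema):
        sample = core_schema.cls("sample")
        assert class_iri("study") in sample.disjoint_with
        assert class_iri("analyte") in sample.disjoint_with

    def test_license_is_declared(self, core_schema):
        assert core_schema.license

    def test_naming_convention_label_to_local(self, core_schema):
        for c in core_schema.classes.values():
            assert label_to_local(c.label) == local_name(c.iri)

    def test_inverses_are_mutual(self, core_schema):
        for p in core_schema.object_properties.values():
            if p.inverse is not None:
                assert core_schema.object_properties[p.inverse].inverse \
                    == p.iri

    def test_has_reference_genome_has_no_inverse(self, core_schema):
        p = core_schema.object_properties[
            core_schema.prop("has_reference_genome")]
        assert p.inverse is None and p.inverse_exempt


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["turtle", "xml", "nt"])
    def test_round_trip_is_identity(self, fmt):
        m = build_core_schema()
        doc = write_ontology(m, format=fmt)
        assert load_ontology(doc) == m

    def test_statistics_invariant_under_round_trip(self, core_schema):
        reloaded = load_ontology(write_ontology(core_schema))
        assert schema_statistics(reloaded) == schema_statistics(core_schema)

    def test_minimal_document_yields_one_class(self):
        doc = """
        @prefix owl: <http://www.w3.org/2002/07/owl#> .
        @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
        <https://w3id.org/impo#thing> a owl:Class ; rdfs:label "thing" .
        """
        m = load_ontology(doc)
        assert len(m.classes) == 1
        assert not m.object_properties and not m.data_properties

    def test_empty_schema_serializes_to_header_only(self):
        m = SchemaModel(license="https://example.org/license")
        doc = write_ontology(m)
        m2 = load_ontology(doc)
        assert not m2.classes and m2.license == m.license

    def test_malformed_document_raises(self):
        with pytest.raises(SchemaLoadError):
            load_ontology("this is not rdf @@@")

    def test_write_refuses_invariant_violation(self):
        m = build_core_schema()
        m.classes[class_iri("ghost")] = ClassDef(
            class_iri("ghost"), "ghost",
            parents=frozenset({class_iri("nowhere")}))
        with pytest.raises(SchemaError, match="unresolved parent"):
            write_ontology(m)

    def test_subclass_cycle_detected(self):
        m = SchemaModel()
        m.add_class(ClassDef(class_iri("a"), "a",
                             parents=frozenset({class_iri("b")})))
        m.add_class(ClassDef(class_iri("b"), "b",
                             parents=frozenset({class_iri("a")})))
        assert any("cycle" in p for p in m.check_invariants())

    def test_punned_entity_round_trips_with_both_facets(self):
        m = build_core_schema()
        register_punned_class(m, class_iri("MET_gene"), "MET_gene",
                              class_iri("gene"))
        doc = write_ontology(m)
        assert "NamedIndividual" in doc
        m2 = load_ontology(doc)
        facet = m2.classes[class_iri("MET_gene")]
        assert facet.punned and class_iri("gene") in facet.parents
        assert schema_statistics(m2).punned_entities == 1

    def test_punning_does_not_create_subclass_cycles(self):
        m = build_core_schema()
        register_punned_class(m, class_iri("MET_gene"), "MET_gene",
                              class_iri("gene"))
        assert not any("cycle" in p for p in m.check_invariants())


class TestStatistics:
    def test_core_counts(self, core_schema):
        s = schema_statistics(core_schema)
        assert (s.classes, s.punned_entities, s.cross_references) \
            == (38, 0, 0)
        assert s.object_properties > 0 and s.data_properties > 0

    def test_empty_schema_all_zero(self):
        s = schema_statistics(SchemaModel())
        assert (s.classes, s.object_properties, s.data_properties,
                s.punned_entities, s.cross_references) == (0, 0, 0, 0, 0)


class TestDLProfile:
    def test_core_schema_is_compliant(self, core_schema):
        assert check_dl_profile(core_schema) == []

    def test_cardinality_on_transitive_property_is_flagged(self):
        m = build_core_schema()
        m.add_restriction(Restriction(
            m.cls("gene").iri, m.prop("part_of"), "exactly", None, 1))
        violations = check_dl_profile(m)
        assert len(violations) == 1
        assert violations[0].property == m.prop("part_of")

    def test_transitive_property_without_restrictions_is_fine(self):
        m = build_core_schema()
        m.restrictions.clear()
        assert check_dl_profile(m) == []

    def test_sound_and_complete_against_brute_force(self):
        # independent brute-force scan of (transitive prop, restriction)
        m = build_core_schema()
        m.add_restriction(Restriction(
            m.cls("gene").iri, m.prop("part_of"), "min", None, 1))
        m.add_restriction(Restriction(
            m.cls("sample").iri, m.prop("has_part"), "max", None, 2))
        m.add_restriction(Restriction(
            m.cls("sample").iri, m.prop("has_cancer"), "exactly", None, 1))
        expected = {
            (r.property, r.kind)
            for r in m.restrictions
            if r.kind in ("exactly", "min", "max")
            and m.object_properties.get(r.property) is not None
            and m.object_properties[r.property].transitive
        }
        got = {(v.restriction.property, v.restriction.kind)
               for v in check_dl_profile(m)}
        assert got == expected and len(expected) == 2


class TestPitfalls:
    def test_core_schema_is_clean(self, core_schema):
        report = check_structural_pitfalls(core_schema)
        assert not report.all_findings()
        assert not report.has_critical

    def test_synonym_classes_trigger_p02(self):
        m = build_core_schema()
        m.equivalences.add(frozenset({
            m.cls("peptide_genome_assignment").iri,
            m.cls("genomic_region").iri}))
        report = check_structural_pitfalls(m)
        assert len(report["P02"]) == 1
        assert report.has_critical

    def test_no_disjointness_triggers_p10(self):
        m = build_core_schema()
        for iri, c in list(m.classes.items()):
            m.classes[iri] = ClassDef(
                c.iri, c.label, c.definition, c.parents, frozenset(),
                c.punned, c.cross_references)
        report = check_structural_pitfalls(m)
        assert len(report["P10"]) == 1

    def test_missing_inverse_triggers_p13_unless_exempt(self):
        m = build_core_schema()
        perf = m.object_properties[m.prop("performed_on")]
        inv = m.object_properties.pop(perf.inverse)
        m.object_properties[perf.iri] = type(perf)(
            perf.iri, perf.label, perf.domain, perf.range, None,
            perf.transitive, perf.broad_scope, perf.inverse_exempt)
        report = check_structural_pitfalls(m)
        flagged = {e for f in report["P13"] for e in f.entities}
        assert perf.iri in flagged
        assert m.prop("has_reference_genome") not in flagged
        assert inv.label == "analyzed by"

    def test_broad_scope_properties_exempt_from_p11(self, core_schema):
        report = check_structural_pitfalls(core_schema)
        assert not report["P11"]  # part_of/member_of are flagged broad

    def test_missing_license_triggers_p41(self):
        m = build_core_schema()
        m.license = None
        report = check_structural_pitfalls(m)
        assert len(report["P41"]) == 1

    def test_degraded_schema_triggers_all_three(self):
        m = build_core_schema()
        m.license = None
        m.equivalences.add(frozenset({
            m.cls("peptide_genome_assignment").iri,
            m.cls("genomic_region").iri}))
        for iri, c in list(m.classes.items()):
            m.classes[iri] = ClassDef(
                c.iri, c.label, c.definition, c.parents, frozenset(),
                c.punned, c.cross_references)
        report = check_structural_pitfalls(m)
        assert report["P02"] and report["P10"] and report["P41"]
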