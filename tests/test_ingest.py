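"""TSV reading and the instancing rules, checked against hand application
and brute-force relational counts."""

import pytest

from impo.ingest import (
    IngestIntegrityError, MappingCompileError, MappingRule, MappingSet,
    ROLE_FILENAMES, RowError, TABLE_SPECS, Table, TableSchemaError,
    apply_mappings, default_mapping_set, intervals_overlap, read_table,
)
from impo.naming import class_iri
from impo.schema import build_core_schema
from impo.store import TABLE_ROLES


def empty_tables():
    return {role: Table(TABLE_SPECS[role], []) for role in TABLE_ROLES}


def micro_tables(**rows_by_role):
    tables = empty_tables()
    for role, rows in rows_by_role.items():
        tables[role] = Table(TABLE_SPECS[role], rows)
    return tables


META_ROW = {"cancer_type": "Melanoma", "sample_id": "S01",
            "sample_type": "Tissues", "treatment": "Untreated",
            "ms_instrument": "Orbitrap", "study_id": "PXD000001"}
CLOSED_ROW = {"spectrum": "scan1", "peptide_sequence": "SIINFEKL",
              "sample_id": "S01", "study_id": "PXD000001", "score": 87.5}


class TestReadTable:
    def test_single_closed_search_row_is_typed(self):
        text = ("spectrum\tpeptide_sequence\tsample_id\tstudy_id\tscore\n"
                "scan1\tSIINFEKL\tS01\tPXD000001\t87.5\n")
        t = read_table(text, TABLE_SPECS["closed_search"])
        assert len(t) == 1
        assert t.rows[0]["score"] == 87.5

    def test_header_only_file_has_zero_rows(self):
        text = "spectrum\tpeptide_sequence\tsample_id\tstudy_id\tscore\n"
        assert len(read_table(text, TABLE_SPECS["closed_search"])) == 0

    def test_missing_column_names_the_absentee(self):
        text = "spectrum\tpeptide_sequence\tsample_id\tstudy_id\nx\ty\tz\tw\n"
        with pytest.raises(TableSchemaError, match="score"):
            read_table(text, TABLE_SPECS["closed_search"])

    def test_non_numeric_value_reports_row_number(self):
        text = ("spectrum\tpeptide_sequence\tsample_id\tstudy_id\tscore\n"
                "scan1\tSIINFEKL\tS01\tPXD000001\thigh\n")
        with pytest.raises(RowError, match="row 1"):
            read_table(text, TABLE_SPECS["closed_search"])

    def test_empty_optional_cells_become_nulls(self):
        cols = TABLE_SPECS["open_search"].required_columns
        text = "\t".join(cols) + "\nscan1\tSIINFEKL\tS01\tPXD1\t80\t\t\t\t\n"
        t = read_table(text, TABLE_SPECS["open_search"])
        assert t.rows[0]["position"] is None
        assert t.rows[0]["modification_type"] is None

    def test_header_aliases_are_applied(self):
        text = ("Spectrum ID\tpeptide_sequence\tsample_id\tstudy_id\tscore\n"
                "scan1\tSIINFEKL\tS01\tPXD1\t80\n")
        t = read_table(text, TABLE_SPECS["closed_search"],
                       aliases={"Spectrum ID": "spectrum"})
        assert t.rows[0]["spectrum"] == "scan1"

    def test_every_role_has_a_conventional_filename(self):
        assert set(ROLE_FILENAMES) == set(TABLE_ROLES)


class TestIntervalOverlap:
    @pytest.mark.parametrize("b, expected", [
        (("1", 110, 110), True),    # inside
        (("1", 126, 130), True),    # one shared base at the boundary
        (("1", 127, 130), False),   # adjacent, no shared base
        (("2", 110, 110), False),   # other chromosome
    ])
    def test_one_based_inclusive_semantics(self, b, expected):
        assert intervals_overlap("1", 100, 126, *b) is expected


class TestDefaultMapping:
    def test_compile_error_for_unknown_property(self):
        mappings = MappingSet([MappingRule(
            "closed_search", "x_{spectrum}", "spectrum",
            literal_map=(("score", "no_such_property"),))])
        with pytest.raises(MappingCompileError, match="no_such_property"):
            apply_mappings(micro_tables(closed_search=[CLOSED_ROW]),
                           mappings, build_core_schema())

    def test_empty_tables_yield_empty_graph(self):
        g = apply_mappings(empty_tables(), default_mapping_set(),
                           build_core_schema())
        assert g.statistics()["individuals"] == 0

    def test_one_closed_psm_row_yields_the_identification_triple(self):
        schema = build_core_schema()
        g = apply_mappings(
            micro_tables(study_metadata=[META_ROW],
                         closed_search=[CLOSED_ROW]),
            default_mapping_set(), schema)
        spectra = g.of_type(class_iri("spectrum"))
        peptides = g.of_type(class_iri("peptide"))
        psms = g.of_type(class_iri("spectrum_peptide_identification"))
        assert len(spectra) == len(peptides) == len(psms) == 1
        psm = next(iter(psms))
        assert g.objects(psm, schema.prop("has_source")) == spectra
        assert g.objects(psm, schema.prop("has_target")) == peptides
        assert g.values(psm, schema.prop("has_score")) == {87.5}
        assert g.values(psm, schema.prop("has_ms_strategy")) == {"closed"}

    def test_disease_free_sample_mints_no_cancer(self):
        row = dict(META_ROW, cancer_type="Disease free")
        g = apply_mappings(micro_tables(study_metadata=[row]),
                           default_mapping_set(), build_core_schema())
        schema = g.schema
        assert not any(
            g.of_type(c.iri) for c in schema.classes.values()
            if class_iri("cancer") in schema.ancestors(c.iri))

    def test_cancer_sample_typed_by_matching_subclass(self):
        g = apply_mappings(micro_tables(study_metadata=[META_ROW]),
                           default_mapping_set(), build_core_schema())
        cancers = g.of_type(class_iri("melanoma"))
        assert len(cancers) == 1
        assert g.individuals[next(iter(cancers))].label == "melanoma"

    def test_unknown_indication_falls_back_to_generic_cancer(self):
        row = dict(META_ROW, cancer_type="Umbrella syndrome")
        g = apply_mappings(micro_tables(study_metadata=[row]),
                           default_mapping_set(), build_core_schema())
        assert len(g.of_type(class_iri("cancer"))) == 1

    def test_unresolvable_psm_sample_is_an_integrity_error(self):
        with pytest.raises(IngestIntegrityError, match="row 1"):
            apply_mappings(micro_tables(closed_search=[CLOSED_ROW]),
                           default_mapping_set(), build_core_schema())

    def test_overlap_materialization_on_micro_bundle(self):
        schema = build_core_schema()
        lib = {"peptide_sequence": "SIINFEKL", "start": 100, "end": 126,
               "chromosome": "1", "tag": "canonical",
               "ms_strategy": "closed", "sample_id": "S01",
               "study_id": "PXD000001", "protein_id": None,
               "protein_start": None, "protein_end": None,
               "probability": None}
        muts = [
            {"mutation_id": "COSV1", "chromosome": "1", "strand": "+",
             "start": 110, "end": 110, "contig": "EC1"},
            {"mutation_id": "COSV2", "chromosome": "2", "strand": "+",
             "start": 110, "end": 110, "contig": "EC1"},
        ]
        contig = {"contig_id": "EC1", "chromosome": "1", "strand": "+",
                  "start": 90, "end": 200, "gene_mutational_ratio": 0.1,
                  "population_coverage": 0.5, "overlap_score": 0.2,
                  "expression": 10.0, "immune_score": 1.0}
        g = apply_mappings(
            micro_tables(study_metadata=[META_ROW], peptide_library=[lib],
                         mutations=muts, epitope_contigs=[contig]),
            default_mapping_set(), schema)
        overlaps = g._fwd[schema.prop("overlaps_mutation")]
        targets = {o for objs in overlaps.values() for o in objs}
        assert len(targets) == 1
        assert g.individuals[next(iter(targets))].label == "COSV1"
        contains = g._fwd[schema.prop("contains_peptide")]
        assert sum(len(v) for v in contains.values()) == 1

    def test_materialized_overlap_carries_library_provenance(self):
        schema = build_core_schema()
        lib = {"peptide_sequence": "SIINFEKL", "start": 100, "end": 126,
               "chromosome": "1", "tag": "canonical",
               "ms_strategy": "closed", "sample_id": "S01",
               "study_id": "PXD000001", "protein_id": None,
               "protein_start": None, "protein_end": None,
               "probability": None}
        mut = {"mutation_id": "COSV1", "chromosome": "1", "strand": "+",
               "start": 110, "end": 110, "contig": "EC1"}
        contig = {"contig_id": "EC1", "chromosome": "1", "strand": "+",
                  "start": 90, "end": 200, "gene_mutational_ratio": 0.1,
                  "population_coverage": 0.5, "overlap_score": 0.2,
                  "expression": 10.0, "immune_score": 1.0}
        g = apply_mappings(
            micro_tables(study_metadata=[META_ROW], peptide_library=[lib],
                         mutations=[mut], epitope_contigs=[contig]),
            default_mapping_set(), schema)
        a = next(x for x in g.assertions
                 if x.predicate == schema.prop("overlaps_mutation"))
        assert a.provenance.file_role == "peptide_library"
        assert a.provenance.row_number == 1

    def test_every_ingested_assertion_has_provenance(self, default_graph):
        assert all(a.provenance is not None
                   for a in default_graph.assertions)


class TestOracleCounts:
    def test_entity_counts_match_distinct_table_keys(self, default_bundle,
                                                     default_graph):
        t = default_bundle.tables
        expected = {
            "peptide": len(
                {r["peptide_sequence"] for r in t["peptide_library"].rows}
                | {r["peptide_sequence"]
                   for role in ("closed_search", "denovo_search",
                                "open_search")
                   for r in t[role].rows}
                | {r["peptide_sequence"]
                   for r in t["peptide_clusters"].rows}),
            "sample": len({r["sample_id"]
                           for r in t["study_metadata"].rows}),
            "gene": len({r["gene_name"] for r in t["id_mappings"].rows}),
            "transcript": len({r["transcript_id"]
                               for r in t["id_mappings"].rows}),
            "protein": len({r["protein_id"]
                            for r in t["id_mappings"].rows}),
            "mutation": len({r["mutation_id"]
                             for r in t["mutations"].rows}),
            "epitope_contig": len({r["contig_id"]
                                   for r in t["epitope_contigs"].rows}),
            "study": len({r["study_id"] for r in t["study_metadata"].rows}),
        }
        for local, n in expected.items():
            assert len(default_graph.of_type(class_iri(local))) == n, local

    def test_mapping_is_deterministic(self, default_bundle, default_graph):
        again = apply_mappings(default_bundle.tables, default_mapping_set(),
                               build_core_schema())
        assert again.serialize("nt") == default_graph.serialize("nt")

    def test_appending_rows_never_removes_assertions(self, default_bundle):
        schema_a = build_core_schema()
        base = apply_mappings(default_bundle.tables, default_mapping_set(),
                              schema_a)
        extended = dict(default_bundle.tables)
        meta = default_bundle.tables["study_metadata"].rows[0]
        extra = {"spectrum": "extra_scan", "peptide_sequence": "AAAAAAAA",
                 "sample_id": meta["sample_id"],
                 "study_id": meta["study_id"], "score": 50.0}
        extended["closed_search"] = Table(
            TABLE_SPECS["closed_search"],
            default_bundle.tables["closed_search"].rows + [extra])
        bigger = apply_mappings(extended, default_mapping_set(),
                                build_core_schema())
        assert base.assertions <= bigger.assertions
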