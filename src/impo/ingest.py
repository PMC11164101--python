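"""TSV-to-graph instancing via declarative mapping rules.

Ten tab-separated file roles describe a processed immunopeptidomics data
collection: three peptide-spectrum-match (PSM) tables (closed, de novo and
open search), peptide clustering and PSWM annotation, a COSMIC-style
mutation export, epitope-contig annotations, the identified-peptide
library, gene/transcript/protein ID mappings and study metadata.  Each
role carries a fixed column list; ``default_mapping_set`` holds the
normative rules that turn those rows into typed individuals and
assertions, every one stamped with its (file, row, column) provenance.

Coordinates are 1-based and inclusive on both ends (COSMIC convention);
genomic-interval overlap requires the same chromosome and at least one
shared base, ignoring strand.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Callable

import pandas as pd

from .naming import (
    class_iri, instance_iri, label_to_local, motif_key, normalize_cancer_label,
    is_disease_free, placement_key, protein_assignment_key, psm_key, ptm_key,
)
from .schema import SchemaModel
from .store import Assertion, InstanceGraph, SourceRef, TABLE_ROLES

log = logging.getLogger(__name__)


class TableSchemaError(ValueError):
    """A table is missing required columns (all absentees are listed)."""


class RowError(ValueError):
    """A cell value cannot be typed; the message names the 1-based row."""


class MappingCompileError(ValueError):
    """A mapping rule references an entity absent from the schema."""


class IngestIntegrityError(ValueError):
    """A join key cannot be resolved; offending rows are listed."""


# ---------------------------------------------------------------------------
# Table specifications (normative column lists, snake_case)

@dataclass(frozen=True)
class TableSpec:
    role: str
    required_columns: tuple[str, ...]
    key_columns: tuple[str, ...]
    #: column -> datatype for typed parsing ("text" columns are omitted)
    column_types: dict = field(default_factory=dict, compare=False)
    #: columns where an empty cell is an explicit null
    nullable: frozenset[str] = frozenset()


_PSM_COLS = ("spectrum", "peptide_sequence", "sample_id", "study_id", "score")

TABLE_SPECS: dict[str, TableSpec] = {
    "peptide_clusters": TableSpec(
        "peptide_clusters", ("peptide_sequence", "sample_id"),
        ("peptide_sequence", "sample_id")),
    "pswm_annotation": TableSpec(
        "pswm_annotation",
        ("component_1", "component_2", "pswm_group", "inferred_allele",
         "sample_id"),
        ("sample_id", "pswm_group"),
        {"component_1": "decimal", "component_2": "decimal"}),
    "closed_search": TableSpec(
        "closed_search", _PSM_COLS, ("peptide_sequence", "sample_id"),
        {"score": "decimal"}),
    "denovo_search": TableSpec(
        "denovo_search", _PSM_COLS, ("peptide_sequence", "sample_id"),
        {"score": "decimal"}),
    "open_search": TableSpec(
        "open_search",
        _PSM_COLS + ("position", "mass_shift", "modification",
                     "modification_type"),
        ("peptide_sequence", "sample_id"),
        {"score": "decimal", "position": "integer", "mass_shift": "decimal"},
        frozenset({"position", "mass_shift", "modification",
                   "modification_type"})),
    "mutations": TableSpec(
        "mutations",
        ("mutation_id", "chromosome", "strand", "start", "end", "contig"),
        ("mutation_id", "contig"),
        {"start": "integer", "end": "integer"}),
    "epitope_contigs": TableSpec(
        "epitope_contigs",
        ("contig_id", "chromosome", "strand", "start", "end",
         "gene_mutational_ratio", "population_coverage", "overlap_score",
         "expression", "immune_score"),
        ("contig_id",),
        {"start": "integer", "end": "integer",
         "gene_mutational_ratio": "decimal", "population_coverage": "decimal",
         "overlap_score": "decimal", "expression": "decimal",
         "immune_score": "decimal"}),
    "peptide_library": TableSpec(
        "peptide_library",
        ("peptide_sequence", "start", "end", "chromosome", "tag",
         "ms_strategy", "sample_id", "study_id", "protein_id",
         "protein_start", "protein_end", "probability"),
        ("peptide_sequence", "protein_id", "sample_id"),
        {"start": "integer", "end": "integer", "protein_start": "integer",
         "protein_end": "integer", "probability": "decimal"},
        frozenset({"protein_id", "protein_start", "protein_end",
                   "probability"})),
    "id_mappings": TableSpec(
        "id_mappings",
        ("gene_name", "gene_id", "transcript_name", "transcript_id",
         "protein_id"),
        ("gene_name", "transcript_id", "protein_id")),
    "study_metadata": TableSpec(
        "study_metadata",
        ("cancer_type", "sample_id", "sample_type", "treatment",
         "ms_instrument", "study_id"),
        ("sample_id", "study_id")),
}

#: Conventional on-disk file name per role.
ROLE_FILENAMES = {
    "peptide_clusters": "0.05_LG_umap_peptides_annotation_clustering.tsv",
    "pswm_annotation": "pswm_clustering_annotation.tsv",
    "closed_search": "closed_search_PSMs_HLA-I.tsv",
    "denovo_search": "denovo_90ALC_HLA-I.tsv",
    "open_search": "opensearch_PTMiner_HLA-I.tsv",
    "mutations": "CosmicMutantExport_nonredundant-immune-visible.tsv",
    "epitope_contigs": "GenomicImmuneClusters.tsv",
    "peptide_library": "immunopeptides_library.tsv",
    "id_mappings": "mappings.tsv",
    "study_metadata": "study_metadata.tsv",
}


@dataclass
class Table:
    spec: TableSpec
    rows: list[dict]

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Table) and self.spec.role == other.spec.role
                and self.rows == other.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.spec.required_columns)


def _type_cell(raw: str, datatype: str, nullable: bool, row_n: int,
               column: str):
    if raw == "" or raw is None:
        if nullable:
            return None
        raise RowError(f"row {row_n}: required column {column!r} is empty")
    if datatype == "integer":
        try:
            return int(raw)
        except ValueError:
            raise RowError(
                f"row {row_n}: non-numeric value {raw!r} in integer "
                f"column {column!r}") from None
    if datatype == "decimal":
        try:
            return float(raw)
        except ValueError:
            raise RowError(
                f"row {row_n}: non-numeric value {raw!r} in decimal "
                f"column {column!r}") from None
    return raw


def read_table(document, spec: TableSpec,
               aliases: dict[str, str] | None = None) -> Table:
    """Read one UTF-8, tab-separated file into a typed Table.

    ``document`` is a path or the raw text itself.  ``aliases`` optionally
    maps foreign header names to the normative snake_case columns.
    Decimals use the '.' separator; empty optional cells become nulls.
    """
    if isinstance(document, (str, os.PathLike)) and (
            isinstance(document, os.PathLike)
            or ("\n" not in document and "\t" not in document
                and os.path.exists(document))):
        text = Path(document).read_text(encoding="utf-8")
    else:
        text = str(document)
    df = pd.read_csv(StringIO(text), sep="\t", dtype=str,
                     keep_default_na=False)
    if aliases:
        df = df.rename(columns=aliases)
    missing = [c for c in spec.required_columns if c not in df.columns]
    if missing:
        raise TableSchemaError(
            f"table {spec.role!r} is missing required columns: "
            + ", ".join(missing))
    rows: list[dict] = []
    for i, rec in enumerate(df[list(spec.required_columns)]
                            .to_dict("records"), start=1):
        rows.append({
            c: _type_cell(rec[c], spec.column_types.get(c, "text"),
                          c in spec.nullable, i, c)
            for c in spec.required_columns
        })
    return Table(spec, rows)


def write_table(table: Table, path) -> None:
    from .store import canonical_lexical
    spec = table.spec
    lines = ["\t".join(spec.required_columns)]
    for row in table.rows:
        cells = []
        for c in spec.required_columns:
            v = row[c]
            if v is None:
                cells.append("")
            else:
                cells.append(canonical_lexical(
                    v, spec.column_types.get(c, "text")))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Genomic interval arithmetic (1-based, inclusive; strand ignored)

def intervals_overlap(chrom_a: str, start_a: int, end_a: int,
                      chrom_b: str, start_b: int, end_b: int) -> bool:
    """True when the two 1-based inclusive intervals share >= 1 bp."""
    return str(chrom_a) == str(chrom_b) and start_a <= end_b \
        and start_b <= end_a


# ---------------------------------------------------------------------------
# Mapping rules

@dataclass(frozen=True)
class LinkRule:
    """One object-property edge produced per source row."""

    property: str            # property label-local (e.g. "has_source")
    target_template: str     # IRI local-name pattern over columns
    target_class: str        # class local name
    #: "out": subject --property--> target; "in": target --property--> subject
    direction: str = "out"
    #: mint the other end if absent; False -> it must already exist (join)
    mint: bool = False
    target_label: str | None = None
    source_column: str = ""


@dataclass(frozen=True)
class MappingRule:
    source_role: str
    subject_template: str
    subject_class: str       # class local name; may be overridden per row
    label_template: str | None = None
    #: column -> data-property local name (datatype comes from the schema)
    literal_map: tuple = ()
    #: (property local, value, datatype) constants asserted per row
    constant_literals: tuple = ()
    link_map: tuple[LinkRule, ...] = ()
    condition: Callable[[dict], bool] | None = None
    punned: bool = False
    #: per-row class override, e.g. the cancer subclass for an indication
    class_fn: Callable[[dict, SchemaModel], tuple[str, str]] | None = \
        field(default=None, compare=False)
    constants: dict = field(default_factory=dict, compare=False)


@dataclass
class MappingSet:
    rules: list[MappingRule]
    post_passes: list[Callable] = field(default_factory=list)


def cancer_class_for(indication: str, schema: SchemaModel) -> tuple[str, str]:
    """Resolve an indication to a cancer subclass (iri, label).

    Unknown indications fall back to the generic cancer class with a
    warning.
    """
    label = normalize_cancer_label(indication)
    iri = class_iri(label_to_local(label), schema.namespace)
    cancer = class_iri("cancer", schema.namespace)
    if iri in schema.classes and cancer in schema.ancestors(iri):
        return iri, label
    log.warning("unknown cancer indication %r mapped to generic cancer",
                indication)
    return cancer, "cancer"


def _has_modification(row: dict) -> bool:
    return row.get("modification_type") is not None \
        and row.get("position") is not None


def _has_protein(row: dict) -> bool:
    return row.get("protein_id") is not None


def default_mapping_set() -> MappingSet:
    """The normative rules instancing the ten table roles.

    Per study-metadata row: study, sample (type/treatment literals, part_of
    the study), instrument, one mass-spectrometry assay per (sample, study)
    and — for non-disease-free samples — a cancer individual typed by the
    subclass matching the indication.  PSM rows yield spectrum, peptide and
    a scored spectrum-peptide identification; open-search rows with an
    annotated modification add a PTM individual.  The library yields
    genomic and protein placements of each peptide; mutations attach to
    their epitope contig.  Materialization passes then join motifs to
    clustered peptides and compute the genomic-interval overlaps behind
    ``contains_peptide`` and ``overlaps_mutation``.
    """
    rules: list[MappingRule] = []

    # --- study metadata ---------------------------------------------------
    rules += [
        MappingRule("study_metadata", "study_{study_id}", "study",
                    label_template="{study_id}"),
        MappingRule("study_metadata", "sample_{sample_id}", "sample",
                    label_template="{sample_id}",
                    literal_map=(("sample_type", "has_sample_type"),
                                 ("treatment", "has_treatment")),
                    link_map=(LinkRule("part_of", "study_{study_id}",
                                       "study", source_column="study_id"),)),
        MappingRule("study_metadata", "instrument_{ms_instrument}",
                    "ms_instrument", label_template="{ms_instrument}",
                    literal_map=(("ms_instrument", "has_instrument_model"),)),
        MappingRule("study_metadata", "ms_{sample_id}_{study_id}",
                    "mass_spectrometry",
                    label_template="ms_{sample_id}_{study_id}",
                    link_map=(
                        LinkRule("performed_on", "sample_{sample_id}",
                                 "sample", source_column="sample_id"),
                        LinkRule("uses_instrument",
                                 "instrument_{ms_instrument}",
                                 "ms_instrument",
                                 source_column="ms_instrument"),
                    )),
        MappingRule("study_metadata", "cancer_{sample_id}", "cancer",
                    condition=lambda r: not is_disease_free(r["cancer_type"]),
                    class_fn=lambda r, s: cancer_class_for(
                        r["cancer_type"], s),
                    link_map=(LinkRule("has_cancer", "sample_{sample_id}",
                                       "sample", direction="in",
                                       source_column="sample_id"),)),
    ]

    # --- gene / transcript / protein mappings -----------------------------
    rules += [
        MappingRule("id_mappings", "gene_{gene_name}", "gene",
                    label_template="{gene_name}", punned=True,
                    literal_map=(("gene_name", "has_gene_name"),
                                 ("gene_id", "has_gene_id"))),
        MappingRule("id_mappings", "transcript_{transcript_id}", "transcript",
                    label_template="{transcript_name}",
                    literal_map=(("transcript_id", "has_transcript_id"),),
                    link_map=(LinkRule("transcribed_to", "gene_{gene_name}",
                                       "gene", direction="in",
                                       source_column="gene_name"),)),
        MappingRule("id_mappings", "protein_{protein_id}", "protein",
                    label_template="{protein_id}",
                    literal_map=(("protein_id", "has_protein_id"),),
                    link_map=(LinkRule("translated_to",
                                       "transcript_{transcript_id}",
                                       "transcript", direction="in",
                                       source_column="transcript_id"),)),
    ]

    # --- epitope contigs ---------------------------------------------------
    rules.append(MappingRule(
        "epitope_contigs", "contig_{contig_id}", "epitope_contig",
        label_template="{contig_id}",
        literal_map=(("chromosome", "has_chromosome"),
                     ("strand", "has_strand"),
                     ("start", "has_start_position"),
                     ("end", "has_end_position"),
                     ("gene_mutational_ratio", "gene_mutational_ratio"),
                     ("population_coverage", "population_coverage"),
                     ("overlap_score", "overlap_score"),
                     ("expression", "expression"),
                     ("immune_score", "immune_score"))))

    # --- the three PSM strategies ------------------------------------------
    for role, strategy in (("closed_search", "closed"),
                           ("denovo_search", "denovo"),
                           ("open_search", "open")):
        rules += [
            MappingRule(role, "spectrum_{sample_id}_{spectrum}", "spectrum",
                        label_template="{spectrum}",
                        link_map=(LinkRule(
                            "has_output", "ms_{sample_id}_{study_id}",
                            "mass_spectrometry", direction="in",
                            source_column="sample_id"),)),
            MappingRule(role, "peptide_{peptide_sequence}", "peptide",
                        label_template="{peptide_sequence}",
                        literal_map=(("peptide_sequence", "has_sequence"),)),
            MappingRule(
                role,
                "psm_%s_{sample_id}_{spectrum}_{peptide_sequence}" % strategy,
                "spectrum_peptide_identification",
                label_template=(
                    "%s_{sample_id}_{spectrum}_{peptide_sequence}" % strategy),
                literal_map=(("score", "has_score"),),
                constant_literals=(("has_ms_strategy", strategy, "text"),),
                link_map=(
                    LinkRule("has_source", "spectrum_{sample_id}_{spectrum}",
                             "spectrum", mint=True,
                             source_column="spectrum"),
                    LinkRule("has_target", "peptide_{peptide_sequence}",
                             "peptide", mint=True,
                             source_column="peptide_sequence"),
                )),
        ]
    rules.append(MappingRule(
        "open_search",
        "ptm_{modification_type}_{peptide_sequence}_{position}",
        "post_translational_modification",
        label_template="{modification_type}_{peptide_sequence}_pos{position}",
        condition=_has_modification,
        literal_map=(("position", "has_modification_position"),
                     ("mass_shift", "has_mass_shift"),
                     ("modification_type", "has_modification_type")),
        link_map=(LinkRule("modifies", "peptide_{peptide_sequence}",
                           "peptide", mint=True,
                           source_column="peptide_sequence"),)))

    # --- peptide library: genomic and protein placements --------------------
    rules += [
        MappingRule("peptide_library", "peptide_{peptide_sequence}",
                    "peptide", label_template="{peptide_sequence}",
                    literal_map=(("peptide_sequence", "has_sequence"),)),
        MappingRule(
            "peptide_library",
            "pga_{peptide_sequence}_{chromosome}_{start}_{end}",
            "peptide_genome_assignment",
            label_template="{peptide_sequence}_{chromosome}_{start}_{end}",
            literal_map=(("chromosome", "has_chromosome"),
                         ("start", "has_start_position"),
                         ("end", "has_end_position"),
                         ("tag", "has_tag")),
            link_map=(LinkRule("has_source", "peptide_{peptide_sequence}",
                               "peptide", mint=True,
                               source_column="peptide_sequence"),)),
        MappingRule(
            "peptide_library", "ppa_{peptide_sequence}_{protein_id}",
            "peptide_protein_assignment",
            label_template="{peptide_sequence}_{protein_id}",
            condition=_has_protein,
            literal_map=(("protein_start", "has_start_position"),
                         ("protein_end", "has_end_position"),
                         ("probability", "has_probability")),
            link_map=(
                LinkRule("has_source", "peptide_{peptide_sequence}",
                         "peptide", mint=True,
                         source_column="peptide_sequence"),
                LinkRule("has_target", "protein_{protein_id}", "protein",
                         source_column="protein_id"),
            )),
    ]

    # --- mutations ----------------------------------------------------------
    rules.append(MappingRule(
        "mutations", "mutation_{mutation_id}", "mutation",
        label_template="{mutation_id}",
        literal_map=(("mutation_id", "has_mutation_id"),
                     ("chromosome", "has_chromosome"),
                     ("strand", "has_strand"),
                     ("start", "has_start_position"),
                     ("end", "has_end_position")),
        link_map=(LinkRule("located_in", "contig_{contig}", "epitope_contig",
                           source_column="contig"),)))

    # --- PSWM clustering: motifs and inferred HLA alleles --------------------
    rules += [
        MappingRule("pswm_annotation", "motif_{sample_id}_{pswm_group}",
                    "motif", label_template="{sample_id}_{pswm_group}",
                    literal_map=(("pswm_group", "has_pswm_group"),
                                 ("component_1", "has_component_1"),
                                 ("component_2", "has_component_2"))),
        MappingRule("pswm_annotation", "hla_{inferred_allele}",
                    "human_leukocyte_antigen",
                    label_template="{inferred_allele}",
                    literal_map=(("inferred_allele", "has_inferred_allele"),),
                    link_map=(
                        LinkRule("has_motif",
                                 "motif_{sample_id}_{pswm_group}", "motif",
                                 mint=True, source_column="pswm_group"),
                        LinkRule("observed_in", "sample_{sample_id}",
                                 "sample", source_column="sample_id"),
                    )),
        MappingRule("peptide_clusters", "peptide_{peptide_sequence}",
                    "peptide", label_template="{peptide_sequence}",
                    literal_map=(("peptide_sequence", "has_sequence"),)),
    ]

    return MappingSet(rules, post_passes=[
        _materialize_motif_membership,
        _materialize_contains_peptide,
        _materialize_overlaps_mutation,
    ])


# ---------------------------------------------------------------------------
# Materialization passes

def _materialize_motif_membership(tables, graph: InstanceGraph,
                                  schema: SchemaModel) -> None:
    """motif --derived_from--> peptide for every clustered peptide of the
    motif's sample (the clusters file carries no group column, so the join
    is on sample alone)."""
    derived = schema.prop("derived_from")
    by_sample: dict[str, list[str]] = {}
    for row in tables["pswm_annotation"].rows:
        by_sample.setdefault(row["sample_id"], []).append(
            motif_key(row["sample_id"], row["pswm_group"]))
    for n, row in enumerate(tables["peptide_clusters"].rows, start=1):
        pep = instance_iri("peptide_" + row["peptide_sequence"])
        for mk in by_sample.get(row["sample_id"], ()):
            graph.add_assertion(Assertion(
                instance_iri("motif_" + mk), derived, object=pep,
                provenance=SourceRef("peptide_clusters", n,
                                     "peptide_sequence")))


def _materialize_contains_peptide(tables, graph: InstanceGraph,
                                  schema: SchemaModel) -> None:
    """epitope_contig --contains_peptide--> peptide by genomic overlap."""
    contains = schema.prop("contains_peptide")
    for n, lib in enumerate(tables["peptide_library"].rows, start=1):
        for contig in tables["epitope_contigs"].rows:
            if intervals_overlap(contig["chromosome"], contig["start"],
                                 contig["end"], lib["chromosome"],
                                 lib["start"], lib["end"]):
                graph.add_assertion(Assertion(
                    instance_iri("contig_" + contig["contig_id"]), contains,
                    object=instance_iri(
                        "peptide_" + lib["peptide_sequence"]),
                    provenance=SourceRef("peptide_library", n,
                                         "peptide_sequence")))


def _materialize_overlaps_mutation(tables, graph: InstanceGraph,
                                   schema: SchemaModel) -> None:
    """peptide_genome_assignment --overlaps_mutation--> mutation."""
    overlaps = schema.prop("overlaps_mutation")
    for n, lib in enumerate(tables["peptide_library"].rows, start=1):
        pga = instance_iri("pga_" + placement_key(
            lib["peptide_sequence"], lib["chromosome"], lib["start"],
            lib["end"]))
        for mut in tables["mutations"].rows:
            if intervals_overlap(lib["chromosome"], lib["start"], lib["end"],
                                 mut["chromosome"], mut["start"], mut["end"]):
                graph.add_assertion(Assertion(
                    pga, overlaps,
                    object=instance_iri("mutation_" + mut["mutation_id"]),
                    provenance=SourceRef("peptide_library", n,
                                         "peptide_sequence")))


# ---------------------------------------------------------------------------
# Engine

def _compile(mappings: MappingSet, schema: SchemaModel) -> None:
    for rule in mappings.rules:
        if rule.source_role not in TABLE_ROLES:
            raise MappingCompileError(f"unknown role {rule.source_role!r}")
        if rule.class_fn is None:
            iri = class_iri(rule.subject_class, schema.namespace)
            if iri not in schema.classes:
                raise MappingCompileError(
                    f"rule on {rule.source_role!r}: unknown class "
                    f"{rule.subject_class!r}")
        for _, prop in rule.literal_map:
            if class_iri(prop, schema.namespace) \
                    not in schema.data_properties:
                raise MappingCompileError(
                    f"rule on {rule.source_role!r}: unknown data property "
                    f"{prop!r}")
        for prop, _, _ in rule.constant_literals:
            if class_iri(prop, schema.namespace) \
                    not in schema.data_properties:
                raise MappingCompileError(
                    f"rule on {rule.source_role!r}: unknown data property "
                    f"{prop!r}")
        for link in rule.link_map:
            if class_iri(link.property, schema.namespace) \
                    not in schema.object_properties:
                raise MappingCompileError(
                    f"rule on {rule.source_role!r}: unknown object property "
                    f"{link.property!r}")
            if class_iri(link.target_class, schema.namespace) \
                    not in schema.classes:
                raise MappingCompileError(
                    f"rule on {rule.source_role!r}: unknown class "
                    f"{link.target_class!r}")


def _fmt(template: str, row: dict) -> str:
    return template.format(**row)


def apply_mappings(tables: dict[str, Table], mappings: MappingSet,
                   schema: SchemaModel) -> InstanceGraph:
    """Instance the tables into a fresh graph (deterministic).

    Mapping-compile errors surface before any row is processed; unresolvable
    join keys (e.g. a PSM sample absent from study_metadata) raise an
    integrity error listing every offending row.
    """
    _compile(mappings, schema)
    roles_needed = {r.source_role for r in mappings.rules}
    missing_roles = sorted(roles_needed - set(tables))
    if missing_roles:
        raise KeyError(f"missing table roles: {', '.join(missing_roles)}")

    graph = InstanceGraph(schema=schema)
    offenses: list[str] = []

    for rule in mappings.rules:
        cls_iri_default = class_iri(rule.subject_class, schema.namespace) \
            if rule.class_fn is None else None
        for n, row in enumerate(tables[rule.source_role].rows, start=1):
            if rule.condition is not None and not rule.condition(row):
                continue
            if rule.class_fn is not None:
                cls_iri, label = rule.class_fn(row, schema)
            else:
                cls_iri = cls_iri_default
                label = _fmt(rule.label_template, row) \
                    if rule.label_template else None
            subject = graph.mint_individual(
                cls_iri, _fmt(rule.subject_template, row), label=label,
                punned=rule.punned)
            for column, prop in rule.literal_map:
                value = row.get(column)
                if value is None:
                    continue
                spec = tables[rule.source_role].spec
                graph.add_assertion(Assertion(
                    subject.iri, class_iri(prop, schema.namespace),
                    value=value,
                    datatype=spec.column_types.get(column, "text"),
                    provenance=SourceRef(rule.source_role, n, column)))
            for prop, value, dt in rule.constant_literals:
                graph.add_assertion(Assertion(
                    subject.iri, class_iri(prop, schema.namespace),
                    value=value, datatype=dt,
                    provenance=SourceRef(rule.source_role, n, prop)))
            for link in rule.link_map:
                target_local = _fmt(link.target_template, row)
                target_iri = instance_iri(target_local)
                if target_iri not in graph.individuals:
                    if link.mint:
                        graph.mint_individual(
                            class_iri(link.target_class, schema.namespace),
                            target_local,
                            label=_fmt(link.target_label, row)
                            if link.target_label else None)
                    else:
                        offenses.append(
                            f"{rule.source_role} row {n}: unresolvable "
                            f"{link.source_column or link.property} -> "
                            f"{target_local}")
                        continue
                prov = SourceRef(rule.source_role, n,
                                 link.source_column or link.property)
                if link.direction == "out":
                    a = Assertion(subject.iri,
                                  class_iri(link.property, schema.namespace),
                                  object=target_iri, provenance=prov)
                else:
                    a = Assertion(target_iri,
                                  class_iri(link.property, schema.namespace),
                                  object=subject.iri, provenance=prov)
                graph.add_assertion(a)

    if offenses:
        raise IngestIntegrityError(
            "unresolvable join keys:\n" + "\n".join(offenses))

    for post in mappings.post_passes:
        post(tables, graph, schema)
    return graph


def read_tables(paths: dict[str, str | os.PathLike],
                aliases: dict[str, dict[str, str]] | None = None
                ) -> dict[str, Table]:
    """Read a role -> path manifest into typed tables."""
    tables = {}
    for role, path in paths.items():
        if role not in TABLE_SPECS:
            raise KeyError(f"unknown table role {role!r}")
        tables[role] = read_table(Path(path), TABLE_SPECS[role],
                                  (aliases or {}).get(role))
    return tables
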