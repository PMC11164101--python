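"""The fifteen competency questions as executable queries.

Each question is formalized as a basic graph pattern over the core schema
(the "ontological path" between the entities named in the question) and
answered along two independent routes: a small hand-written join engine
over the in-memory instance graph, and a SPARQL 1.1 SELECT generated from
the same pattern and executed by rdflib.  Answer tuples contain entity
labels (natural keys) and literal values, so they are directly comparable
with the relational oracle computed from the source tables.

Accuracy is Jaccard similarity times 100 — 100 exactly when the obtained
and expected sets are equal (two empty sets count as equal), which
operationalizes "retrieve all the expected entries and no others" while
giving partial credit proportional to the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

from rdflib import Literal, RDFS

from .naming import SCHEMA_NS, class_iri
from .results import CQ_VARIABLES, ResultSet
from .schema import SchemaModel, build_core_schema
from .store import InstanceGraph
from .synthdata import DatasetBundle, SHARED_PEPTIDE_THRESHOLD, \
    oracle_answers


class CatalogSchemaError(KeyError):
    """A catalogued path references an entity absent from the schema."""


class QuerySchemaMismatch(ValueError):
    """Two result sets with different variable schemas were compared."""


# pattern kinds: ("type", var, class_local)
#                ("edge", subj_var, property_local, obj_var)
#                ("lit",  subj_var, property_local, value_var)
Pattern = tuple


@dataclass(frozen=True)
class Grouping:
    """HAVING COUNT(DISTINCT counted) >= threshold, grouped by ``key``."""

    key: str
    counted: str
    threshold: int


@dataclass
class CompetencyQuestion:
    id: int
    text: str
    #: documented entity chain: (class, property to next, direction)
    path: tuple[tuple[str, str | None, str | None], ...]
    patterns: tuple[Pattern, ...]
    #: selected (variable, kind) pairs; kind "ind" projects the label
    select: tuple[tuple[str, str], ...]
    result_schema: tuple[str, ...]
    grouping: Grouping | None = None
    #: for composite questions: (patterns, projections) sub-blocks joined
    #: on their shared variables in the generated SPARQL
    blocks: tuple | None = None
    sparql: str = field(default="", compare=False)


_CQ_TEXTS = {
    1: "For each sample, extract the corresponding peptides",
    2: "For each HLA type, extract the corresponding peptides",
    3: "For each epitope contig, extract the corresponding peptides",
    4: "For each sample, extract the MS instrument",
    5: "For each protein, extract the peptides",
    6: "For each gene, extract the peptides",
    7: "For each post-translational modification, extract the position in "
       "the corresponding peptide",
    8: "Extract peptides that are shared across at least 10 "
       "non-disease-free samples",
    9: "For each peptide, extract all associated mutations and their "
       "genomic coordinates",
    10: "For each epitope contig, extract all associated mutations and "
        "their genomic coordinates",
    11: "For each cancer, extract all associated mutations and proteins",
    12: "For each cancer, extract all associated mutations and peptides",
    13: "For each cancer, extract all associated mutations and PSMs",
    14: "For each cancer, extract all associated mutations and PTMs",
    15: "For each cancer, extract all associated mutations and epitope "
        "contigs",
}

#: How many of the ten files the relational oracle consults per question.
CQ_FILES_CONSULTED = {
    1: "3/10", 2: "2/10", 3: "2/10", 4: "1/10", 5: "1/10", 6: "2/10",
    7: "1/10", 8: "4/10", 9: "2/10", 10: "2/10", 11: "6/10", 12: "6/10",
    13: "6/10", 14: "6/10", 15: "7/10",
}

# sample -> mass spectrometry -> spectrum -> identification -> peptide
# (type constraints follow the edge that binds their variable, so both
# engines evaluate the patterns as a selective chain, never a product)
_CHAIN_SAMPLE_PEPTIDE: tuple[Pattern, ...] = (
    ("type", "?s", "sample"),
    ("edge", "?ms", "performed_on", "?s"),
    ("edge", "?ms", "has_output", "?sp"),
    ("edge", "?psm", "has_source", "?sp"),
    ("type", "?psm", "spectrum_peptide_identification"),
    ("edge", "?psm", "has_target", "?p"),
)
_PATH_SAMPLE_PEPTIDE = (
    ("sample", "performed_on", "inverse"),
    ("mass_spectrometry", "has_output", "forward"),
    ("spectrum", "has_source", "inverse"),
    ("spectrum_peptide_identification", "has_target", "forward"),
    ("peptide", None, None),
)

_CHAIN_PROTEIN: tuple[Pattern, ...] = (
    ("type", "?ppa", "peptide_protein_assignment"),
    ("edge", "?ppa", "has_source", "?p"),
    ("edge", "?ppa", "has_target", "?pr"),
)

# same relation entered from an already-bound peptide variable
_CHAIN_PROTEIN_FROM_P: tuple[Pattern, ...] = (
    ("edge", "?ppa", "has_source", "?p"),
    ("type", "?ppa", "peptide_protein_assignment"),
    ("edge", "?ppa", "has_target", "?pr"),
)

_CHAIN_MUTATION: tuple[Pattern, ...] = (
    ("edge", "?pga", "has_source", "?p"),
    ("type", "?pga", "peptide_genome_assignment"),
    ("edge", "?pga", "overlaps_mutation", "?m"),
)

_CANCER_BASE: tuple[Pattern, ...] = (
    ("edge", "?s", "has_cancer", "?c"),
) + _CHAIN_SAMPLE_PEPTIDE + _CHAIN_MUTATION

_PATH_CANCER = (("cancer", "has_cancer", "inverse"),) \
    + _PATH_SAMPLE_PEPTIDE[:-1] \
    + (("peptide", "has_source", "inverse"),
       ("peptide_genome_assignment", "overlaps_mutation", "forward"),
       ("mutation", None, None))


def _definitions() -> dict[int, dict]:
    mut_lits: tuple[Pattern, ...] = (
        ("lit", "?m", "has_chromosome", "?ch"),
        ("lit", "?m", "has_start_position", "?st"),
        ("lit", "?m", "has_end_position", "?en"),
    )
    # sub-select blocks for the composite cancer questions, joined on ?p
    block_cancer_peptide = (
        (("edge", "?s", "has_cancer", "?c"),) + _CHAIN_SAMPLE_PEPTIDE,
        (("?c", "out"), ("?p", "join")))
    block_peptide_mutation = (
        _CHAIN_MUTATION, (("?p", "join"), ("?m", "out")))
    return {
        1: dict(patterns=_CHAIN_SAMPLE_PEPTIDE,
                select=(("?s", "ind"), ("?p", "ind")),
                path=_PATH_SAMPLE_PEPTIDE),
        2: dict(patterns=(("type", "?h", "human_leukocyte_antigen"),
                          ("edge", "?h", "has_motif", "?mo"),
                          ("edge", "?mo", "derived_from", "?p")),
                select=(("?h", "ind"), ("?p", "ind")),
                path=(("human_leukocyte_antigen", "has_motif", "forward"),
                      ("motif", "derived_from", "forward"),
                      ("peptide", None, None))),
        3: dict(patterns=(("type", "?ec", "epitope_contig"),
                          ("edge", "?ec", "contains_peptide", "?p")),
                select=(("?ec", "ind"), ("?p", "ind")),
                path=(("epitope_contig", "contains_peptide", "forward"),
                      ("peptide", None, None))),
        4: dict(patterns=(("type", "?s", "sample"),
                          ("edge", "?ms", "performed_on", "?s"),
                          ("edge", "?ms", "uses_instrument", "?i")),
                select=(("?s", "ind"), ("?i", "ind")),
                path=(("sample", "performed_on", "inverse"),
                      ("mass_spectrometry", "uses_instrument", "forward"),
                      ("ms_instrument", None, None))),
        5: dict(patterns=_CHAIN_PROTEIN,
                select=(("?pr", "ind"), ("?p", "ind")),
                path=(("protein", "has_target", "inverse"),
                      ("peptide_protein_assignment", "has_source",
                       "forward"),
                      ("peptide", None, None))),
        6: dict(patterns=(("type", "?g", "gene"),
                          ("edge", "?g", "transcribed_to", "?t"),
                          ("edge", "?t", "translated_to", "?pr"),
                          ("edge", "?ppa", "has_target", "?pr"),
                          ("type", "?ppa", "peptide_protein_assignment"),
                          ("edge", "?ppa", "has_source", "?p")),
                select=(("?g", "ind"), ("?p", "ind")),
                path=(("gene", "transcribed_to", "forward"),
                      ("transcript", "translated_to", "forward"),
                      ("protein", "has_target", "inverse"),
                      ("peptide_protein_assignment", "has_source",
                       "forward"),
                      ("peptide", None, None))),
        7: dict(patterns=(("type", "?ptm",
                           "post_translational_modification"),
                          ("edge", "?ptm", "modifies", "?p"),
                          ("lit", "?ptm", "has_modification_position",
                           "?pos")),
                select=(("?ptm", "ind"), ("?p", "ind"), ("?pos", "lit")),
                path=(("post_translational_modification", "modifies",
                       "forward"),
                      ("peptide", None, None))),
        8: dict(patterns=_CHAIN_SAMPLE_PEPTIDE
                + (("edge", "?s", "has_cancer", "?c"),),
                select=(("?p", "ind"),),
                grouping=Grouping("?p", "?s", SHARED_PEPTIDE_THRESHOLD),
                path=_PATH_SAMPLE_PEPTIDE),
        9: dict(patterns=_CHAIN_MUTATION + mut_lits,
                select=(("?p", "ind"), ("?m", "ind"), ("?ch", "lit"),
                        ("?st", "lit"), ("?en", "lit")),
                path=(("peptide", "has_source", "inverse"),
                      ("peptide_genome_assignment", "overlaps_mutation",
                       "forward"),
                      ("mutation", None, None))),
        10: dict(patterns=(("type", "?m", "mutation"),
                           ("edge", "?m", "located_in", "?ec")) + mut_lits,
                 select=(("?ec", "ind"), ("?m", "ind"), ("?ch", "lit"),
                         ("?st", "lit"), ("?en", "lit")),
                 path=(("epitope_contig", "located_in", "inverse"),
                       ("mutation", None, None))),
        11: dict(patterns=_CANCER_BASE + _CHAIN_PROTEIN_FROM_P,
                 select=(("?c", "ind"), ("?m", "ind"), ("?pr", "ind")),
                 blocks=(block_cancer_peptide, block_peptide_mutation,
                         (_CHAIN_PROTEIN_FROM_P,
                          (("?p", "join"), ("?pr", "out")))),
                 path=_PATH_CANCER),
        12: dict(patterns=_CANCER_BASE,
                 select=(("?c", "ind"), ("?m", "ind"), ("?p", "ind")),
                 blocks=(block_cancer_peptide, block_peptide_mutation,
                         ((), (("?p", "join"), ("?p", "out")))),
                 path=_PATH_CANCER),
        13: dict(patterns=_CANCER_BASE
                 + (("edge", "?psm2", "has_target", "?p"),
                    ("type", "?psm2", "spectrum_peptide_identification")),
                 select=(("?c", "ind"), ("?m", "ind"), ("?psm2", "ind")),
                 blocks=(block_cancer_peptide, block_peptide_mutation,
                         ((("edge", "?psm2", "has_target", "?p"),
                           ("type", "?psm2",
                            "spectrum_peptide_identification")),
                          (("?p", "join"), ("?psm2", "out")))),
                 path=_PATH_CANCER),
        14: dict(patterns=_CANCER_BASE
                 + (("edge", "?ptm", "modifies", "?p"),
                    ("type", "?ptm", "post_translational_modification")),
                 select=(("?c", "ind"), ("?m", "ind"), ("?ptm", "ind")),
                 blocks=(block_cancer_peptide, block_peptide_mutation,
                         ((("edge", "?ptm", "modifies", "?p"),
                           ("type", "?ptm",
                            "post_translational_modification")),
                          (("?p", "join"), ("?ptm", "out")))),
                 path=_PATH_CANCER),
        15: dict(patterns=_CANCER_BASE
                 + (("edge", "?ec", "contains_peptide", "?p"),
                    ("type", "?ec", "epitope_contig")),
                 select=(("?c", "ind"), ("?m", "ind"), ("?ec", "ind")),
                 blocks=(block_cancer_peptide, block_peptide_mutation,
                         ((("edge", "?ec", "contains_peptide", "?p"),
                           ("type", "?ec", "epitope_contig")),
                          (("?p", "join"), ("?ec", "out")))),
                 path=_PATH_CANCER),
    }


def _pattern_lines(patterns, indent: str = "    ") -> list[str]:
    body = []
    for pat in patterns:
        if pat[0] == "type":
            body.append(f"{indent}{pat[1]} a impo:{pat[2]} .")
        else:
            _, s, prop, o = pat
            body.append(f"{indent}{s} impo:{prop} {o} .")
    return body


def _to_sparql(patterns, select, grouping, namespace: str,
               blocks=None) -> str:
    lines = [
        f"PREFIX impo: <{namespace}>",
        f"PREFIX rdfs: <{str(RDFS)}>",
    ]
    if blocks is not None:
        # Composite question: each block becomes a DISTINCT sub-select
        # projecting its join variables and the labels of its outputs.
        # This keeps every intermediate result small no matter how the
        # engine orders the joins.
        proj = [f"{var}_label" if kind == "ind" else var
                for var, kind in select]
        lines.append("SELECT DISTINCT " + " ".join(proj) + " WHERE {")
        for block_patterns, block_proj in blocks:
            inner_proj, inner_body = [], _pattern_lines(block_patterns,
                                                        "        ")
            for var, kind in block_proj:
                if kind == "join":
                    inner_proj.append(var)
                else:  # "out": project this individual's label
                    inner_body.append(
                        f"        {var} rdfs:label {var}_label .")
                    inner_proj.append(f"{var}_label")
            lines.append("    { SELECT DISTINCT "
                         + " ".join(inner_proj) + " WHERE {")
            lines.extend(inner_body)
            lines.append("    } }")
        lines.append("}")
        return "\n".join(lines)

    body = _pattern_lines(patterns)
    proj = []
    for var, kind in select:
        if kind == "ind":
            label_var = f"{var}_label"
            body.append(f"    {var} rdfs:label {label_var} .")
            proj.append(label_var)
        else:
            proj.append(var)
    if grouping is None:
        lines.append("SELECT DISTINCT " + " ".join(proj) + " WHERE {")
        lines.extend(body)
        lines.append("}")
    else:
        lines.append("SELECT " + " ".join(proj) + " WHERE {")
        lines.extend(body)
        lines.append("}")
        lines.append("GROUP BY " + " ".join(proj))
        lines.append(
            f"HAVING (COUNT(DISTINCT {grouping.counted}) >= "
            f"{grouping.threshold})")
    return "\n".join(lines)


def cq_catalog(namespace: str = SCHEMA_NS) -> list[CompetencyQuestion]:
    """The fifteen catalogued competency questions, in published order."""
    catalog = []
    for cq_id, d in sorted(_definitions().items()):
        cq = CompetencyQuestion(
            id=cq_id, text=_CQ_TEXTS[cq_id], path=tuple(d["path"]),
            patterns=tuple(d["patterns"]), select=tuple(d["select"]),
            result_schema=CQ_VARIABLES[cq_id],
            grouping=d.get("grouping"), blocks=d.get("blocks"))
        cq.sparql = _to_sparql(cq.patterns, cq.select, cq.grouping,
                               namespace, blocks=cq.blocks)
        catalog.append(cq)
    return catalog


# ---------------------------------------------------------------------------
# Native evaluation: a sequential-join basic-graph-pattern matcher


def _check_catalog_against_schema(cq: CompetencyQuestion,
                                  schema: SchemaModel) -> None:
    for pat in cq.patterns:
        if pat[0] == "type":
            if class_iri(pat[2], schema.namespace) not in schema.classes:
                raise CatalogSchemaError(
                    f"CQ{cq.id}: class {pat[2]!r} missing from schema")
        else:
            try:
                schema.prop(pat[2])
            except KeyError:
                raise CatalogSchemaError(
                    f"CQ{cq.id}: property {pat[2]!r} missing from "
                    "schema") from None


def _match(graph: InstanceGraph, schema: SchemaModel, pat: Pattern,
           binding: dict) -> list[dict]:
    kind = pat[0]
    if kind == "type":
        _, var, cls = pat
        iris = graph.of_type(class_iri(cls, schema.namespace))
        if var in binding:
            return [binding] if binding[var] in iris else []
        return [{**binding, var: iri} for iri in sorted(iris)]
    if kind == "edge":
        _, s, prop, o = pat
        pred = class_iri(prop, schema.namespace)
        sb, ob = binding.get(s), binding.get(o)
        if sb is not None and ob is not None:
            return [binding] if ob in graph.objects(sb, pred) else []
        if sb is not None:
            return [{**binding, o: x}
                    for x in sorted(graph.objects(sb, pred))]
        if ob is not None:
            return [{**binding, s: x}
                    for x in sorted(graph.subjects(pred, ob))]
        out = []
        for subj, objs in sorted(graph._fwd[pred].items()):
            for obj in sorted(objs):
                out.append({**binding, s: subj, o: obj})
        return out
    # literal
    _, s, prop, v = pat
    pred = class_iri(prop, schema.namespace)
    sb = binding.get(s)
    if sb is not None:
        vals = graph.values(sb, pred)
        if v in binding:
            return [binding] if binding[v] in vals else []
        return [{**binding, v: x} for x in sorted(vals, key=str)]
    out = []
    for subj, vals in sorted(graph._data[pred].items()):
        for val, _dt in sorted(vals, key=str):
            out.append({**binding, s: subj, v: val})
    return out


def _project(graph: InstanceGraph, binding: dict,
             select) -> tuple:
    row = []
    for var, kind in select:
        v = binding[var]
        if kind == "ind":
            ind = graph.individuals.get(v)
            row.append(ind.label if ind is not None else v)
        else:
            row.append(v)
    return tuple(row)


def answer_cq(graph: InstanceGraph, cq: CompetencyQuestion) -> ResultSet:
    """Answer one question by native graph traversal (deduplicated,
    deterministic)."""
    schema = graph.schema or build_core_schema()
    _check_catalog_against_schema(cq, schema)
    bindings: list[dict] = [{}]
    for pat in cq.patterns:
        nxt: list[dict] = []
        for b in bindings:
            nxt.extend(_match(graph, schema, pat, b))
        bindings = nxt
        if not bindings:
            break
    if cq.grouping is not None:
        groups: dict[object, set] = {}
        for b in bindings:
            groups.setdefault(b[cq.grouping.key], set()).add(
                b[cq.grouping.counted])
        bindings = [
            {cq.grouping.key: key}
            for key, members in groups.items()
            if len(members) >= cq.grouping.threshold
        ]
    tuples = {_project(graph, b, cq.select) for b in bindings}
    return ResultSet(cq.result_schema, frozenset(tuples))


def answer_cq_sparql(graph: InstanceGraph,
                     cq: CompetencyQuestion) -> ResultSet:
    """Answer one question through the generated SPARQL query (rdflib)."""
    try:
        rows = graph.to_rdflib().query(cq.sparql)
    except Exception as exc:
        raise RuntimeError(f"SPARQL engine failure on CQ{cq.id}: "
                           f"{exc}") from exc
    tuples = set()
    for row in rows:
        out = []
        for cell in row:
            if isinstance(cell, Literal):
                v = cell.toPython()
                if isinstance(v, Decimal):
                    v = float(v)
                out.append(v)
            else:
                out.append(str(cell))
        tuples.add(tuple(out))
    return ResultSet(cq.result_schema, frozenset(tuples))


# ---------------------------------------------------------------------------
# Scoring


def score_accuracy(obtained: ResultSet, expected: ResultSet) -> float:
    """Jaccard similarity x 100; 100.0 for two empty sets; symmetric."""
    if obtained.variables != expected.variables:
        raise QuerySchemaMismatch(
            f"variable schemas differ: {obtained.variables} vs "
            f"{expected.variables}")
    union = obtained.tuples | expected.tuples
    if not union:
        return 100.0
    return 100.0 * len(obtained.tuples & expected.tuples) / len(union)


@dataclass
class SuiteRow:
    cq_id: int
    text: str
    expected_count: int
    obtained_count: int
    accuracy: float
    files_consulted: str


@dataclass
class SuiteReport:
    rows: list[SuiteRow]
    engine: str

    @property
    def min_accuracy(self) -> float:
        return min((r.accuracy for r in self.rows), default=100.0)

    def to_tsv(self) -> str:
        lines = ["CQ\tExpected entries\tTuples by query\tAccuracy (%)"
                 "\tFiles"]
        for r in self.rows:
            lines.append(
                f"{r.cq_id}. {r.text}\t{r.expected_count}"
                f"\t{r.obtained_count}\t{r.accuracy:g}\t{r.files_consulted}")
        return "\n".join(lines) + "\n"


def run_suite(graph: InstanceGraph, bundle: DatasetBundle,
              engine: str = "native") -> SuiteReport:
    """Score every catalogued question against the relational oracle."""
    evaluate = {"native": answer_cq, "sparql": answer_cq_sparql}[engine]
    rows = []
    for cq in cq_catalog():
        expected = bundle.ground_truth.get(cq.id) \
            or oracle_answers(bundle, cq.id)
        obtained = evaluate(graph, cq)
        rows.append(SuiteRow(
            cq.id, cq.text, len(expected), len(obtained),
            score_accuracy(obtained, expected),
            CQ_FILES_CONSULTED[cq.id]))
    return SuiteReport(rows, engine)
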