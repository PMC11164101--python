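# Methods

## The semantic model

The model splits immunopeptidomics into an experimental and a biological
subdomain. Experimentally, a `mass_spectrometry` assay is `performed_on` a
`sample` (which is `part_of` a `study`, carries type/treatment attributes
and, for tumor samples, `has_cancer` an individual typed by the matching
cancer subclass) and `has_output` one `spectrum` per acquired scan.
Inference results are reified as `assignment` individuals rather than bare
edges, because each inferred relation carries attributes of its own: a
`spectrum_peptide_identification` connects a spectrum (`has_source`) to a
`peptide` (`has_target`) with a search score and strategy; a
`peptide_protein_assignment` places a peptide in a protein with positions
and a probability; a `peptide_genome_assignment` places it on the genome.
Biologically, `gene → transcript → protein` chains come from the ID
mappings, `mutation`s live inside `epitope_contig`s (genomic regions
surveyed by the immune system at high frequency, scored by expression,
population coverage, immune score, gene-mutational ratio and overlap
score), and PSWM clustering yields per-sample `motif`s from which the
presenting `human_leukocyte_antigen` allele is inferred.

Three modelling conventions matter downstream:

- **Punning.** Reference-genome genes are both individuals (the single
  instance placed on the genome) and classes (so patient-level gene
  concepts can subclass them). The two facets share one IRI but are
  distinct nodes for every structural check, so punning never influences
  cycle detection or disjointness.
- **Cancer types.** Each tumor sample's disease is an individual typed
  *solely* by the matching cancer subclass (melanoma, leukemia, ...); the
  generic `cancer` class is used only for unrecognized indications, with a
  warning.
- **Naming.** Local names are the human-readable labels with underscores
  (`human_leukocyte_antigen`), not alphanumeric codes, because the
  ontology is meant to be instanced with data that people read. Instance
  IRIs embed natural keys (sample IDs, peptide sequences, allele names),
  which makes instancing deterministic and answers comparable by label.

The built-in core schema is a normative 38-class subset that covers
everything the ten file roles need. Property names that the ten tables
require but that have no canonical published name (`performed_on`,
`transcribed_to`, `contains_peptide`, ...) are minted here and documented
in the schema module; the broad-scope `part_of` is transitive with
deliberately empty domain and range, and its non-transitive sibling
`member_of` exists for relations that need cardinality restrictions
(OWL 2 DL forbids cardinality on transitive properties — the profile
checker enforces exactly this rule). Larger published ontology documents
can be loaded with `load_ontology`, which tolerates dangling references
(collected as warnings) and recognizes punned declarations.

Multiple domain (or range) classes on one property are interpreted
**set-wise** — the subject must match *any* of them — both in
serialization (multiple `rdfs:domain` triples) and in validation. This
deviates from OWL's intersection semantics deliberately: the validator is
a closed-world data-QC tool, and "any-of" is the semantics the source
tables actually obey (e.g. `has_start_position` applies to assignments,
mutations and contigs alike).

## Pitfall severities

The five structural checks (P02 synonym classes, P10 missing
disjointness, P11 missing domain/range, P13 missing inverses, P41 missing
license) are ranked critical / important / important / minor / important
respectively — our own mapping, chosen so that only an outright modelling
error (two named classes declared equivalent) fails a lint run.
Broad-scope properties are exempt from P11 and `has_reference_genome`
from P13, since its inverse would never be asserted at the data level.

## Instancing

Mapping rules are declarative: per source row, a subject template over
column values, a class, literal assignments and link rules whose targets
either get minted or must already exist (the latter is how unresolvable
join keys — e.g. a PSM referencing an unknown sample — surface as
integrity errors listing the offending rows). Every assertion carries a
`(file role, 1-based row, column)` provenance reference. Two
materialization passes compute genomic-interval overlaps after the row
rules: `contains_peptide` (contig × library placement) and
`overlaps_mutation` (placement × mutation). Coordinates are 1-based and
inclusive on both ends (the COSMIC convention), an overlap needs at least
one shared base on the same chromosome, and strand is ignored. Peptide
identity is the exact sequence string (isoleucine and leucine are *not*
merged): the files join on sequence text, so the graph does too. Motifs
join to clustered peptides on sample alone, because the clustering file
carries no group column.

The instance store uses RDF set semantics (duplicate assertions collapse
silently — the same peptide legitimately arrives from several files),
never emits blank nodes, and canonicalizes literal lexical forms
(shortest-round-trip decimals, unpadded integers), so sorted N-Triples
output is byte-identical across runs and round trips reduce to set
equality. In-memory provenance is not serialized; round-trip equality is
defined over individuals and assertions.

## Competency questions

Each of the fifteen questions is formalized as a basic graph pattern plus
a projection, and answered along two genuinely independent routes: a
hand-written sequential-join evaluator over the store's indexes, and a
SPARQL 1.1 SELECT generated from the same pattern and executed by rdflib.
CQ8's "shared across at least 10 non-disease-free samples" becomes
`GROUP BY` / `HAVING COUNT(DISTINCT sample) >= 10`; non-disease-free is
operationalized as "has a `has_cancer` assertion". The composite cancer
questions (11–15) read as: samples of a cancer subclass → their peptides
→ mutations overlapping those peptides' genomic placements → the protein
/ peptide / PSM / PTM / contig linked **through the same witness
peptide**; the generated SPARQL expresses them as joins of three DISTINCT
sub-SELECTs sharing the peptide variable, which keeps every intermediate
result small regardless of how the engine orders its joins (type
constraints likewise follow the edge that binds their variable — rdflib's
planner otherwise builds cross products). Answer tuples contain labels
and literal values, never IRIs, so they are directly comparable with the
table-side oracle.

Accuracy is Jaccard similarity × 100, with two empty sets scoring 100.
This makes 100 equivalent to exact set equality ("all expected entries
and no others") while degrading proportionally when tuples are missing or
spurious; no published definition of partial credit exists, so this is
the package's own choice.

## Synthetic data and the oracle

The generator emulates a processed collection: studies with
PRIDE-style accession IDs; samples with indications drawn from the ten
cancer subclasses plus "Disease free"; gene/transcript/protein chains
with Ensembl-style IDs; an identified-peptide library whose placements
sit inside their gene's locus; PSMs per sample and strategy; open-search
PTM annotations; epitope contigs built as unions of 1–4 member peptide
placements (so each contig genuinely contains a placement); and mutations
placed inside contig intervals. Defaults: 3 studies, 16 samples, 25%
disease-free, 30 genes, 1–2 transcripts per gene, 2–4 peptides per
protein, peptide lengths uniform on 8–12 (HLA class I), 5–10 PSMs per
sample per strategy, PTM rate 0.3, 40 mutations, 8 contigs. Scores are
Normal(80, 10) truncated to [0, 100]; mass shifts come from four common
modifications (oxidation +15.9949, acetylation +42.0106, phosphorylation
+79.9663, pyro-glu −17.0265); PSWM components are uniform on [−10, 10];
amino acids are uniform over the 20 canonical letters. Sixteen samples is
the smallest default under which the 25% disease-free fraction still
leaves enough tumor samples to plant a peptide shared across ten of them,
so that the shared-peptide question has a non-empty answer; the generator
additionally plants one modified, mutation-overlapping, clustered peptide
in a tumor sample so every question has at least one witness. All sizes
are chosen for fast, fully in-memory test runs (the whole default bundle
is ~1400 individuals and ~4200 assertions).

The ground truth is computed at generation time by relational joins over
the just-generated tables — never through the graph or the query engines —
which is what makes it an independent oracle. What passing the suite
shows is therefore *structural* correctness: instancing and querying
preserve the relational content of the files exactly. What it does not
show is biophysical realism — there are no spectra, retention times,
binding-affinity models or realistic marginal distributions, and real
collections bring header variants (an alias map is accepted), missing
values and scale (millions of rows) that the in-memory store does not
target.

## Validation semantics

Checking is closed-world: an individual missing a `min 1` filler is
itself the violation — the opposite of open-world OWL entailment, and the
right behaviour for QC during instancing, where every absence traces to a
source row. Domain/range checks use the subclass closure; empty sets mean
unconstrained; cardinality is counted only on individuals explicitly
typed by the restricted class or a subclass; disjointness is inherited to
subclasses. The injection harness plants seeded corruptions such that
each planned entry yields exactly one violation of the planned kind
(e.g. extra fillers for a max-cardinality overflow are typed to satisfy
the property's range), so validator completeness is measurable as recall
of the manifest. The core schema ships with participation (`some`)
restrictions only; no exactly-one-placement constraint is assumed for
genomic assignments, since multi-mapping peptides are real.

## Known limitations

- No DL reasoning or SHACL: the validator localizes row-level problems
  and checks one DL profile rule; it does not compute entailments.
- The core schema is a 38-class subset; conformance statistics for the
  full published ontology are only available by loading that document.
- Cross-references to external ontologies are representable as
  annotations but never computed.
- The SPARQL route depends on rdflib's evaluator; queries are generated
  in a shape that avoids its planner's cross products, but other engines
  may prefer different formulations.
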