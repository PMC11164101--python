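# impo-toolkit

An executable semantic model for **immunopeptidomics** — the study of the
peptides presented on the cell surface by HLA (human leukocyte antigen)
molecules. Processed immunopeptidomics collections arrive as a set of
loosely coupled tab-separated files: peptide-spectrum matches (PSMs) from
closed, open and de novo searches, PSWM peptide clustering with inferred
HLA alleles, an identified-peptide library with genomic placements,
COSMIC-style mutation exports, epitope-contig annotations, ID mappings and
study metadata. Answering even simple questions ("which peptides were seen
in which samples?", "which mutations fall inside presented peptides?")
requires joining several of these files by hand.

This package turns such collections into a typed knowledge graph and makes
the joins first-class:

- **schema** — the terminological layer: 38 core classes (assay /
  assay-result / assignment on the experimental side; gene, transcript,
  protein, peptide, mutation, HLA, motif, epitope contig on the biological
  side, plus ten cancer subclasses), 35 object and 29 data properties,
  participation restrictions, pairwise disjointness of top-level classes,
  and gene metamodelling by *punning* (one IRI as both class and
  individual). Includes an OWL 2 DL profile check (no cardinality
  restriction on a transitive property) and a scanner for five structural
  design pitfalls (P02 synonym classes, P10 missing disjointness, P11
  missing domain/range, P13 missing inverses, P41 missing license).
- **store** — an in-memory instance graph with per-assertion row-level
  provenance and lossless Turtle / sorted-N-Triples round trips.
- **ingest** — declarative column→entity mapping rules instancing the ten
  file roles, including materialization of genomic-interval overlaps
  (`contains_peptide`, `overlaps_mutation`; 1-based inclusive coordinates,
  one shared base suffices, strand ignored).
- **validate** — closed-world constraint checking (domain, range,
  datatype, cardinality, disjointness, dangling references) plus seeded
  violation injection for measuring validator recall.
- **query** — fifteen competency questions (CQs) formalized as graph
  patterns, answered by two independent engines (a native join evaluator
  and generated SPARQL 1.1 run by rdflib) and scored against a relational
  oracle. A query's accuracy is `100 × |obtained ∩ expected| /
  |obtained ∪ expected|`, so 100 means "every expected tuple and no
  others".
- **synthdata** — a seeded generator of referentially consistent ten-file
  bundles together with ground-truth CQ answers computed *purely by table
  joins*, independent of all graph code.

## Worked example

```sh
impo generate --seed 42 -o bundle        # ten TSVs + ground_truth/cq*.tsv
impo build --data bundle -o kg.ttl       # instance the tables
impo validate kg.ttl --report report.json
impo query kg.ttl --data bundle --report table5.tsv
```

The build step prints

```
wrote 1385 individuals, 1834 object and 2374 data assertions to kg.ttl
```

validation reports `clean: True (0 error violations)`, and the query suite
ends with

```
CQ14	expected=5	obtained=5	accuracy=100
CQ15	expected=5	obtained=5	accuracy=100
minimum accuracy: 100
```

`table5.tsv` lists one row per question — expected tuple count, obtained
tuple count, accuracy and how many of the ten files the oracle had to
consult, e.g.:

```
CQ	Expected entries	Tuples by query	Accuracy (%)	Files
1. For each sample, extract the corresponding peptides	329	329	100	3/10
8. Extract peptides that are shared across at least 10 non-disease-free samples	1	1	100	4/10
10. For each epitope contig, extract all associated mutations and their genomic coordinates	40	40	100	2/10
```

An accuracy of 100 on every row means the graph instancing preserved the
relational content of the source files exactly: each question's answer
over the graph coincides with the answer computed by joining the raw
tables. `impo query --emit-sparql DIR` exports the fifteen generated
SPARQL queries; `impo schema stats` / `impo schema lint` inspect the
terminological layer.

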