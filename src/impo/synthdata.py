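"""Seeded generator for referentially consistent ten-file bundles.

The generator emulates a processed immunopeptidomics data collection —
studies from a proteomics repository, samples with cancer indications,
gene/transcript/protein mappings, an identified-peptide library with
genomic placements, PSMs from three search strategies, PSWM clustering
with inferred HLA alleles, COSMIC-style mutations and epitope contigs —
with full referential integrity across files.  Alongside the tables it
computes the ground-truth answer to each of the fifteen competency
questions *purely by relational joins over the tables*, never touching
any graph code, so the answers can serve as an independent oracle for the
graph-side query engines.

Statistical choices (the tables themselves carry no published marginals):
peptide lengths uniform over the configured range, search scores
Normal(80, 10) truncated to [0, 100], mass shifts drawn from four common
modifications (oxidation, acetylation, phosphorylation, pyro-glu), contig
intervals as unions of 1-4 member peptide placements, PSWM components
uniform in [-10, 10], amino acids uniform over the 20 canonical letters.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .ingest import ROLE_FILENAMES, TABLE_SPECS, Table, intervals_overlap, \
    read_table
from .naming import is_disease_free, normalize_cancer_label, psm_key, ptm_key
from .results import CQ_VARIABLES, ResultSet
from .store import TABLE_ROLES

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: (mass shift, modification label) pool for open-search annotations.
MASS_SHIFTS = (
    (15.9949, "Oxidation"),
    (42.0106, "Acetylation"),
    (79.9663, "Phosphorylation"),
    (-17.0265, "Pyro-glu"),
)

DEFAULT_CANCER_POOL = (
    "Melanoma", "Leukemia", "Carcinoma", "Colon cancer", "Breast cancer",
    "Brain cancer", "Lung cancer", "Lymphoma", "Neuroblastoma",
    "Bone cancer", "Disease free",
)

#: Minimum number of distinct non-disease-free samples sharing a peptide
#: for it to count as broadly shared (competency question 8).
SHARED_PEPTIDE_THRESHOLD = 10


class ConfigError(ValueError):
    """The generator configuration is invalid or infeasible."""


class BundleError(ValueError):
    """A bundle directory is missing a role file."""


@dataclass(frozen=True)
class GenConfig:
    seed: int = 42
    n_studies: int = 3
    n_samples: int = 16
    fraction_disease_free: float = 0.25
    cancer_type_pool: tuple[str, ...] = DEFAULT_CANCER_POOL
    n_genes: int = 30
    transcripts_per_gene: tuple[int, int] = (1, 2)
    peptides_per_protein: tuple[int, int] = (2, 4)
    peptide_length_range: tuple[int, int] = (8, 12)
    psms_per_sample_per_strategy: tuple[int, int] = (5, 10)
    ptm_rate: float = 0.3
    n_mutations: int = 40
    n_contigs: int = 8
    hla_allele_pool: tuple[str, ...] = (
        "HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02", "HLA-B*57:01",
        "HLA-C*07:01")
    instrument_pool: tuple[str, ...] = ("Orbitrap", "Q-Exactive")

    def validate(self) -> None:
        for name in ("n_studies", "n_samples", "n_genes", "n_mutations",
                     "n_contigs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("fraction_disease_free", "ptm_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("transcripts_per_gene", "peptides_per_protein",
                     "peptide_length_range",
                     "psms_per_sample_per_strategy"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} must be 0 <= low <= high")
        if self.peptide_length_range[0] < 1 and self.n_genes > 0 \
                and self.peptides_per_protein[1] > 0:
            raise ConfigError("peptide length must be >= 1")
        if self.n_samples > 0 and self.n_studies == 0:
            raise ConfigError("samples require at least one study")
        peptides_possible = (
            self.n_samples > 0 and self.n_genes > 0
            and self.transcripts_per_gene[1] > 0
            and self.peptides_per_protein[1] > 0)
        if self.n_contigs > 0 and not peptides_possible:
            raise ConfigError(
                "n_contigs > 0 requires genes, samples and peptides")
        if self.n_mutations > 0 and self.n_contigs == 0:
            raise ConfigError(
                "n_mutations > 0 requires n_contigs > 0 (every mutation "
                "references a contig)")
        if (self.n_samples > 0
                and self.psms_per_sample_per_strategy[0] > 0
                and not peptides_possible):
            raise ConfigError("PSMs require an identified-peptide library")


@dataclass
class DatasetBundle:
    tables: dict[str, Table]
    ground_truth: dict[int, ResultSet] = field(default_factory=dict)
    config: GenConfig | None = None

    def table_equal(self, other: "DatasetBundle") -> bool:
        return all(self.tables[r] == other.tables[r] for r in TABLE_ROLES)


def _table(role: str, rows: list[dict]) -> Table:
    return Table(TABLE_SPECS[role], rows)


def generate_bundle(config: GenConfig | None = None, **overrides
                    ) -> DatasetBundle:
    """Generate one bundle; byte-deterministic under the seed.

    Guarantees referential integrity (every sample in any file appears in
    study_metadata, every mutation's contig exists, clustered peptides come
    from PSMs, library proteins come from the ID mappings, contig intervals
    contain their member peptide placements) and, whenever at least
    ``SHARED_PEPTIDE_THRESHOLD`` non-disease-free samples exist, plants one
    peptide shared across that many of them plus one modified, mutation-
    overlapping, clustered peptide in a cancer sample so that every
    competency question has a non-empty answer.
    """
    cfg = replace(config or GenConfig(), **overrides) if overrides \
        else (config or GenConfig())
    cfg.validate()
    rng = random.Random(cfg.seed)

    studies = [f"PXD{100000 + 13 * i:06d}" for i in range(cfg.n_studies)]

    # --- study metadata ----------------------------------------------------
    n_df = int(round(cfg.n_samples * cfg.fraction_disease_free))
    df_idx = set(rng.sample(range(cfg.n_samples), n_df)) \
        if cfg.n_samples else set()
    tumor_pool = [c for c in cfg.cancer_type_pool if not is_disease_free(c)]
    meta_rows = []
    for i in range(cfg.n_samples):
        indication = "Disease free" if i in df_idx or not tumor_pool \
            else rng.choice(tumor_pool)
        meta_rows.append({
            "cancer_type": indication,
            "sample_id": f"S{i + 1:02d}",
            "sample_type": rng.choice(("Cell culture", "Tissues")),
            "treatment": rng.choice(("Untreated", "IFN-gamma", "DAC")),
            "ms_instrument": rng.choice(cfg.instrument_pool)
            if cfg.instrument_pool else "Orbitrap",
            "study_id": studies[i % cfg.n_studies],
        })
    sample_study = {r["sample_id"]: r["study_id"] for r in meta_rows}
    non_df_samples = [r["sample_id"] for r in meta_rows
                      if not is_disease_free(r["cancer_type"])]

    # --- genes, transcripts, proteins --------------------------------------
    mapping_rows = []
    gene_locus: dict[str, tuple[str, int]] = {}
    counter = 0
    for g in range(cfg.n_genes):
        gname = f"GENE{g + 1}"
        gene_locus[gname] = (str(rng.randint(1, 22)),
                             rng.randrange(1_000_000, 100_000_000))
        for t in range(rng.randint(*cfg.transcripts_per_gene)):
            counter += 1
            mapping_rows.append({
                "gene_name": gname,
                "gene_id": f"ENSG{g + 1:011d}",
                "transcript_name": f"{gname}-T{t + 1}",
                "transcript_id": f"ENST{counter:011d}",
                "protein_id": f"ENSP{counter:011d}",
            })

    # --- identified-peptide library -----------------------------------------
    library_rows = []
    gene_placements: dict[str, list[dict]] = {}
    if cfg.n_samples > 0:
        for mrow in mapping_rows:
            chrom, gstart = gene_locus[mrow["gene_name"]]
            for _ in range(rng.randint(*cfg.peptides_per_protein)):
                length = rng.randint(*cfg.peptide_length_range)
                seq = "".join(rng.choice(AMINO_ACIDS)
                              for _ in range(length))
                pstart = gstart + rng.randrange(0, 30_000)
                prot_start = rng.randint(1, 300)
                sid = rng.choice(meta_rows)["sample_id"]
                row = {
                    "peptide_sequence": seq,
                    "start": pstart,
                    "end": pstart + 3 * length - 1,
                    "chromosome": chrom,
                    "tag": rng.choice(("canonical", "non-canonical")),
                    "ms_strategy": rng.choice(("closed", "denovo", "open")),
                    "sample_id": sid,
                    "study_id": sample_study[sid],
                    "protein_id": mrow["protein_id"],
                    "protein_start": prot_start,
                    "protein_end": prot_start + length - 1,
                    "probability": round(rng.uniform(0.5, 0.999), 3),
                }
                library_rows.append(row)
                gene_placements.setdefault(mrow["gene_name"], []).append(row)

    # --- PSMs per sample per strategy ---------------------------------------
    def score() -> float:
        return round(min(100.0, max(0.0, rng.gauss(80, 10))), 2)

    psm_rows: dict[str, list[dict]] = {"closed_search": [],
                                       "denovo_search": [],
                                       "open_search": []}
    sample_peptides: dict[str, set[str]] = {}
    for meta in meta_rows:
        sid = meta["sample_id"]
        for role, prefix in (("closed_search", "cl"), ("denovo_search", "de"),
                             ("open_search", "op")):
            k = rng.randint(*cfg.psms_per_sample_per_strategy) \
                if library_rows else 0
            for j in range(k):
                lib = rng.choice(library_rows)
                seq = lib["peptide_sequence"]
                row = {
                    "spectrum": f"{prefix}scan{j + 1}",
                    "peptide_sequence": seq,
                    "sample_id": sid,
                    "study_id": meta["study_id"],
                    "score": score(),
                }
                if role == "open_search":
                    if rng.random() < cfg.ptm_rate:
                        shift, label = rng.choice(MASS_SHIFTS)
                        pos = rng.randint(1, len(seq))
                        row.update(position=pos, mass_shift=shift,
                                   modification=f"{label} ({seq[pos - 1]}"
                                                f"{pos})",
                                   modification_type=label)
                    else:
                        row.update(position=None, mass_shift=None,
                                   modification=None, modification_type=None)
                psm_rows[role].append(row)
                sample_peptides.setdefault(sid, set()).add(seq)

    # --- planted witnesses --------------------------------------------------
    hero = library_rows[0] if library_rows else None
    hero_seq = hero["peptide_sequence"] if hero else None
    if hero and len(non_df_samples) >= SHARED_PEPTIDE_THRESHOLD:
        for sid in non_df_samples[:SHARED_PEPTIDE_THRESHOLD]:
            psm_rows["closed_search"].append({
                "spectrum": "clplant1",
                "peptide_sequence": hero_seq,
                "sample_id": sid,
                "study_id": sample_study[sid],
                "score": score(),
            })
            sample_peptides.setdefault(sid, set()).add(hero_seq)
    if hero and non_df_samples:
        sid = non_df_samples[0]
        shift, label = MASS_SHIFTS[0]
        psm_rows["open_search"].append({
            "spectrum": "opplant1",
            "peptide_sequence": hero_seq,
            "sample_id": sid,
            "study_id": sample_study[sid],
            "score": score(),
            "position": 1,
            "mass_shift": shift,
            "modification": f"{label} ({hero_seq[0]}1)",
            "modification_type": label,
        })
        sample_peptides.setdefault(sid, set()).add(hero_seq)

    # --- epitope contigs (unions of member peptide placements) ---------------
    contig_rows = []
    genes_with_peps = sorted(gene_placements)
    for j in range(cfg.n_contigs):
        if j == 0 and hero is not None:
            gname = next(g for g, rows in gene_placements.items()
                         if hero in rows)
            members = [hero] + rng.sample(
                gene_placements[gname],
                min(len(gene_placements[gname]) - 0, rng.randint(1, 4)) - 1)
        else:
            gname = rng.choice(genes_with_peps)
            members = rng.sample(
                gene_placements[gname],
                min(len(gene_placements[gname]), rng.randint(1, 4)))
        contig_rows.append({
            "contig_id": f"EC{j + 1:04d}",
            "chromosome": gene_locus[gname][0],
            "strand": rng.choice("+-"),
            "start": min(m["start"] for m in members),
            "end": max(m["end"] for m in members),
            "gene_mutational_ratio": round(rng.uniform(0, 1), 4),
            "population_coverage": round(rng.uniform(0, 1), 4),
            "overlap_score": round(rng.uniform(0, 1), 4),
            "expression": round(rng.uniform(0, 500), 2),
            "immune_score": round(rng.uniform(0, 10), 3),
        })

    # --- mutations (placed inside contig intervals) ---------------------------
    mutation_rows = []
    for m in range(cfg.n_mutations):
        if m == 0 and hero is not None:
            contig = contig_rows[0]
            start = hero["start"] + 1
            end = min(start + 2, hero["end"])
        else:
            contig = rng.choice(contig_rows)
            start = rng.randint(contig["start"], contig["end"])
            end = min(start + rng.choice((0, 0, 0, 2)), contig["end"])
        mutation_rows.append({
            "mutation_id": f"COSV{86000000 + m}",
            "chromosome": contig["chromosome"],
            "strand": rng.choice("+-"),
            "start": start,
            "end": end,
            "contig": contig["contig_id"],
        })

    # --- clustering + PSWM annotation ----------------------------------------
    cluster_rows, pswm_rows = [], []
    hero_cluster_sample = non_df_samples[0] if (hero and non_df_samples) \
        else None
    for meta in meta_rows:
        sid = meta["sample_id"]
        peps = sorted(sample_peptides.get(sid, ()))
        if not peps:
            continue
        chosen = set(rng.sample(peps, min(5, len(peps))))
        if sid == hero_cluster_sample:
            chosen.add(hero_seq)
        for seq in sorted(chosen):
            cluster_rows.append({"peptide_sequence": seq, "sample_id": sid})
        pswm_rows.append({
            "component_1": round(rng.uniform(-10, 10), 3),
            "component_2": round(rng.uniform(-10, 10), 3),
            "pswm_group": "G1",
            "inferred_allele": rng.choice(cfg.hla_allele_pool)
            if cfg.hla_allele_pool else "HLA-A*02:01",
            "sample_id": sid,
        })

    bundle = DatasetBundle(tables={
        "peptide_clusters": _table("peptide_clusters", cluster_rows),
        "pswm_annotation": _table("pswm_annotation", pswm_rows),
        "closed_search": _table("closed_search", psm_rows["closed_search"]),
        "denovo_search": _table("denovo_search", psm_rows["denovo_search"]),
        "open_search": _table("open_search", psm_rows["open_search"]),
        "mutations": _table("mutations", mutation_rows),
        "epitope_contigs": _table("epitope_contigs", contig_rows),
        "peptide_library": _table("peptide_library", library_rows),
        "id_mappings": _table("id_mappings", mapping_rows),
        "study_metadata": _table("study_metadata", meta_rows),
    }, config=cfg)
    bundle.ground_truth = {cq: oracle_answers(bundle, cq)
                           for cq in range(1, 16)}
    return bundle


# ---------------------------------------------------------------------------
# Integrity checking

def check_bundle_integrity(bundle: DatasetBundle) -> list[str]:
    """Return referential-integrity problems (empty when consistent)."""
    t = bundle.tables
    problems: list[str] = []
    known_samples = {r["sample_id"] for r in t["study_metadata"].rows}
    for role in ("peptide_clusters", "pswm_annotation", "closed_search",
                 "denovo_search", "open_search", "peptide_library"):
        for r in t[role].rows:
            if r["sample_id"] not in known_samples:
                problems.append(f"{role}: unknown sample {r['sample_id']}")
    contig_ids = {r["contig_id"] for r in t["epitope_contigs"].rows}
    for r in t["mutations"].rows:
        if r["contig"] not in contig_ids:
            problems.append(f"mutations: unknown contig {r['contig']}")
    psm_seqs = {r["peptide_sequence"]
                for role in ("closed_search", "denovo_search", "open_search")
                for r in t[role].rows}
    for r in t["peptide_clusters"].rows:
        if r["peptide_sequence"] not in psm_seqs:
            problems.append(
                f"peptide_clusters: {r['peptide_sequence']} not in any PSM "
                "file")
    protein_ids = {r["protein_id"] for r in t["id_mappings"].rows}
    for r in t["peptide_library"].rows:
        if r["protein_id"] is not None and r["protein_id"] not in protein_ids:
            problems.append(
                f"peptide_library: unknown protein {r['protein_id']}")
    for c in t["epitope_contigs"].rows:
        contained = any(
            lib["chromosome"] == c["chromosome"]
            and c["start"] <= lib["start"] and lib["end"] <= c["end"]
            for lib in t["peptide_library"].rows)
        if not contained:
            problems.append(
                f"epitope_contigs: {c['contig_id']} contains no member "
                "peptide interval")
    return problems


# ---------------------------------------------------------------------------
# Bundle I/O

def write_bundle(bundle: DatasetBundle, directory) -> None:
    from .ingest import write_table
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for role, fname in ROLE_FILENAMES.items():
        write_table(bundle.tables[role], d / fname)
    gt_dir = d / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    for cq, rs in sorted(bundle.ground_truth.items()):
        (gt_dir / f"cq{cq}.tsv").write_text(rs.to_tsv(), encoding="utf-8")


def read_bundle(directory) -> DatasetBundle:
    """Read a bundle directory; ground truth is recomputed from the tables."""
    d = Path(directory)
    tables = {}
    for role, fname in ROLE_FILENAMES.items():
        path = d / fname
        if not path.exists():
            raise BundleError(f"missing file for role {role!r}: {fname}")
        tables[role] = read_table(path, TABLE_SPECS[role])
    bundle = DatasetBundle(tables=tables)
    bundle.ground_truth = {cq: oracle_answers(bundle, cq)
                           for cq in range(1, 16)}
    return bundle


# ---------------------------------------------------------------------------
# Relational oracle: competency-question answers straight from the tables.
# These joins never touch the graph or the query engines.

def _psm_records(bundle: DatasetBundle) -> list[tuple[str, dict]]:
    return [(strategy, r)
            for role, strategy in (("closed_search", "closed"),
                                   ("denovo_search", "denovo"),
                                   ("open_search", "open"))
            for r in bundle.tables[role].rows]


def _sample_peptide_pairs(bundle: DatasetBundle) -> set[tuple[str, str]]:
    return {(r["sample_id"], r["peptide_sequence"])
            for _, r in _psm_records(bundle)}


def _contig_peptide_pairs(bundle: DatasetBundle) -> set[tuple[str, str]]:
    pairs = set()
    for c in bundle.tables["epitope_contigs"].rows:
        for lib in bundle.tables["peptide_library"].rows:
            if intervals_overlap(c["chromosome"], c["start"], c["end"],
                                 lib["chromosome"], lib["start"], lib["end"]):
                pairs.add((c["contig_id"], lib["peptide_sequence"]))
    return pairs


def _peptide_mutation_rows(bundle: DatasetBundle) -> set[tuple]:
    out = set()
    for lib in bundle.tables["peptide_library"].rows:
        for m in bundle.tables["mutations"].rows:
            if intervals_overlap(lib["chromosome"], lib["start"], lib["end"],
                                 m["chromosome"], m["start"], m["end"]):
                out.add((lib["peptide_sequence"], m["mutation_id"],
                         m["chromosome"], m["start"], m["end"]))
    return out


def _ptm_rows(bundle: DatasetBundle) -> set[tuple[str, str, int]]:
    return {
        (ptm_key(r["modification_type"], r["peptide_sequence"],
                 r["position"]),
         r["peptide_sequence"], r["position"])
        for r in bundle.tables["open_search"].rows
        if r["modification_type"] is not None and r["position"] is not None
    }


def _cancer_mutation_peptide(bundle: DatasetBundle) -> set[tuple]:
    """(cancer label, mutation id, witness peptide) triples."""
    sample_cancer = {
        r["sample_id"]: normalize_cancer_label(r["cancer_type"])
        for r in bundle.tables["study_metadata"].rows
        if not is_disease_free(r["cancer_type"])}
    pep_mut = {(seq, mid) for seq, mid, *_ in _peptide_mutation_rows(bundle)}
    out = set()
    for sid, seq in _sample_peptide_pairs(bundle):
        cancer = sample_cancer.get(sid)
        if cancer is None:
            continue
        for pseq, mid in pep_mut:
            if pseq == seq:
                out.add((cancer, mid, seq))
    return out


def oracle_answers(bundle: DatasetBundle, cq_id: int) -> ResultSet:
    """Ground-truth answer to one competency question, from tables alone."""
    if cq_id not in CQ_VARIABLES:
        raise KeyError(f"unknown competency question id {cq_id}")
    t = bundle.tables
    variables = CQ_VARIABLES[cq_id]

    if cq_id == 1:
        tuples = _sample_peptide_pairs(bundle)
    elif cq_id == 2:
        pswm = pd.DataFrame(t["pswm_annotation"].rows,
                            columns=TABLE_SPECS["pswm_annotation"]
                            .required_columns)
        clusters = pd.DataFrame(t["peptide_clusters"].rows,
                                columns=TABLE_SPECS["peptide_clusters"]
                                .required_columns)
        merged = pswm.merge(clusters, on="sample_id")
        tuples = {(r.inferred_allele, r.peptide_sequence)
                  for r in merged.itertuples()}
    elif cq_id == 3:
        tuples = _contig_peptide_pairs(bundle)
    elif cq_id == 4:
        tuples = {(r["sample_id"], r["ms_instrument"])
                  for r in t["study_metadata"].rows}
    elif cq_id == 5:
        tuples = {(r["protein_id"], r["peptide_sequence"])
                  for r in t["peptide_library"].rows
                  if r["protein_id"] is not None}
    elif cq_id == 6:
        prot_gene = {r["protein_id"]: r["gene_name"]
                     for r in t["id_mappings"].rows}
        tuples = {(prot_gene[r["protein_id"]], r["peptide_sequence"])
                  for r in t["peptide_library"].rows
                  if r["protein_id"] in prot_gene}
    elif cq_id == 7:
        tuples = _ptm_rows(bundle)
    elif cq_id == 8:
        non_df = {r["sample_id"] for r in t["study_metadata"].rows
                  if not is_disease_free(r["cancer_type"])}
        counts: dict[str, set[str]] = {}
        for sid, seq in _sample_peptide_pairs(bundle):
            if sid in non_df:
                counts.setdefault(seq, set()).add(sid)
        tuples = {(seq,) for seq, sids in counts.items()
                  if len(sids) >= SHARED_PEPTIDE_THRESHOLD}
    elif cq_id == 9:
        tuples = _peptide_mutation_rows(bundle)
    elif cq_id == 10:
        contigs = {c["contig_id"] for c in t["epitope_contigs"].rows}
        tuples = {(m["contig"], m["mutation_id"], m["chromosome"],
                   m["start"], m["end"])
                  for m in t["mutations"].rows if m["contig"] in contigs}
    elif cq_id in (11, 12, 13, 14, 15):
        base = _cancer_mutation_peptide(bundle)
        if cq_id == 11:
            by_pep: dict[str, set[str]] = {}
            for r in t["peptide_library"].rows:
                if r["protein_id"] is not None:
                    by_pep.setdefault(r["peptide_sequence"], set()).add(
                        r["protein_id"])
            tuples = {(c, mid, prot) for c, mid, seq in base
                      for prot in by_pep.get(seq, ())}
        elif cq_id == 12:
            tuples = {(c, mid, seq) for c, mid, seq in base}
        elif cq_id == 13:
            by_pep = {}
            for strategy, r in _psm_records(bundle):
                by_pep.setdefault(r["peptide_sequence"], set()).add(
                    psm_key(strategy, r["sample_id"], r["spectrum"],
                            r["peptide_sequence"]))
            tuples = {(c, mid, key) for c, mid, seq in base
                      for key in by_pep.get(seq, ())}
        elif cq_id == 14:
            by_pep = {}
            for key, seq, _pos in _ptm_rows(bundle):
                by_pep.setdefault(seq, set()).add(key)
            tuples = {(c, mid, key) for c, mid, seq in base
                      for key in by_pep.get(seq, ())}
        else:
            by_pep = {}
            for cid, seq in _contig_peptide_pairs(bundle):
                by_pep.setdefault(seq, set()).add(cid)
            tuples = {(c, mid, cid) for c, mid, seq in base
                      for cid in by_pep.get(seq, ())}
    return ResultSet(variables, frozenset(tuples))
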