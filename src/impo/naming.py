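"""IRI minting and naming conventions.

All schema entities use human-readable snake_case local names (the label with
spaces replaced by underscores) under the schema namespace; instance-level
individuals live under a separate instance namespace.  Natural keys from the
source tables (sample IDs, peptide sequences, HLA alleles, ...) are embedded
in the local names so that instance IRIs are deterministic and stable.
"""

from __future__ import annotations

import re

#: Default base namespace of the semantic model (terminological layer).
SCHEMA_NS = "https://w3id.org/impo#"
#: Default namespace for data-level individuals.
INSTANCE_NS = "https://w3id.org/impo/instance/"

_SLUG_RE = re.compile(r"[^A-Za-z0-9_]+")


def slug(text: str) -> str:
    """Turn an arbitrary natural key into an IRI-safe local-name fragment.

    Case is preserved (peptide sequences are case-sensitive identifiers);
    every run of non-alphanumeric characters collapses to one underscore.
    """
    s = _SLUG_RE.sub("_", str(text).strip())
    return s.strip("_")


def class_iri(local: str, ns: str = SCHEMA_NS) -> str:
    return ns + local


def instance_iri(local: str, ns: str = INSTANCE_NS) -> str:
    return ns + slug(local)


def label_to_local(label: str) -> str:
    """Naming convention: local name = label with spaces as underscores."""
    return label.replace(" ", "_")


def local_name(iri: str) -> str:
    """Fragment after the last '#' or '/'."""
    for sep in ("#", "/"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri


# ---------------------------------------------------------------------------
# Natural-key builders shared by the instancing rules and the relational
# oracle.  These are pure string formatters: both code paths must agree on
# how a row names the entity it gives rise to, while computing *which* rows
# relate entirely independently.

def psm_key(strategy: str, sample_id: str, spectrum: str, sequence: str) -> str:
    return f"{strategy}_{sample_id}_{spectrum}_{sequence}"


def ptm_key(modification_type: str, sequence: str, position: int) -> str:
    return f"{modification_type}_{sequence}_pos{position}"


def motif_key(sample_id: str, pswm_group: str) -> str:
    return f"{sample_id}_{pswm_group}"


def placement_key(sequence: str, chromosome: str, start: int, end: int) -> str:
    return f"{sequence}_{chromosome}_{start}_{end}"


def protein_assignment_key(sequence: str, protein_id: str) -> str:
    return f"{sequence}_{protein_id}"


def normalize_cancer_label(indication: str) -> str:
    """Normalize a study-metadata indication to a cancer-subclass label."""
    return str(indication).strip().lower()


def is_disease_free(indication: str) -> bool:
    return normalize_cancer_label(indication) == "disease free"
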