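"""Answer sets for competency questions.

A :class:`ResultSet` is an order-insensitive set of tuples together with
the variable names defining the tuple schema.  Both the graph-side query
engines and the table-side relational oracle produce ResultSets, which is
what makes them directly comparable.

Tuple elements are natural keys (sample IDs, peptide sequences, HLA
alleles, mutation IDs, ...) or literal values (positions as ints), never
IRIs — entity identity in answers is by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Normative variable schema (tuple arity and meaning) per question id.
CQ_VARIABLES: dict[int, tuple[str, ...]] = {
    1: ("sample", "peptide"),
    2: ("hla", "peptide"),
    3: ("contig", "peptide"),
    4: ("sample", "instrument"),
    5: ("protein", "peptide"),
    6: ("gene", "peptide"),
    7: ("ptm", "peptide", "position"),
    8: ("peptide",),
    9: ("peptide", "mutation", "chromosome", "start", "end"),
    10: ("contig", "mutation", "chromosome", "start", "end"),
    11: ("cancer", "mutation", "protein"),
    12: ("cancer", "mutation", "peptide"),
    13: ("cancer", "mutation", "psm"),
    14: ("cancer", "mutation", "ptm"),
    15: ("cancer", "mutation", "contig"),
}


@dataclass
class ResultSet:
    variables: tuple[str, ...]
    tuples: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.tuples = frozenset(tuple(t) for t in self.tuples)
        arity = len(self.variables)
        for t in self.tuples:
            if len(t) != arity:
                raise ValueError(
                    f"tuple arity {len(t)} != schema arity {arity}")

    def __len__(self) -> int:
        return len(self.tuples)

    def __iter__(self):
        return iter(self.tuples)

    def __contains__(self, t) -> bool:
        return tuple(t) in self.tuples

    def __eq__(self, other) -> bool:
        return (isinstance(other, ResultSet)
                and self.variables == other.variables
                and self.tuples == other.tuples)

    def sorted_rows(self) -> list[tuple]:
        return sorted(self.tuples, key=lambda t: tuple(map(str, t)))

    def to_tsv(self) -> str:
        lines = ["\t".join(self.variables)]
        for t in self.sorted_rows():
            lines.append("\t".join(str(v) for v in t))
        return "\n".join(lines) + "\n"
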