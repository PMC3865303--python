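"""Standard nuclear genetic code, wrapped for codon-level statistics.

The table itself comes from biopython; this module pins the conventions the
rest of the package relies on: uppercase DNA codons, ``*`` for stop, and the
invariant of exactly 61 sense codons + 3 stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
#: transitions are A<->G and C<->T; everything else is a transversion
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    return a != b and ({a, b} <= PURINES or {a, b} <= PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid map plus the stop-codon set."""

    forward: dict[str, str]
    stops: frozenset[str]
    sense_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if len(self.forward) + len(self.stops) != 64:
            raise ValueError("genetic code must cover all 64 codons")
        object.__setattr__(
            self, "sense_codons", tuple(sorted(self.forward))
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        return cls(
            forward=dict(table.forward_table),
            stops=frozenset(table.stop_codons),
        )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def translate(self, codon: str) -> str:
        """Amino acid for a sense codon, ``*`` for a stop."""
        if codon in self.stops:
            return "*"
        return self.forward[codon]

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        """True when both codons are sense and encode the same amino acid."""
        if codon_a in self.stops or codon_b in self.stops:
            return False
        return self.forward[codon_a] == self.forward[codon_b]


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    return GeneticCode.standard()


def all_codons() -> list[str]:
    return [a + b + c for a in BASES for b in BASES for c in BASES]
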