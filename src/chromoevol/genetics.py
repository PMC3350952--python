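"""Genetic-code tables and codon indexing.

Everything downstream of the codon substitution models works in the index
space of the 61 sense codons of the standard nuclear code; this module owns
that mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, eq=False)  # identity hash: safe with lru_cache
class GeneticCode:
    """A codon -> amino-acid table plus the ordered list of sense codons.

    ``sense_codons`` is sorted alphabetically, which fixes the 0-60 index
    convention used by the rate matrices, the simulator and
    :class:`~chromoevol.io.CodonAlignment`.
    """

    name: str
    table: dict  # codon -> one-letter amino acid, stops mapped to "*"
    stop_codons: tuple
    sense_codons: tuple

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError("genetic code must cover all 64 codons")
        if len(self.sense_codons) != len(self.table) - len(self.stop_codons):
            raise ValueError("sense codon count inconsistent with stops")

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        """0-based index of a sense codon; raises for stops/ambiguity."""
        return self._index_map()[codon.upper()]

    @lru_cache(maxsize=None)
    def _index_map(self):
        return {c: i for i, c in enumerate(self.sense_codons)}

    def codon(self, index: int) -> str:
        return self.sense_codons[index]

    def aa(self, codon: str) -> str:
        return self.table[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def translate(self, cds: str) -> str:
        """Translate an in-frame CDS; internal stops become '*'."""
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        cds = cds.upper()
        return "".join(self.table.get(cds[i:i + 3], "X")
                       for i in range(0, len(cds), 3))


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI table 1)."""
    bio = unambiguous_dna_by_id[1]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = "*"
    # fill any codon Biopython leaves implicit (none for table 1, but keep
    # the hook honest for other tables)
    codons = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES
              for c in NUCLEOTIDES]
    sense = tuple(c for c in codons if table[c] != "*")
    return GeneticCode(
        name="standard",
        table={c: table[c] for c in codons},
        stop_codons=tuple(sorted(bio.stop_codons)),
        sense_codons=sense,
    )


def is_transition(a: str, b: str) -> bool:
    """True when the nucleotide change a<->b is a transition (A<->G, C<->T)."""
    return a != b and ({a, b} <= PURINES or {a, b} <= PYRIMIDINES)
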