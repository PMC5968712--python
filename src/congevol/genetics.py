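"""Genetic codes, coding sequences, and codon-level primitives.

Everything downstream (site counting, codon substitution models, the
simulator) works on the 61 sense codons of a genetic code; this module owns
the codon <-> index bookkeeping so that the rest of the package can treat a
codon as a small integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterator

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
STOP = "*"

#: Purine/pyrimidine classes used to distinguish transitions from
#: transversions.
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product(NUCLEOTIDES, repeat=3)
)


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated (e.g. internal stop codon)."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table over the 64 DNA codons.

    Parameters
    ----------
    table_id : int
        NCBI translation-table number (1 = standard).
    codon_to_aa : dict
        Maps each of the 64 codons to a one-letter amino acid or ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must cover all 64 codons, got {len(self.codon_to_aa)}"
            )

    @classmethod
    def from_ncbi(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: STOP for c in table.stop_codons}
        mapping.update(table.forward_table)
        # Biopython keys are uppercase DNA codons already.
        full = {codon: mapping[codon] for codon in ALL_CODONS}
        return cls(table_id=table_id, codon_to_aa=full)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The codons that encode an amino acid, in TCAG lexical order."""
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[codon]


@lru_cache(maxsize=8)
def standard_code(table_id: int = 1) -> GeneticCode:
    """The (cached) NCBI genetic code; table 1 is the plant-nuclear default."""
    return GeneticCode.from_ncbi(table_id)


def codon_index(code: GeneticCode) -> dict[str, int]:
    """Map each sense codon to its index in ``code.sense_codons``."""
    return {c: i for i, c in enumerate(code.sense_codons)}


def is_transition(a: str, b: str) -> bool:
    """True when nucleotides a, b are both purines or both pyrimidines."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


@dataclass(frozen=True)
class CodingSequence:
    """A stop-free coding nucleotide sequence whose length is a multiple of 3."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if len(self.nucleotides) % 3 != 0:
            raise ValueError(
                f"{self.id}: CDS length {len(self.nucleotides)} not divisible by 3"
            )
        bad = set(self.nucleotides) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: invalid nucleotides {sorted(bad)}")

    def codons(self) -> Iterator[str]:
        s = self.nucleotides
        for i in range(0, len(s), 3):
            yield s[i : i + 3]

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the 20-letter alphabet plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def translate(cds: CodingSequence, code: GeneticCode | None = None) -> ProteinSequence:
    """Translate a CDS, one residue per codon.

    Codons containing N (or any ambiguity) translate to X.  An internal or
    terminal stop codon is an error that names the offending codon index
    (0-based); trim terminal stops before translating.
    """
    if code is None:
        code = standard_code()
    residues = []
    for i, codon in enumerate(cds.codons()):
        if "N" in codon:
            residues.append("X")
            continue
        aa = code.aa(codon)
        if aa == STOP:
            raise TranslationError(
                f"{cds.id}: stop codon {codon} at codon index {i}"
            )
        residues.append(aa)
    return ProteinSequence(id=cds.id, residues="".join(residues))
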