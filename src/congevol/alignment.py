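"""Codon alignments: gapped, codon-structured nucleotide alignments."""

from __future__ import annotations

from dataclasses import dataclass

from .genetics import GeneticCode, standard_code

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length gapped coding sequences with gaps on codon boundaries.

    Rows are nucleotide strings over {A,C,G,T,N,-}; every gap run has length
    a multiple of 3 and starts on a codon boundary, so column *c* of the
    codon view is nucleotides ``3c .. 3c+3`` of every row.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        for sid, row in zip(self.ids, self.rows):
            for i in range(0, length, 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"{sid}: partial gap codon {codon!r} at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon_column(self, c: int) -> tuple[str, ...]:
        return tuple(row[3 * c : 3 * c + 3] for row in self.rows)

    def codon_row(self, sid: str) -> list[str]:
        row = self.rows[self.ids.index(sid)]
        return [row[i : i + 3] for i in range(0, len(row), 3)]

    def ungapped(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)].replace("-", "")

    def clean(self, code: GeneticCode | None = None) -> "CodonAlignment":
        """Drop codon columns containing a gap or an ambiguous/stop codon.

        Complete-deletion filtering: only columns where every row holds an
        unambiguous sense codon survive, which is what the substitution
        counters and likelihood machinery require.
        """
        if code is None:
            code = standard_code()
        sense = set(code.sense_codons)
        kept: list[int] = []
        for c in range(self.n_codons):
            if all(codon in sense for codon in self.codon_column(c)):
                kept.append(c)
        rows = tuple(
            "".join(row[3 * c : 3 * c + 3] for c in kept) for row in self.rows
        )
        return CodonAlignment(ids=self.ids, rows=rows)

    def subset(self, ids: list[str]) -> "CodonAlignment":
        rows = tuple(self.rows[self.ids.index(i)] for i in ids)
        return CodonAlignment(ids=tuple(ids), rows=rows)
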