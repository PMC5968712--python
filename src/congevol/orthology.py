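"""Ortholog identification and protein-guided codon alignment.

Orthologs between two species are called by reciprocal best hits (RBH):
gene x pairs with gene y iff y is x's unique best-scoring match and vice
versa.  Scores come either from a user-supplied BLAST tabular hit table or
from the internal global protein aligner (Needleman–Wunsch with BLOSUM62
and affine gaps), which removes any external-binary dependency at desk
scale.  Single-copy groups across k species are RBH cliques.  Codon
alignments are built by aligning the proteins and expanding each residue
column to its source codon (a residue gap becomes ``---``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .alignment import GAP_CODON, CodonAlignment
from .genetics import (
    CodingSequence,
    GeneticCode,
    ProteinSequence,
    standard_code,
    translate,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    a: str
    b: str
    score: float
    pident: float


def make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_proteins_global(
    a: ProteinSequence,
    b: ProteinSequence,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins.

    Returns the two gapped rows and the alignment score (symmetric in
    argument order).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty protein sequence")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    return str(best[0]), str(best[1]), float(best.score)


def _percent_identity(row_a: str, row_b: str) -> float:
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-"
    )
    aligned = sum(
        1 for x, y in zip(row_a, row_b) if x != "-" and y != "-"
    )
    return 100.0 * matches / aligned if aligned else 0.0


def score_all_pairs(
    proteome_a: list[ProteinSequence],
    proteome_b: list[ProteinSequence],
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """All-vs-all alignment scores as a hit table (query, subject, bitscore,
    pident); symmetric scoring stands in for a reciprocal BLAST search."""
    if aligner is None:
        aligner = make_aligner()
    records = []
    for pa in proteome_a:
        for pb in proteome_b:
            row_a, row_b, score = align_proteins_global(pa, pb, aligner)
            records.append(
                {
                    "query": pa.id,
                    "subject": pb.id,
                    "bitscore": score,
                    "pident": _percent_identity(row_a, row_b),
                }
            )
    return pd.DataFrame(records)


def _best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Unique best subject per query; ties exclude the query entirely."""
    best: dict[str, str] = {}
    for query, group in hits.groupby("query"):
        top = group["bitscore"].max()
        winners = group.loc[group["bitscore"] == top, "subject"].tolist()
        if len(winners) == 1:
            best[str(query)] = str(winners[0])
        else:
            logger.warning(
                "query %s has %d tied best hits; excluded from RBH",
                query, len(winners),
            )
    return best


def rbh_pairs(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame | None = None
) -> list[OrthologPair]:
    """Reciprocal best hits from hit tables.

    ``hits_ab`` scores species-A queries against species-B subjects; if
    ``hits_ba`` is omitted the same table is used symmetrically (an
    internal symmetric scorer covers both directions).
    """
    if hits_ba is None:
        hits_ba = hits_ab.rename(
            columns={"query": "subject", "subject": "query"}
        )
    fwd = _best_hits(hits_ab)
    rev = _best_hits(hits_ba)
    lookup = hits_ab.set_index(["query", "subject"])
    pairs = []
    for a, b in sorted(fwd.items()):
        if rev.get(b) == a:
            row = lookup.loc[(a, b)]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            pident = float(row["pident"]) if "pident" in row else float("nan")
            pairs.append(
                OrthologPair(a=a, b=b, score=float(row["bitscore"]), pident=pident)
            )
    return pairs


def filter_hits(
    hits: pd.DataFrame,
    max_evalue: float | None = None,
    min_bitscore: float | None = None,
) -> pd.DataFrame:
    if max_evalue is not None and "evalue" in hits:
        hits = hits[hits["evalue"] <= max_evalue]
    if min_bitscore is not None:
        hits = hits[hits["bitscore"] >= min_bitscore]
    return hits.reset_index(drop=True)


def single_copy_groups(
    pairwise: dict[tuple[str, str], list[OrthologPair]],
    species: list[str],
) -> list[dict[str, str]]:
    """RBH cliques of size k: one gene per species, every cross pair RBH.

    ``pairwise[(sp_a, sp_b)]`` holds the RBH pairs with a-genes from sp_a.
    Each gene appears in at most one group (RBH uniqueness guarantees it).
    """
    maps: dict[tuple[str, str], dict[str, str]] = {}
    for (sa, sb), pairs in pairwise.items():
        maps[(sa, sb)] = {p.a: p.b for p in pairs}
        maps[(sb, sa)] = {p.b: p.a for p in pairs}
    for sa, sb in combinations(species, 2):
        if (sa, sb) not in maps:
            raise ValueError(f"missing RBH set for ({sa}, {sb})")
    anchor = species[0]
    groups = []
    for gene in sorted(maps[(anchor, species[1])]):
        member = {anchor: gene}
        ok = True
        for sp in species[1:]:
            partner = maps[(anchor, sp)].get(gene)
            if partner is None:
                ok = False
                break
            member[sp] = partner
        if not ok:
            continue
        for sa, sb in combinations(species[1:], 2):
            if maps[(sa, sb)].get(member[sa]) != member[sb]:
                ok = False
                break
        if ok:
            groups.append(member)
    return groups


def backtranslate_alignment(
    protein_rows: dict[str, str],
    cds: dict[str, CodingSequence],
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Expand a gapped protein alignment to a codon alignment.

    Each sequence's CDS must translate exactly to its ungapped protein row;
    a mismatch is an error naming the sequence and residue index.
    """
    if code is None:
        code = standard_code()
    ids = tuple(protein_rows)
    lengths = {len(r) for r in protein_rows.values()}
    if len(lengths) != 1:
        raise ValueError("protein rows have unequal lengths")
    rows = []
    for sid in ids:
        prot_row = protein_rows[sid]
        seq = cds[sid]
        translated = translate(seq, code).residues
        ungapped = prot_row.replace("-", "")
        if len(translated) != len(ungapped):
            raise ValueError(
                f"{sid}: CDS translates to {len(translated)} residues, "
                f"protein row has {len(ungapped)}"
            )
        codons = list(seq.codons())
        out = []
        k = 0
        for pos, residue in enumerate(prot_row):
            if residue == "-":
                out.append(GAP_CODON)
                continue
            if translated[k] != residue:
                raise ValueError(
                    f"{sid}: translation mismatch at residue {k} "
                    f"({translated[k]!r} != {residue!r})"
                )
            out.append(codons[k])
            k += 1
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=tuple(rows))


def build_codon_alignment(
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    code: GeneticCode | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> CodonAlignment:
    """Protein-guided codon alignment of one ortholog pair."""
    if code is None:
        code = standard_code()
    pa, pb = translate(cds_a, code), translate(cds_b, code)
    row_a, row_b, _ = align_proteins_global(pa, pb, aligner)
    return backtranslate_alignment(
        {cds_a.id: row_a, cds_b.id: row_b},
        {cds_a.id: cds_a, cds_b.id: cds_b},
        code,
    )
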