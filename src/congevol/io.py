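"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Bio.SeqIO; tabular formats (two-column gene->category
annotations, gene x sample count matrices, BLAST tabular hits) go through
pandas.  All readers validate and fail loudly with line context; all
reader/writer pairs round-trip on simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs; duplicate ids error."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


@dataclass
class AnnotationTable:
    """Gene id -> set of functional category ids (GO terms, pathways)."""

    gene_to_categories: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_to_categories = {
            g: frozenset(cats)
            for g, cats in self.gene_to_categories.items()
            if cats
        }

    def categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.gene_to_categories.values():
            out |= cats
        return out

    def genes_in(self, category: str) -> set[str]:
        return {
            g
            for g, cats in self.gene_to_categories.items()
            if category in cats
        }

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cats in self.gene_to_categories.values():
            for c in cats:
                sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def __len__(self) -> int:
        return len(self.gene_to_categories)


def read_annotation_tsv(path) -> AnnotationTable:
    """Two-column (gene, category) TSV, one pair per line."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'gene<TAB>category', got {line!r}"
                )
            mapping.setdefault(parts[0], set()).add(parts[1])
    return AnnotationTable(gene_to_categories=mapping)


def write_annotation_tsv(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table.gene_to_categories):
            for cat in sorted(table.gene_to_categories[gene]):
                fh.write(f"{gene}\t{cat}\n")


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample library sizes.

    Library sizes default to column sums, the convention used when counts
    come straight from a read counter.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not (self.counts.values == self.counts.values.astype(int)).all():
            raise ValueError("non-integer counts")
        self.counts = self.counts.astype(int)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        bad = df.index[(df < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count for gene {bad!r}")
    return CountMatrix(counts=df)


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t")


BLAST6_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_blast_tab(path) -> pd.DataFrame:
    """BLAST tabular (outfmt 6) hits, keeping the best bitscore per
    (query, subject) pair."""
    try:
        df = pd.read_csv(
            path, sep="\t", names=BLAST6_COLUMNS, comment="#", header=None
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: malformed BLAST tabular file: {exc}") from exc
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    if df["bitscore"].isna().any():
        lineno = int(df.index[df["bitscore"].isna()][0]) + 1
        raise ValueError(f"{path}:{lineno}: missing bitscore")
    df = (
        df.sort_values("bitscore", ascending=False)
        .drop_duplicates(subset=["query", "subject"], keep="first")
        .reset_index(drop=True)
    )
    return df


def validate_files(paths: list[str | Path]) -> dict[str, str]:
    """Best-effort format validation keyed by filename; used by the CLI."""
    readers = {
        ".fa": read_fasta,
        ".fasta": read_fasta,
        ".fna": read_fasta,
        ".faa": read_fasta,
        ".tsv": read_annotation_tsv,
    }
    from .trees import read_newick

    results: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        reader = readers.get(path.suffix)
        if path.suffix in {".nwk", ".newick", ".tre"}:
            reader = read_newick
        if reader is None:
            results[str(path)] = "skipped (unknown extension)"
            continue
        try:
            reader(path)
        except Exception as exc:
            results[str(path)] = f"INVALID: {exc}"
        else:
            results[str(path)] = "ok"
    return results
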