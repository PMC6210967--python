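"""Readers and writers for the pipeline's standard formats.

FASTA goes through Biopython; tables through pandas with tab delimiters,
header rows, UTF-8, and explicit missing values.  BLAST tabular input is
the 12-column outfmt-6 layout, optionally extended with query/subject
coverage columns, or a native TSV with named columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_blast_tab",
]

FASTA_WRAP = 60

BLAST12_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(header, sequence) pairs; headers preserved verbatim (without '>')."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Write records wrapped at 60 columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Tab-delimited table with a header row; empty cells become NaN."""
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_blast_tab(path: str | Path, coverage_columns: bool = False) -> pd.DataFrame:
    """Parse BLAST tabular output (outfmt 6).

    With ``coverage_columns=True`` two extra trailing columns
    (query_coverage_pct, template_coverage_pct) are expected, giving the
    hit layout the interolog stage consumes; subject_id is then exposed as
    template_id.
    """
    names = list(BLAST12_COLUMNS)
    if coverage_columns:
        names += ["query_coverage_pct", "template_coverage_pct"]
    try:
        table = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed BLAST tabular file: {exc}") from exc
    if table.shape[0] == 0:
        raise ValueError(f"{path}: empty BLAST tabular file")
    if table[names[-1]].isna().any():
        bad = int(table[names[-1]].isna().idxmax()) + 1
        raise ValueError(f"{path}: line {bad}: expected {len(names)} tab-separated columns")
    if coverage_columns:
        table = table.rename(columns={"subject_id": "template_id"})
    return table
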