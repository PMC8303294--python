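"""Plain-text readers/writers: TSV tables and FASTA sequences."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_counts",
    "read_table",
    "write_table",
    "read_fasta",
    "write_fasta",
]


def read_counts(path) -> pd.DataFrame:
    """miRNA x sample count matrix from TSV/CSV (first column = miRNA ID)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    counts = pd.read_csv(path, sep=sep, index_col=0)
    if counts.isna().any().any():
        raise ValueError(f"count matrix {path} contains missing values")
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"count matrix {path} contains negative values")
    return counts


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def write_table(frame: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
    return path


def read_fasta(path) -> dict[str, str]:
    """FASTA to an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return path
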