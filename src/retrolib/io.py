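"""File-format plumbing: FASTA/FASTQ via Biopython, TSV via pandas.

TSV is the interchange dialect (tab, UTF-8, header row, '.' for missing);
FASTA is wrapped at 80 columns; FASTQ may be plain or gzip.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NA_TOKEN = "."


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from a FASTQ(.gz) file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality: int = 40) -> int:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            SeqIO.write(SeqRecord(Seq(seq), id=name, description=""), fh, "fasta")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=True, **kwargs)
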