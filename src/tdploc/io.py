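"""Light wrappers around the file formats the pipeline exchanges.

FASTA goes through Biopython, FASTQ reading through pysam's C parser
(millions of amplicon reads), tables through pandas. FASTQ/BED writing is
plain text because the records are fixed four-line / six-column layouts.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str) -> dict:
    """FASTA -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: Iterable[Tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


class FastqWriter:
    """Four-line FASTQ writer with uniform high base quality."""

    def __init__(self, path: str):
        self._fh = gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    def write(self, name: str, seq: str, qual: str | None = None) -> None:
        if qual is None:
            qual = "I" * len(seq)
        self._fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_fastq_pairs(path1: str, path2: str) -> Iterator[tuple]:
    """Yield (name, seq1, qual1, seq2, qual2) from a FASTQ pair."""
    with pysam.FastxFile(path1) as fq1, pysam.FastxFile(path2) as fq2:
        for r1, r2 in zip(fq1, fq2):
            yield r1.name, r1.sequence, r1.quality, r2.sequence, r2.quality


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """BED6 (0-based half-open) -> DataFrame; malformed lines raise with line number."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns")
    df = df.iloc[:, :6].reindex(columns=range(6))
    df.columns = BED_COLUMNS
    for col in ("start", "end"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as err:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: malformed BED at line {bad + 1}") from err
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: malformed BED at line {bad[0] + 1} (start >= end)")
    return df


def write_bed(path: str, df: pd.DataFrame) -> None:
    df.reindex(columns=BED_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def write_tsv(path: str, df: pd.DataFrame, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_samplesheet(path: str) -> pd.DataFrame:
    """Sample sheet TSV; fastq paths are resolved relative to the sheet."""
    df = pd.read_csv(path, sep="\t")
    base = os.path.dirname(os.path.abspath(path))
    for col in ("fastq1", "fastq2"):
        if col in df:
            df[col] = [p if os.path.isabs(p) else os.path.join(base, p)
                       for p in df[col]]
    return df
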