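"""Readers and writers for the pipeline's on-disk formats.

FASTA and FASTQ go through Biopython; GFF3, GMT and the various TSV tables
are simple columnar formats written/read with pandas or plain text. All
coordinates on disk are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as FASTA."""
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- FASTQ

def write_fastq_gz(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (name, sequence, quality) triples as gzipped Phred+33 FASTQ."""
    with gzip.open(str(path), "wt", compresslevel=1) as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Iterate (title, sequence, quality) from plain or gzipped FASTQ."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


# ---------------------------------------------------------------- GFF3

def write_gff3(path: str | Path, rows: Iterable[tuple]) -> None:
    """Write (chrom, source, type, start, end, strand, attributes) rows.

    start/end are 1-based inclusive; attributes is a preformatted string.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, start, end, strand, attrs in rows:
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame with parsed attribute dict column."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": f[0],
                    "source": f[1],
                    "type": f[2],
                    "start": int(f[3]),
                    "end": int(f[4]),
                    "strand": f[6],
                    "attributes": attrs,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- GMT / TSV

def write_gmt(path: str | Path, gene_sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
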