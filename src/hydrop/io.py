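"""Format readers/writers shared by all subcommands.

All text formats are gzip-transparent by file extension.  Coordinates in
fragments and BED files are 0-based half-open.  Malformed records raise
with file/line context.
"""

from __future__ import annotations

import gzip
from contextlib import contextmanager
from typing import Iterator

import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def open_text(path, mode: str = "rt"):
    """Open a text file, decompressing transparently for ``.gz`` paths."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (name, sequence, quality) records from a FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title, seq, qual
        except (ValueError, EOFError, OSError) as exc:
            raise ValueError(f"malformed FASTQ {path}: {exc}") from exc


def write_fastq(records, path) -> None:
    with open_text(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fragments(path) -> pd.DataFrame:
    """Read a 5-column fragments TSV: chrom, start, end, barcode, count."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "barcode": str},
        )
    except Exception as exc:
        raise ValueError(f"malformed fragments file {path}: {exc}") from exc
    if df[["start", "end", "count"]].isna().any().any():
        bad = int(df[["start", "end", "count"]].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed fragments file {path}: bad record at line {bad}")
    return df


def write_fragments(df: pd.DataFrame, path, sort: bool = True) -> None:
    """Write a fragments TSV, canonically sorted by (chrom, start, end,
    barcode) unless ``sort=False``."""
    out = df[FRAGMENT_COLUMNS]
    if sort:
        out = out.sort_values(["chrom", "start", "end", "barcode"], kind="mergesort")
    with open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6; returns chrom/start/end (+ name/score/strand when
    present)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except Exception as exc:
        raise ValueError(f"malformed BED {path}: {exc}") from exc
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    with open_text(path, "wt") as fh:
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    with open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
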