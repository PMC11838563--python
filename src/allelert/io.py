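"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables are tab-separated with a header line; genomic intervals follow the
BED convention (0-based, half-open).  RT tracks are written as bedGraph with
masked bins omitted, plus a sidecar ``.meta`` file recording bin size and
normalization state.  FASTQ is the standard 4-line record format; the reader
reports the index of the first malformed record, which matters when a
simulated file is truncated or hand-edited.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd

from .errors import FastqFormatError

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_fastq",
    "write_fastq",
]

_FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3/BED6 into columns chrom, start, end[, name, score, strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(profile, path: str | os.PathLike) -> None:
    """Write an RTProfile as bedGraph; masked bins are omitted."""
    import numpy as np

    bins = profile.bins
    keep = ~np.isnan(profile.values)
    out = bins.loc[keep, ["chrom", "start", "end"]].copy()
    out["value"] = profile.values[keep]
    out.to_csv(path, sep="\t", index=False, header=False, float_format=_FLOAT_FORMAT)
    meta = {
        "bin_size": profile.bin_size,
        "state": profile.state,
        "allele": profile.allele,
        "replicate": profile.replicate,
    }
    with open(f"{path}.meta", "w") as fh:
        for key, val in meta.items():
            fh.write(f"{key}\t{val}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "value"]
    return df


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) per 4-line FASTQ record.

    Raises FastqFormatError with the 0-based record index on the first
    malformed record (bad headers, truncated record, length mismatch).
    """
    with open(path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError("header does not start with '@'", index)
            if seq == "" and plus == "" and qual == "":
                raise FastqFormatError("truncated record", index)
            if not plus.startswith("+"):
                raise FastqFormatError("separator line does not start with '+'", index)
            if len(seq) != len(qual):
                raise FastqFormatError("sequence and quality lengths differ", index)
            yield header[1:], seq, qual
            index += 1


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
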