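"""Nascent transcription, read-through, barcodes and per-insertion expression.

Nascent (Bru-Seq-like) libraries measure transcription rate rather than
steady-state RNA; quantification counts reads whose 5' end falls in an
annotated interval, strand-aware (the directional protocol yields reads
antisense to the gene, so the default mode is reverse-stranded).  Reporter
barcodes are counted by exact 16-mer substring matching, reads matching two
distinct barcodes are discarded and logged.  Expression units are
RPM = count * 1e6 / library_total and RPKM = RPM * 1e3 / length_bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .io import read_fastq

__all__ = [
    "quantify_nascent",
    "readthrough_fraction",
    "differential_expression",
    "extract_barcodes",
    "barcode_rpm",
    "per_insertion_expression",
    "BarcodeCounts",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _strand_match(read_strand, gene_strand, mode: str):
    if mode == "unstranded":
        return np.ones(len(read_strand), dtype=bool)
    if mode == "forward":
        return read_strand == gene_strand
    if mode == "reverse":
        return read_strand != gene_strand
    raise ConfigError(f"unknown strandedness mode {mode!r}")


def quantify_nascent(
    reads: pd.DataFrame,
    annotations: pd.DataFrame,
    library_size: int | None = None,
    strandedness: str = "reverse",
) -> pd.DataFrame:
    """Count reads whose 5' end falls inside each annotated interval.

    ``reads`` needs (chrom, start, end, strand) and optionally ``allele``
    (values a1/a2/unassigned); ``annotations`` is BED6-like with columns
    (chrom, start, end, name, strand) -- ``name`` is the gene id.  Returns
    one row per (gene, allele) with count, rpm, rpkm; alleles absent from
    ``reads`` collapse to a single "all" row per gene.  ``library_size``
    defaults to the number of reads and must be positive.
    """
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ConfigError("library_size must be > 0")
    reads = reads.copy()
    if "strand" not in reads.columns:
        reads["strand"] = "+"
    if "allele" not in reads.columns:
        reads["allele"] = "all"
    five = np.where(reads["strand"] == "-", reads["end"] - 1, reads["start"])
    alleles = sorted(reads["allele"].unique()) if len(reads) else ["all"]

    rows = []
    for ann in annotations.itertuples(index=False):
        gene = ann.name
        length_bp = ann.end - ann.start
        if length_bp <= 0:
            raise ConfigError(f"annotation {gene!r} has non-positive length")
        if len(reads):
            hit = (
                (reads["chrom"].to_numpy() == ann.chrom)
                & (five >= ann.start)
                & (five < ann.end)
                & _strand_match(reads["strand"].to_numpy(), ann.strand, strandedness)
            )
        else:
            hit = np.zeros(0, dtype=bool)
        for allele in alleles:
            count = int(np.sum(hit & (reads["allele"].to_numpy() == allele))) if len(reads) else 0
            rpm = count * 1e6 / library_size
            rows.append(
                {
                    "gene": gene,
                    "allele": allele,
                    "length_bp": length_bp,
                    "count": count,
                    "rpm": rpm,
                    "rpkm": rpm * 1e3 / length_bp,
                }
            )
    return pd.DataFrame(rows)


def readthrough_fraction(
    expr: pd.DataFrame,
    reporter: str,
    downstream: str,
    allele: str | None = None,
) -> float:
    """Downstream-to-reporter RPKM ratio past the reporter's polyA site.

    0 when both are silent; an error when the reporter is silent but the
    downstream interval is not (the ratio would be meaningless).
    """
    sub = expr if allele is None else expr[expr["allele"] == allele]
    try:
        rep = float(sub.loc[sub["gene"] == reporter, "rpkm"].sum())
        dwn = float(sub.loc[sub["gene"] == downstream, "rpkm"].sum())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc))
    if rep == 0:
        if dwn == 0:
            return 0.0
        raise ConfigError("reporter is silent but downstream signal is present")
    return dwn / rep


def _median_of_ratios(mat: np.ndarray) -> np.ndarray:
    """Per-sample size factors: median ratio to the per-gene geometric mean.

    Genes with a zero in any sample are excluded from the reference, as
    usual; falls back to total-count factors when no gene qualifies.
    """
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    ref = log_mat.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        totals = mat.sum(axis=0)
        grand = totals.mean() if totals.mean() > 0 else 1.0
        return np.where(totals > 0, totals / grand, 1.0)
    sf = np.exp(np.median(log_mat[usable] - ref[usable, None], axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def differential_expression(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
) -> pd.DataFrame:
    """Simple differential test between two conditions.

    ``counts_a``/``counts_b`` are genes x replicates integer count tables
    (index = gene).  Library sizes are estimated with median-of-ratios size
    factors (the standard normalization robust to a minority of genuinely
    changed genes; plain totals would absorb their signal into every null
    gene); log2FC is the ratio of size-factor-normalized condition means
    with pseudocount 1; the p-value is a two-sided conditional-binomial
    exact Poisson rate test on the summed counts, with the null proportion
    set by the summed size factors; q is Benjamini-Hochberg.  Genes with
    zero counts in both conditions return log2FC 0, p 1.

    This is a deliberately transparent substitute for a negative-binomial
    shrinkage model: it flags presence of a rate difference, it does not
    moderate effect sizes.
    """
    genes = counts_a.index
    if not genes.equals(counts_b.index):
        raise ConfigError("count tables must share the same gene index")
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    sf = _median_of_ratios(np.concatenate([a, b], axis=1))
    sf_a, sf_b = sf[: a.shape[1]], sf[a.shape[1]:]
    mean_a = (a / sf_a).mean(axis=1)
    mean_b = (b / sf_b).mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    sum_a = a.sum(axis=1)
    sum_b = b.sum(axis=1)
    tot_a, tot_b = sf_a.sum(), sf_b.sum()
    p0 = tot_a / (tot_a + tot_b) if (tot_a + tot_b) > 0 else 0.5
    pvals = np.ones(len(genes))
    for i in range(len(genes)):
        n = int(sum_a[i] + sum_b[i])
        if n == 0:
            log2fc[i] = 0.0
            continue
        pvals[i] = _sstats.binomtest(int(sum_a[i]), n, p0, alternative="two-sided").pvalue
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "p": pvals, "q": qvals}
    ).set_index("gene")


@dataclass
class BarcodeCounts:
    """Exact-match barcode counts plus the ambiguity log."""

    counts: pd.Series  # index barcode_id
    n_ambiguous: int
    ambiguous_reads: list[str]
    n_reads: int

    def rpm(self, total_reads: int | None = None) -> pd.Series:
        return barcode_rpm(self.counts, total_reads if total_reads is not None else self.n_reads)


def extract_barcodes(
    fastq: str | Iterable[tuple[str, str, str]],
    manifest: pd.DataFrame,
    scan_revcomp: bool = False,
) -> BarcodeCounts:
    """Count reads containing each exact 16-nt barcode as a substring.

    ``fastq`` is a path or an iterable of (name, seq, qual) records.  A
    read increments barcode b iff b occurs in the read (forward
    orientation; ``scan_revcomp`` also scans the reverse complement).  A
    read matching two or more distinct barcodes increments none and is
    logged.  Malformed FASTQ records raise with the record index.
    """
    seqs = manifest["sequence"].tolist()
    ids = manifest["barcode_id"].tolist()
    if len(set(seqs)) != len(seqs):
        raise ConfigError("duplicate barcode sequences in manifest")
    for s in seqs:
        if len(s) != 16 or set(s) - set("ACGT"):
            raise ConfigError(f"barcode {s!r} is not a 16-nt ACGT string")
    import os

    records = (
        read_fastq(fastq) if isinstance(fastq, (str, bytes, os.PathLike)) else iter(fastq)
    )

    counts = np.zeros(len(seqs), dtype=np.int64)
    ambiguous: list[str] = []
    n_reads = 0
    for name, seq, _qual in records:
        n_reads += 1
        targets = (seq, _revcomp(seq)) if scan_revcomp else (seq,)
        hits = [j for j, bc in enumerate(seqs) if any(bc in t for t in targets)]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1:
            ambiguous.append(name)
    return BarcodeCounts(
        counts=pd.Series(counts, index=pd.Index(ids, name="barcode_id"), name="count"),
        n_ambiguous=len(ambiguous),
        ambiguous_reads=ambiguous,
        n_reads=n_reads,
    )


def barcode_rpm(counts: pd.Series, total_reads: int) -> pd.Series:
    """Reads per million: count * 1e6 / total_reads."""
    if total_reads <= 0:
        raise ConfigError("total_reads must be > 0")
    return counts * 1e6 / total_reads


def per_insertion_expression(
    reporter_rpkm: float,
    n_insertions: int,
    gene_rpkm_distribution: Sequence[float],
) -> tuple[float, float]:
    """Per-insertion reporter RPKM and its percentile among genes.

    A clone carrying ``n_insertions`` identical reporters contributes their
    summed expression; dividing by the insertion count gives the average
    expression of one insertion.  The percentile is the fraction (in %) of
    genes with strictly lower RPKM.
    """
    if n_insertions < 1:
        raise ConfigError("n_insertions must be >= 1")
    per_insertion = reporter_rpkm / n_insertions
    genes = np.asarray(gene_rpkm_distribution, dtype=float)
    if genes.size == 0:
        raise ConfigError("gene RPKM distribution is empty")
    percentile = 100.0 * float(np.mean(genes < per_insertion))
    return per_insertion, percentile
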