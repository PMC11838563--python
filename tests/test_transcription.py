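"""Nascent quantification, differential test, barcode counting, expression units."""

import math

import numpy as np
import pandas as pd
import pytest

import allelert as al
from allelert.errors import ConfigError, FastqFormatError
from allelert.io import write_fastq
from allelert.simulate import simulate_barcode_fastq
from allelert.transcription import (
    barcode_rpm,
    differential_expression,
    extract_barcodes,
    per_insertion_expression,
    quantify_nascent,
    readthrough_fraction,
)

ANNOTATIONS = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1_000, 10_000, 5_000],
        "end": [2_000, 106_000, 9_000],
        "name": ["geneA", "geneB", "geneC"],
        "score": [0, 0, 0],
        "strand": ["+", "-", "+"],
    }
)


def _reads(rng, n):
    chroms = rng.choice(["chr1", "chr2"], size=n)
    start = rng.integers(0, 120_000, size=n)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": start,
            "end": start + 100,
            "strand": rng.choice(["+", "-"], size=n),
            "allele": rng.choice(["a1", "a2", "unassigned"], size=n),
        }
    )


class TestQuantifyNascent:
    def test_empty_reads_give_zeros(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        out = quantify_nascent(empty, ANNOTATIONS, library_size=1000)
        assert (out["count"] == 0).all() and (out["rpkm"] == 0).all()

    def test_closed_form_rpm_rpkm(self):
        # 10 reads in a 1-kb gene, library 1e6 => RPM 10, RPKM 10
        reads = pd.DataFrame(
            {"chrom": ["chr1"] * 10, "start": [1_500] * 10, "end": [1_600] * 10,
             "strand": ["+"] * 10}
        )
        out = quantify_nascent(reads, ANNOTATIONS, library_size=10**6,
                               strandedness="forward")
        row = out[out["gene"] == "geneA"].iloc[0]
        assert row["count"] == 10
        assert row["rpm"] == pytest.approx(10.0)
        assert row["rpkm"] == pytest.approx(10.0)

    @pytest.mark.parametrize("mode", ["reverse", "forward", "unstranded"])
    def test_matches_per_read_loop(self, mode):
        rng = np.random.default_rng(11)
        reads = _reads(rng, 10_000)
        out = quantify_nascent(reads, ANNOTATIONS, strandedness=mode)
        for ann in ANNOTATIONS.itertuples(index=False):
            for allele in ("a1", "a2", "unassigned"):
                brute = 0
                for row in reads.itertuples(index=False):
                    if row.allele != allele or row.chrom != ann.chrom:
                        continue
                    pos = row.end - 1 if row.strand == "-" else row.start
                    if not (ann.start <= pos < ann.end):
                        continue
                    if mode == "forward" and row.strand != ann.strand:
                        continue
                    if mode == "reverse" and row.strand == ann.strand:
                        continue
                    brute += 1
                got = out[(out["gene"] == ann.name) & (out["allele"] == allele)]
                assert int(got["count"].iloc[0]) == brute

    def test_zero_library_rejected(self):
        with pytest.raises(ConfigError):
            quantify_nascent(pd.DataFrame(columns=["chrom", "start", "end"]),
                             ANNOTATIONS, library_size=0)


class TestReadthrough:
    def _expr(self, reporter_rpkm, downstream_rpkm):
        return pd.DataFrame(
            {"gene": ["rep", "down"], "allele": ["a1", "a1"],
             "rpkm": [reporter_rpkm, downstream_rpkm]}
        )

    def test_silent_downstream_gives_zero(self):
        assert readthrough_fraction(self._expr(50.0, 0.0), "rep", "down") == 0.0

    def test_both_silent_gives_zero(self):
        assert readthrough_fraction(self._expr(0.0, 0.0), "rep", "down") == 0.0

    def test_silent_reporter_with_signal_rejected(self):
        with pytest.raises(ConfigError):
            readthrough_fraction(self._expr(0.0, 3.0), "rep", "down")

    def test_simulated_readthrough_recovered(self):
        # Poisson oracle at deep coverage: estimate within 3 sigma of 0.05
        genes = pd.DataFrame(
            {"gene": ["rep", "down"], "chrom": ["chr1"] * 2,
             "start": [0, 2_000], "end": [2_000, 12_000], "strand": ["+", "+"]}
        )
        counts = al.simulate_bruseq(
            genes, {("rep", "a1"): 100.0}, library_scale=500.0, n_replicates=1,
            seed=7, readthrough=("rep", "down", 0.05),
        )
        table = counts.assign(
            length_kb=counts["gene"].map({"rep": 2.0, "down": 10.0})
        )
        table["rpkm"] = table["count"] / table["length_kb"]
        est = readthrough_fraction(table[["gene", "allele", "rpkm"]], "rep", "down")
        lam_rep, lam_down = 100 * 2 * 500, 5 * 10 * 500
        sigma = est * math.sqrt(1 / lam_rep + 1 / lam_down)
        assert abs(est - 0.05) < 3 * max(sigma, 0.05 * math.sqrt(1 / lam_down)) + 0.003


class TestDifferentialExpression:
    def _tables(self, rng, n_genes, rate_a, rate_b, reps=3):
        idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene")
        a = pd.DataFrame(rng.poisson(rate_a, size=(n_genes, reps)), index=idx)
        b = pd.DataFrame(rng.poisson(rate_b, size=(n_genes, reps)), index=idx)
        return a, b

    def test_identical_tables_give_zero_log2fc(self):
        rng = np.random.default_rng(0)
        a, _ = self._tables(rng, 50, 20, 20)
        out = differential_expression(a, a.copy())
        np.testing.assert_allclose(out["log2fc"], 0.0, atol=1e-12)

    def test_all_zero_gene_returns_p_one(self):
        idx = pd.Index(["g0"], name="gene")
        zero = pd.DataFrame([[0, 0]], index=idx)
        out = differential_expression(zero, zero.copy())
        assert out["p"].iloc[0] == 1.0 and out["log2fc"].iloc[0] == 0.0

    def test_fourfold_induction_recovered(self):
        # Poisson simulation oracle: 100 genes induced 4x at mean 100 among a
        # majority of unchanged genes; median log2FC lands in [1.8, 2.2]
        # (total-count normalization assumes most genes are unchanged)
        rng = np.random.default_rng(1)
        n, n_induced = 4000, 100
        rates_b = np.full(n, 100.0)
        rates_a = rates_b * np.where(np.arange(n) < n_induced, 4.0, 1.0)
        idx = pd.Index([f"g{i}" for i in range(n)], name="gene")
        a = pd.DataFrame(rng.poisson(rates_a[:, None], size=(n, 3)), index=idx)
        b = pd.DataFrame(rng.poisson(rates_b[:, None], size=(n, 3)), index=idx)
        out = differential_expression(a, b)
        induced = out.iloc[:n_induced]
        assert 1.8 <= induced["log2fc"].median() <= 2.2
        assert (induced["q"] < 0.05).mean() > 0.95

    def test_null_calibration(self):
        # equal rates: fraction with p < 0.05 within [0.03, 0.07] at 2000 genes
        rng = np.random.default_rng(2)
        a, b = self._tables(rng, 2000, 50, 50)
        out = differential_expression(a, b)
        assert 0.03 <= (out["p"] < 0.05).mean() <= 0.07

    def test_agrees_with_negative_binomial_reference_implementation(self):
        # independent cross-check against a published differential-expression
        # package on a mixed null/induced dataset
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        n = 100
        rates_b = np.full(n, 100.0)
        rates_a = rates_b * np.where(np.arange(n) < 10, 4.0, 1.0)
        idx = pd.Index([f"g{i}" for i in range(n)], name="gene")
        a = pd.DataFrame(rng.poisson(rates_a[:, None], size=(n, 3)), index=idx)
        b = pd.DataFrame(rng.poisson(rates_b[:, None], size=(n, 3)), index=idx)
        ours = differential_expression(a, b)

        counts = pd.concat([a, b], axis=1)
        counts.columns = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition",
                           quiet=True)
        dds.deseq2()
        res = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
        res.summary()
        theirs = res.results_df
        corr = np.corrcoef(ours["log2fc"], theirs["log2FoldChange"])[0, 1]
        assert corr > 0.95
        ours_sig = (ours["q"] < 0.05).to_numpy()
        theirs_sig = (theirs["padj"] < 0.05).to_numpy()
        assert (ours_sig == theirs_sig).mean() > 0.9


class TestExtractBarcodes:
    def test_counts_match_generator_truth_exactly(self, barcode_manifest, tmp_path):
        path = tmp_path / "reads.fastq"
        _records, truth = simulate_barcode_fastq(
            barcode_manifest, np.arange(1, 9, dtype=float), 3_000, seed=12,
            path=str(path), background_fraction=0.3,
        )
        result = extract_barcodes(str(path), barcode_manifest)
        pd.testing.assert_series_equal(result.counts, truth, check_names=False)
        assert result.n_ambiguous == 0

    def test_empty_fastq_gives_zeros(self, barcode_manifest, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        result = extract_barcodes(str(path), barcode_manifest)
        assert result.counts.sum() == 0 and result.n_reads == 0

    def test_ambiguous_read_counted_for_neither(self, barcode_manifest):
        b0, b1 = barcode_manifest["sequence"].iloc[:2]
        records = [("ambig", b0 + "AC" + b1, "I" * 34), ("clean", "AA" + b0 + "TT", "I" * 20)]
        result = extract_barcodes(records, barcode_manifest)
        assert result.counts.iloc[0] == 1 and result.counts.iloc[1] == 0
        assert result.n_ambiguous == 1 and result.ambiguous_reads == ["ambig"]

    def test_revcomp_scan_behind_flag(self, barcode_manifest):
        comp = str.maketrans("ACGT", "TGCA")
        b0 = barcode_manifest["sequence"].iloc[0]
        rc = b0.translate(comp)[::-1]
        records = [("r", "AAAA" + rc + "GGGG", "I" * 24)]
        assert extract_barcodes(records, barcode_manifest).counts.iloc[0] == 0
        assert extract_barcodes(records, barcode_manifest,
                                scan_revcomp=True).counts.iloc[0] == 1

    def test_malformed_record_reports_index(self, barcode_manifest, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nOOPS\nIIII\n")
        with pytest.raises(FastqFormatError) as err:
            extract_barcodes(str(path), barcode_manifest)
        assert err.value.record_index == 1


class TestExpressionUnits:
    def test_rpm_closed_form(self):
        counts = pd.Series([5, 0], index=["b1", "b2"])
        rpm = barcode_rpm(counts, 10**6)
        assert rpm["b1"] == pytest.approx(5.0) and rpm["b2"] == 0.0

    def test_rpm_homogeneity(self):
        counts = pd.Series([10, 20, 30])
        np.testing.assert_allclose(barcode_rpm(counts, 2_000_000),
                                   barcode_rpm(counts, 1_000_000) / 2, atol=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ConfigError):
            barcode_rpm(pd.Series([1]), 0)

    def test_per_insertion_division(self):
        per_ins, _ = per_insertion_expression(107.0, 107, [0.5, 0.9])
        assert per_ins == pytest.approx(1.0)

    def test_percentile_above_all_genes_is_100(self):
        _, pct = per_insertion_expression(500.0, 1, [1.0, 2.0, 3.0])
        assert pct == 100.0

    def test_planted_99th_percentile_recovered(self):
        rng = np.random.default_rng(4)
        genes = rng.lognormal(1.0, 1.0, size=5_000)
        target = np.quantile(genes, 0.99)
        _, pct = per_insertion_expression(target * 2, 2, genes)
        assert 98.0 <= pct <= 100.0

    def test_zero_insertions_rejected(self):
        with pytest.raises(ConfigError):
            per_insertion_expression(10.0, 0, [1.0])
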