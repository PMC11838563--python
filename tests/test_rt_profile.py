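"""Binning, log2 E/L profiles, quantile normalization, smoothing, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allelert as al
from allelert.errors import ConfigError, StateError
from allelert.rt import (
    BinnedCounts,
    RTProfile,
    aggregate_bins,
    bin_reads,
    compute_rt,
    quantile_normalize,
    quantile_reference,
    scale_rt,
    smooth_rt,
)

CHROM_SIZES = {"chr1": 500_000, "chr2": 200_000}


def _profile(values, bin_size=50_000, state="raw", chrom="chr1"):
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values)) * bin_size
    bins = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size})
    return RTProfile(bins=bins, values=values, bin_size=bin_size, state=state)


def _random_reads(rng, n, with_strand=True):
    chroms = rng.choice(list(CHROM_SIZES), size=n)
    sizes = np.array([CHROM_SIZES[c] for c in chroms])
    start = rng.integers(0, sizes - 120)
    df = pd.DataFrame({"chrom": chroms, "start": start, "end": start + 100})
    if with_strand:
        df["strand"] = rng.choice(["+", "-"], size=n)
    return df


class TestBinReads:
    def test_boundary_read_goes_to_lower_bin(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [49_999], "end": [50_099]})
        counts = bin_reads(reads, CHROM_SIZES, 50_000)
        hit = counts.df[counts.df["count"] > 0]
        assert len(hit) == 1
        assert (hit["start"].iloc[0], hit["end"].iloc[0]) == (0, 50_000)

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        reads = _random_reads(rng, 1000)
        counts = bin_reads(reads, CHROM_SIZES, 50_000)
        assert counts.df["count"].sum() == 1000

    def test_matches_per_read_loop(self):
        # brute-force oracle: assign each read individually, compare per bin
        rng = np.random.default_rng(2)
        reads = _random_reads(rng, 10_000)
        counts = bin_reads(reads, CHROM_SIZES, 50_000)
        brute: dict[tuple[str, int], int] = {}
        for row in reads.itertuples(index=False):
            pos = row.end - 1 if row.strand == "-" else row.start
            key = (row.chrom, (pos // 50_000) * 50_000)
            brute[key] = brute.get(key, 0) + 1
        table = counts.df.groupby(["chrom", "start"])["count"].sum()
        for key, n in brute.items():
            assert table[key] == n
        assert table.sum() == sum(brute.values())

    def test_read_beyond_chromosome_end_rejected(self):
        reads = pd.DataFrame({"chrom": ["chr2"], "start": [250_000], "end": [250_100]})
        with pytest.raises(ConfigError):
            bin_reads(reads, CHROM_SIZES, 50_000)

    def test_aggregation_equals_direct_coarse_binning(self):
        rng = np.random.default_rng(3)
        reads = _random_reads(rng, 5000)
        reads["allele"] = rng.choice(["a1", "a2"], size=len(reads))
        fine = bin_reads(reads, CHROM_SIZES, 5_000)
        coarse = aggregate_bins(fine, 10)
        direct = bin_reads(reads, CHROM_SIZES, 50_000)
        left = coarse.df.groupby(["chrom", "start", "allele"])["count"].sum()
        right = direct.df.groupby(["chrom", "start", "allele"])["count"].sum()
        pd.testing.assert_series_equal(left, right)


def _counts_frame(early, late, bin_size=50_000):
    n = len(early)
    starts = np.arange(n) * bin_size
    rows = []
    for frac, arr in (("early", early), ("late", late)):
        rows.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": starts,
                    "end": starts + bin_size,
                    "allele": "a1",
                    "fraction": frac,
                    "replicate": 1,
                    "count": arr,
                }
            )
        )
    return BinnedCounts(pd.concat(rows, ignore_index=True), bin_size)


class TestComputeRT:
    def test_equal_fractions_give_zero(self):
        counts = _counts_frame([100, 50, 80], [100, 50, 80])
        prof = compute_rt(counts, min_coverage=1)[("a1", 1)]
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_fourfold_cpm_enrichment_near_two(self):
        # mirrored counts keep both library sizes equal, so bin 0 has
        # E_cpm = 4 * L_cpm (rt ~ +2) and bin 1 the reverse (rt ~ -2)
        counts = _counts_frame([4000, 1000], [1000, 4000])
        prof = compute_rt(counts, pseudocount=1e-6, min_coverage=1)[("a1", 1)]
        np.testing.assert_allclose(prof.values, [2.0, -2.0], atol=1e-3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_swapping_fractions_negates_rt(self, seed):
        rng = np.random.default_rng(seed)
        early = rng.poisson(30, size=40)
        late = rng.poisson(30, size=40)
        counts = _counts_frame(early, late)
        fwd = compute_rt(counts)[("a1", 1)].values
        rev = compute_rt(counts.swap_fractions())[("a1", 1)].values
        np.testing.assert_array_equal(np.isnan(fwd), np.isnan(rev))
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_low_coverage_bins_masked(self):
        counts = _counts_frame([3, 100], [4, 100])
        prof = compute_rt(counts, min_coverage=10)[("a1", 1)]
        assert np.isnan(prof.values[0]) and not np.isnan(prof.values[1])

    def test_missing_fraction_errors(self):
        counts = _counts_frame([10, 10], [10, 10])
        broken = BinnedCounts(
            counts.df[counts.df["fraction"] == "early"].copy(), counts.bin_size
        )
        with pytest.raises(ConfigError, match="missing 'late'"):
            compute_rt(broken)


class TestQuantileNormalize:
    def test_identity_when_sample_equals_reference(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)
        sample, reference = _profile(vals), _profile(vals.copy())
        out = quantile_normalize(sample, reference)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)
        assert out.state == "quantile_normalized"

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=50)
        out = quantile_normalize(_profile(vals + 1.7), _profile(vals))
        np.testing.assert_allclose(np.sort(out.values), np.sort(vals), atol=1e-12)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(10, 80), st.integers(10, 80))
    @settings(max_examples=25, deadline=None)
    def test_sorted_output_matches_reference_quantiles(self, seed, n, m):
        # explicit sort-and-map oracle; exact multiset equality when n == m
        rng = np.random.default_rng(seed)
        sample = _profile(rng.normal(size=n))
        reference = _profile(rng.normal(2, 3, size=m))
        out = quantile_normalize(sample, reference)
        if n == m:
            np.testing.assert_array_equal(np.sort(out.values), np.sort(reference.values))
        else:
            ref_sorted = np.sort(reference.values)
            assert np.min(out.values) >= ref_sorted[0] - 1e-12
            assert np.max(out.values) <= ref_sorted[-1] + 1e-12
            # rank order is preserved
            assert np.all(np.argsort(out.values) == np.argsort(sample.values))

    def test_ties_map_to_mean_of_tied_reference_quantiles(self):
        sample = _profile([1.0, 2.0, 2.0, 3.0])
        reference = _profile([10.0, 20.0, 30.0, 40.0])
        out = quantile_normalize(sample, reference)
        np.testing.assert_allclose(out.values, [10.0, 25.0, 25.0, 40.0])

    def test_masked_bins_stay_masked_and_are_ignored(self):
        sample = _profile([0.5, np.nan, -0.2, 1.0])
        reference = _profile([0.0, 1.0, 2.0, np.nan])
        out = quantile_normalize(sample, reference)
        assert np.isnan(out.values[1])
        np.testing.assert_allclose(np.sort(out.values[[0, 2, 3]]), [0.0, 1.0, 2.0])

    def test_too_few_unmasked_bins_rejected(self):
        with pytest.raises(ConfigError):
            quantile_normalize(_profile([1.0, np.nan, np.nan]), _profile([1.0, 2.0, 3.0]))

    def test_quantile_reference_is_noise_width_matched(self):
        rng = np.random.default_rng(5)
        profs = [_profile(rng.normal(0, 1, size=200)) for _ in range(4)]
        ref = quantile_reference(profs)
        assert ref.values.std() == pytest.approx(1.0, rel=0.15)


class TestSmoothRT:
    def test_constant_profile_unchanged(self):
        prof = _profile([2.5] * 100, bin_size=5_000, state="quantile_normalized")
        out = smooth_rt(prof, span_bp=300_000)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)
        assert out.state == "smoothed"

    def test_spike_matches_brute_force_window_mean(self):
        n, w = 200, 60
        vals = np.zeros(n)
        vals[100] = 6.0
        prof = _profile(vals, bin_size=5_000)
        out = smooth_rt(prof, span_bp=300_000)
        # brute-force centered window mean (pandas-style: left-heavy for even w)
        brute = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - w // 2), min(n, i + (w - 1) // 2 + 1)
            brute[i] = vals[lo:hi].mean()
        np.testing.assert_allclose(out.values, brute, atol=1e-12)
        assert out.values.max() <= 6.0 / w + 1e-9

    def test_linear_ramp_interior_unchanged(self):
        n = 300
        vals = np.linspace(0, 3, n)
        out = smooth_rt(_profile(vals, bin_size=5_000), span_bp=305_000)  # odd window
        w = 61
        interior = slice(w // 2, n - w // 2)
        np.testing.assert_allclose(out.values[interior], vals[interior], atol=1e-9)

    def test_masked_bins_omitted_and_all_masked_window_stays_masked(self):
        vals = np.full(100, np.nan)
        vals[10] = 1.0
        out = smooth_rt(_profile(vals, bin_size=5_000), span_bp=50_000)
        assert out.values[10] == pytest.approx(1.0)
        assert np.isnan(out.values[60])

    def test_mean_conserved_away_from_edges_when_flanks_flat(self):
        # exact conservation when the chromosome ends are flat
        rng = np.random.default_rng(7)
        n, w = 400, 60
        vals = np.zeros(n)
        vals[2 * w: n - 2 * w] = rng.normal(size=n - 4 * w)
        out = smooth_rt(_profile(vals, bin_size=5_000), span_bp=300_000)
        interior = slice(w, n - w)
        assert out.values[interior].sum() == pytest.approx(vals[interior].sum(), abs=1e-9)

    def test_span_validation(self):
        prof = _profile([1.0] * 10, bin_size=5_000)
        with pytest.raises(ConfigError):
            smooth_rt(prof, span_bp=2_000)
        with pytest.raises(ConfigError):
            smooth_rt(prof, span_bp=12_500)

    def test_smoothing_respects_chromosome_boundaries(self):
        bins = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5 + ["chr2"] * 5,
                "start": list(range(0, 25_000, 5_000)) * 2,
                "end": list(range(5_000, 30_000, 5_000)) * 2,
            }
        )
        prof = RTProfile(bins, np.r_[np.zeros(5), np.ones(5)], 5_000, "raw")
        out = smooth_rt(prof, span_bp=25_000)
        np.testing.assert_allclose(out.values[:5], 0.0)
        np.testing.assert_allclose(out.values[5:], 1.0)


class TestScaleRT:
    def test_dynamic_range_rescaled_to_target(self):
        # a track spanning ~(-7, 7) is brought to ~(-3, 3)
        rng = np.random.default_rng(3)
        vals = rng.uniform(-7, 7, size=2000)
        prof = _profile(vals, state="quantile_normalized")
        out = scale_rt(prof, target_halfrange=3.0)
        assert np.percentile(np.abs(out.values), 99.5) == pytest.approx(3.0, abs=1e-9)
        assert out.state == "scaled"

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(4)
        prof = _profile(rng.normal(size=500), state="quantile_normalized")
        once = scale_rt(prof)
        twice = scale_rt(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_degenerate_profiles_rejected(self):
        allmask = _profile([np.nan, np.nan], state="quantile_normalized")
        with pytest.raises(ConfigError):
            scale_rt(allmask)
        zeros = _profile([0.0, 0.0, np.nan], state="quantile_normalized")
        with pytest.raises(ConfigError):
            scale_rt(zeros)

    def test_raw_profile_refused(self):
        with pytest.raises(StateError):
            scale_rt(_profile([1.0, 2.0], state="raw"))


class TestStateMachine:
    def test_states_only_move_forward(self):
        prof = _profile(np.arange(10.0), state="raw")
        qn = quantile_normalize(prof, _profile(np.arange(10.0) * 2))
        sm = smooth_rt(qn, span_bp=100_000)
        sc = scale_rt(sm)
        assert [p.state for p in (prof, qn, sm, sc)] == list(al.rt.STATES)
        with pytest.raises(StateError):
            quantile_normalize(sc, prof)  # backwards transition

    def test_scaled_profile_refused_by_statistics_path(self):
        vals = np.arange(10.0)
        qn = quantile_normalize(_profile(vals), _profile(vals * 2))
        sc = scale_rt(qn)
        with pytest.raises(StateError):
            al.allele_delta(sc, sc)
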