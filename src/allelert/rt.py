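"""From allele-tagged E/L fraction counts to normalized RT profiles.

The statistics path is: bin reads (50-kb windows) -> log2 ratio of
library-size-normalized early to late coverage per bin per allele per
replicate -> quantile normalization to a wild-type reference.  The display
path continues with a 300-kb sliding-mean smoothing of 5-kb bins and a
linear rescaling of the dynamic range; scaled profiles are for track export
only and are refused by the statistics operations downstream, which a
forward-only normalization-state machine enforces
(raw -> quantile_normalized -> smoothed -> scaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .errors import ConfigError, GridMismatchError, StateError

__all__ = [
    "BinnedCounts",
    "RTProfile",
    "STATES",
    "bin_reads",
    "aggregate_bins",
    "compute_rt",
    "quantile_reference",
    "quantile_normalize",
    "smooth_rt",
    "scale_rt",
]

STATES = ("raw", "quantile_normalized", "smoothed", "scaled")

_COUNT_COLUMNS = ["chrom", "start", "end", "allele", "fraction", "replicate", "count"]


@dataclass
class BinnedCounts:
    """Integer read counts keyed by (bin, allele, fraction, replicate).

    Bins are 0-based half-open and of uniform width ``bin_size`` (the last
    bin of a chromosome may be truncated).
    """

    df: pd.DataFrame
    bin_size: int

    def __post_init__(self):
        missing = [c for c in _COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"BinnedCounts missing columns: {missing}")
        if (self.df["count"] < 0).any():
            raise ConfigError("counts must be non-negative")
        width = self.df["end"] - self.df["start"]
        if (width <= 0).any() or (width > self.bin_size).any():
            raise ConfigError("bin widths must be in (0, bin_size]")
        if (self.df["start"] % self.bin_size != 0).any():
            raise ConfigError("bin starts must be multiples of bin_size")

    @property
    def alleles(self) -> list[str]:
        return sorted(self.df["allele"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.df["replicate"].unique())

    def bin_grid(self) -> pd.DataFrame:
        grid = (
            self.df[["chrom", "start", "end"]]
            .drop_duplicates()
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
        return grid

    def swap_fractions(self) -> "BinnedCounts":
        df = self.df.copy()
        df["fraction"] = df["fraction"].map({"early": "late", "late": "early"})
        return BinnedCounts(df, self.bin_size)

    def swap_alleles(self) -> "BinnedCounts":
        df = self.df.copy()
        df["allele"] = df["allele"].map(lambda a: {"a1": "a2", "a2": "a1"}.get(a, a))
        return BinnedCounts(df, self.bin_size)


@dataclass
class RTProfile:
    """One RT track: per-bin values (log2 E/L scale) with NaN = MASKED."""

    bins: pd.DataFrame  # chrom, start, end (sorted)
    values: np.ndarray
    bin_size: int
    state: str = "raw"
    allele: str | None = None
    replicate: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bins):
            raise ConfigError("values and bins lengths differ")
        if self.state not in STATES:
            raise ConfigError(f"unknown state {self.state!r}")

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is MASKED (insufficient coverage)."""
        return np.isnan(self.values)

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def same_grid(self, other: "RTProfile") -> bool:
        if len(self.bins) != len(other.bins):
            return False
        mine = self.bins[["chrom", "start", "end"]].reset_index(drop=True)
        theirs = other.bins[["chrom", "start", "end"]].reset_index(drop=True)
        return bool(mine.equals(theirs))

    def _to_state(self, new_state: str) -> None:
        if STATES.index(new_state) <= STATES.index(self.state):
            raise StateError(
                f"normalization state may only move forward: {self.state} -> {new_state}"
            )
        self.state = new_state

    def with_values(self, values: np.ndarray, state: str | None = None) -> "RTProfile":
        out = RTProfile(
            bins=self.bins,
            values=np.asarray(values, dtype=float),
            bin_size=self.bin_size,
            state=self.state,
            allele=self.allele,
            replicate=self.replicate,
        )
        if state is not None:
            out._to_state(state)
        return out


def bin_reads(
    read_intervals: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> BinnedCounts:
    """Assign each read to the bin containing its 5' start coordinate.

    ``read_intervals`` needs (chrom, start, end); a ``strand`` column makes
    the 5' end strand-aware ('-' reads start at end-1), and any of
    (allele, fraction, replicate) present are carried through as grouping
    keys (absent ones default to a single group).  Counts are conserved:
    the sum over bins equals the number of reads.  Reads outside the
    chromosome bounds raise.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be > 0")
    reads = read_intervals.copy()
    if "strand" in reads.columns:
        five_prime = np.where(reads["strand"] == "-", reads["end"] - 1, reads["start"])
    else:
        five_prime = reads["start"].to_numpy()
    reads["_pos"] = five_prime
    sizes = reads["chrom"].map(chrom_sizes)
    if sizes.isna().any():
        bad = reads.loc[sizes.isna(), "chrom"].unique()
        raise ConfigError(f"reads on unknown chromosomes: {list(bad)}")
    if ((reads["_pos"] < 0) | (reads["_pos"] >= sizes)).any():
        raise ConfigError("read 5' position beyond chromosome end")
    reads["start"] = (reads["_pos"] // bin_size) * bin_size

    group_cols = [c for c in ("allele", "fraction", "replicate") if c in reads.columns]
    counted = (
        reads.groupby(["chrom", "start", *group_cols], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    # dense grid over every chromosome x observed group combination
    grids = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        grids.append(pd.DataFrame({"chrom": chrom, "start": starts}))
    grid = pd.concat(grids, ignore_index=True)
    if group_cols:
        groups = reads[group_cols].drop_duplicates()
        grid = grid.merge(groups, how="cross")
    dense = grid.merge(counted, on=["chrom", "start", *group_cols], how="left")
    dense["count"] = dense["count"].fillna(0).astype(np.int64)
    dense["end"] = np.minimum(dense["start"] + bin_size, dense["chrom"].map(chrom_sizes))
    for col, default in (("allele", "a1"), ("fraction", "early"), ("replicate", 1)):
        if col not in dense.columns:
            dense[col] = default
    return BinnedCounts(dense[_COUNT_COLUMNS], bin_size=bin_size)


def aggregate_bins(counts: BinnedCounts, factor: int) -> BinnedCounts:
    """Sum counts from fine bins into bins ``factor`` times wider.

    Because per-bin counts are integer reads, aggregation is exact: a
    dataset binned at 5 kb aggregated 10x equals the same reads binned at
    50 kb.
    """
    if factor < 1:
        raise ConfigError("factor must be >= 1")
    coarse = counts.df.copy()
    size = counts.bin_size * factor
    coarse["start"] = (coarse["start"] // size) * size
    grouped = (
        coarse.groupby(["chrom", "start", "allele", "fraction", "replicate"], observed=True)
        .agg(count=("count", "sum"), end=("end", "max"))
        .reset_index()
    )
    return BinnedCounts(grouped[_COUNT_COLUMNS], bin_size=size)


def compute_rt(
    counts: BinnedCounts,
    pseudocount: float = 0.1,
    min_coverage: int = 10,
) -> dict[tuple[str, int], RTProfile]:
    """Raw RT = log2((E_cpm + pc) / (L_cpm + pc)) per bin per allele per replicate.

    Library-size normalization (counts per million) is applied within each
    (fraction, replicate) sequencing library, summed over all alleles and
    bins -- allele splitting happens downstream of sequencing.  Bins whose
    raw E+L coverage for an allele falls below ``min_coverage`` are MASKED
    (NaN).  Returns a dict keyed by (allele, replicate).
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    df = counts.df
    grid = counts.bin_grid()
    key = pd.MultiIndex.from_frame(grid)

    lib_sizes = df.groupby(["fraction", "replicate"], observed=True)["count"].sum()
    profiles: dict[tuple[str, int], RTProfile] = {}
    for (allele, rep), sub in df.groupby(["allele", "replicate"], observed=True):
        pivot = (
            sub.pivot_table(
                index=["chrom", "start", "end"],
                columns="fraction",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(key, fill_value=0)
        )
        for fraction in ("early", "late"):
            if fraction not in pivot.columns:
                raise ConfigError(
                    f"missing {fraction!r} fraction for allele {allele}, replicate {rep}"
                )
        early = pivot["early"].to_numpy(dtype=float)
        late = pivot["late"].to_numpy(dtype=float)
        e_cpm = early * 1e6 / lib_sizes[("early", rep)]
        l_cpm = late * 1e6 / lib_sizes[("late", rep)]
        rt = np.log2((e_cpm + pseudocount) / (l_cpm + pseudocount))
        rt[early + late < min_coverage] = np.nan
        profiles[(allele, rep)] = RTProfile(
            bins=grid,
            values=rt,
            bin_size=counts.bin_size,
            state="raw",
            allele=str(allele),
            replicate=int(rep),
        )
    return profiles


def quantile_reference(profiles: Sequence[RTProfile]) -> RTProfile:
    """Build a reference quantile function from wild-type profiles.

    The standard construction: the reference's sorted values are the mean
    of the per-profile quantile functions (evaluated on a common quantile
    grid), so the reference has the same sampling-noise width as each
    single profile being normalized -- a count-pooled reference would be
    artificially narrow and compress the tails of every sample mapped onto
    it.  The returned profile carries the values in sorted order on the
    shared grid; only its value multiset is meaningful.
    """
    if not profiles:
        raise ConfigError("no profiles given")
    n = len(profiles[0].bins)
    qs = np.linspace(0.0, 1.0, n)
    mats = []
    for p in profiles:
        vals = p.unmasked()
        if vals.size < 2:
            raise ConfigError("a reference profile has < 2 unmasked bins")
        mats.append(np.quantile(vals, qs))
    return RTProfile(
        bins=profiles[0].bins,
        values=np.mean(mats, axis=0),
        bin_size=profiles[0].bin_size,
        state="raw",
        allele="reference",
    )


def quantile_normalize(sample: RTProfile, reference: RTProfile) -> RTProfile:
    """Replace each unmasked sample value by the reference value of equal rank.

    Ranks are computed genome-wide over unmasked bins; ties take the mean
    of the tied reference quantiles.  When the unmasked-bin counts of
    sample and reference match, the sorted output values equal the sorted
    reference values exactly.  Masked bins stay masked.
    """
    sample_vals = sample.values
    keep = ~np.isnan(sample_vals)
    ref_vals = reference.unmasked()
    n, m = int(keep.sum()), len(ref_vals)
    if n < 2 or m < 2:
        raise ConfigError("quantile normalization needs >= 2 unmasked bins on each side")
    ranks = _sstats.rankdata(sample_vals[keep])  # 1..n, ties averaged
    ref_sorted = np.sort(ref_vals)
    idx = (ranks - 1.0) if n == m else (ranks - 1.0) * (m - 1) / (n - 1)
    mapped = np.interp(idx, np.arange(m), ref_sorted)
    out = np.full_like(sample_vals, np.nan)
    out[keep] = mapped
    return sample.with_values(out, state="quantile_normalized")


def smooth_rt(profile: RTProfile, span_bp: int = 300_000) -> RTProfile:
    """Centered sliding mean over ``span_bp``, computed per chromosome.

    Masked bins are omitted from each window's mean; a window with no
    unmasked bin stays masked; chromosome edges use the truncated window.
    """
    if span_bp < profile.bin_size:
        raise ConfigError("smoothing span must be >= bin size")
    if span_bp % profile.bin_size != 0:
        raise ConfigError("smoothing span must be a multiple of the bin size")
    window = span_bp // profile.bin_size
    out = np.empty_like(profile.values)
    chroms = profile.bins["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        series = pd.Series(profile.values[sel])
        out[sel] = series.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return profile.with_values(out, state="smoothed")


def scale_rt(profile: RTProfile, target_halfrange: float = 3.0) -> RTProfile:
    """Linearly rescale so the 99.5th percentile of |value| equals the target.

    Display-only: the result is in state "scaled", which the statistics
    operations refuse.
    """
    if profile.state not in ("quantile_normalized", "smoothed", "scaled"):
        raise StateError("scale_rt expects a quantile-normalized (optionally smoothed) profile")
    vals = profile.unmasked()
    if vals.size == 0:
        raise ConfigError("cannot scale an all-masked profile")
    q = np.percentile(np.abs(vals), 99.5)
    if q == 0:
        raise ConfigError("degenerate profile: 99.5th percentile of |value| is zero")
    new_state = None if profile.state == "scaled" else "scaled"
    return profile.with_values(profile.values * (target_halfrange / q), state=new_state)
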