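"""Domain-level RT advance with wild-type baseline normalization.

In a hybrid line, the engineered (a1 = musculus/129) and control
(a2 = castaneus) alleles are assayed in the same cells, so the per-bin
allelic difference delta_w = RT_a1(w) - RT_a2(w) cancels everything shared
between alleles.  The alleles also differ naturally (the musculus allele
replicates slightly earlier in parts of the genome), so the advance
statistic subtracts the wild-type allelic baseline: per replicate r,

    A_r = mean over unmasked domain bins of [delta_mut,r(w) - delta_WT(w)]

where delta_WT(w) is the per-bin mean of the wild-type allelic difference
over its replicates.  The reported advance is the mean of A_r over
replicates; the error bar is their (min, max) range.

Per-window significance replaces the black-box tool the field sometimes
uses with a replicate label-permutation test: the observed statistic per
50-kb window is mean(mutant delta) - mean(WT delta); the null pools the
permuted statistics across windows (and, when fewer than three replicates
per group leave too few distinct permutations, augments the pool with the
observed baseline-subtracted deltas from windows outside annotated
switching domains).  Two-sided p-values get a Benjamini-Hochberg correction
across all tested windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, GridMismatchError, StateError
from .random import substream
from .rt import RTProfile

__all__ = [
    "RTAdvance",
    "allele_delta",
    "rt_advance",
    "window_significance",
    "domain_advance_report",
    "classify_rt_domains",
]


@dataclass
class RTAdvance:
    """Domain-level RT advance (log2 E/L units, pre-scaling)."""

    domain: tuple[str, int, int]
    delta: float
    replicate_range: tuple[float, float]
    per_replicate: tuple[float, ...]
    n_windows: int
    per_window: pd.DataFrame | None = None  # chrom,start,end,delta,p,q,significant

    def n_significant(self, within_domain: bool = True) -> int:
        """Count significant windows; by default restricted to the domain."""
        if self.per_window is None:
            raise ConfigError("per-window significance has not been computed")
        pw = self.per_window
        if within_domain:
            chrom, start, end = self.domain
            pw = pw[(pw["chrom"] == chrom) & (pw["start"] < end) & (pw["end"] > start)]
        return int(pw["significant"].fillna(False).sum())

    def to_frame(self) -> pd.DataFrame:
        chrom, start, end = self.domain
        return pd.DataFrame(
            [
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "delta": self.delta,
                    "range_lo": self.replicate_range[0],
                    "range_hi": self.replicate_range[1],
                    "n_windows": self.n_windows,
                    "n_significant": (
                        self.n_significant() if self.per_window is not None else np.nan
                    ),
                }
            ]
        )


def allele_delta(rt_a1: RTProfile, rt_a2: RTProfile) -> RTProfile:
    """Per-bin allelic difference a1 - a2; masked where either side is masked.

    Both profiles must be on the same grid and quantile-normalized but not
    scaled (scaling is display-only and would corrupt the statistic).
    """
    if not rt_a1.same_grid(rt_a2):
        raise GridMismatchError("allele profiles are not on the same bin grid")
    for p in (rt_a1, rt_a2):
        if p.state != "quantile_normalized":
            raise StateError(
                f"allele_delta requires quantile-normalized unscaled profiles, got {p.state!r}"
            )
    out = RTProfile(
        bins=rt_a1.bins,
        values=rt_a1.values - rt_a2.values,
        bin_size=rt_a1.bin_size,
        state="quantile_normalized",
        allele="a1-a2",
        replicate=rt_a1.replicate,
    )
    return out


def _delta_matrix(deltas: Sequence[RTProfile]) -> tuple[pd.DataFrame, np.ndarray]:
    if not deltas:
        raise ConfigError("no replicate delta profiles given")
    first = deltas[0]
    for d in deltas[1:]:
        if not first.same_grid(d):
            raise GridMismatchError("replicate delta profiles are not on the same grid")
    return first.bins, np.vstack([d.values for d in deltas])


def _domain_mask(bins: pd.DataFrame, domain: tuple[str, int, int]) -> np.ndarray:
    chrom, start, end = domain
    return ((bins["chrom"] == chrom) & (bins["start"] < end) & (bins["end"] > start)).to_numpy()


def rt_advance(
    mutant_deltas: Sequence[RTProfile],
    wt_deltas: Sequence[RTProfile],
    domain: tuple[str, int, int],
) -> RTAdvance:
    """The domain-level advance statistic with replicate-range error bars."""
    bins, mut = _delta_matrix(mutant_deltas)
    bins_wt, wt = _delta_matrix(wt_deltas)
    if not bins.reset_index(drop=True).equals(bins_wt.reset_index(drop=True)):
        raise GridMismatchError("mutant and WT deltas are not on the same grid")
    in_domain = _domain_mask(bins, domain)
    baseline = np.nanmean(wt, axis=0)  # per-bin WT allelic baseline
    per_rep = []
    for r in range(mut.shape[0]):
        contrast = mut[r] - baseline
        vals = contrast[in_domain & ~np.isnan(contrast)]
        if vals.size == 0:
            raise ConfigError("no unmasked bins in the domain for a replicate")
        per_rep.append(float(np.mean(vals)))
    per_rep_t = tuple(per_rep)
    return RTAdvance(
        domain=domain,
        delta=float(np.mean(per_rep_t)),
        replicate_range=(min(per_rep_t), max(per_rep_t)),
        per_replicate=per_rep_t,
        n_windows=int(np.sum(in_domain)),
    )


def window_significance(
    mutant_deltas: Sequence[RTProfile],
    wt_deltas: Sequence[RTProfile],
    n_permutations: int = 1000,
    seed: int = 0,
    exclude_intervals: Sequence[tuple[str, int, int]] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window permutation p-values and BH q-values for the RT change.

    The effect reported per window is mean(mutant delta) - mean(WT delta).
    For the test this difference is studentized, d_w = diff_w / (se_w + s0)
    with se_w the Welch standard error over replicates and s0 the median se
    across windows (a SAM-style damping constant): windows differ in
    sampling variance -- late-replicating bins have noisier log2 ratios
    than mid-S bins -- and pooling raw differences into one null would make
    the noisy windows anti-conservative.  The null is built by permuting
    replicate group labels and pooling the permuted statistics across
    windows *outside* ``exclude_intervals`` (annotated switching domains,
    where a genuine group difference may live: a window with a real shift
    produces permuted statistics at +-fractions of that shift, which would
    otherwise inflate the null and put a floor under every p-value).  With
    < 3 replicates in either group the pool is additionally augmented with
    the observed statistics of the outside windows.  Two-sided
    p = (1 + #{|null| >= |obs|}) / (1 + N); significant iff q < ``alpha``.
    """
    if n_permutations < 100:
        raise ConfigError("n_permutations must be >= 100")
    bins, mut = _delta_matrix(mutant_deltas)
    bins_wt, wt = _delta_matrix(wt_deltas)
    if not bins.reset_index(drop=True).equals(bins_wt.reset_index(drop=True)):
        raise GridMismatchError("mutant and WT deltas are not on the same grid")
    n_mut, n_wt = mut.shape[0], wt.shape[0]
    stacked = np.vstack([mut, wt])
    # only windows with a complete set of replicates are tested: a partially
    # masked window's statistic has a different noise scale than the null
    obs = mut.mean(axis=0) - wt.mean(axis=0)

    def _group_stats(members: np.ndarray, size: int, data: np.ndarray):
        """Group mean and unbiased variance per window for 0/1 membership rows."""
        mean = members @ data / size
        if size > 1:
            var = (members @ data**2 / size - mean**2) * size / (size - 1)
            var = np.maximum(var, 0.0)
        else:
            var = np.zeros_like(mean)
        return mean, var

    def _studentize(diff, var_m, var_w, s0):
        se = np.sqrt(var_m / n_mut + var_w / n_wt)
        return diff / (se + s0)

    ones_m = np.zeros((1, n_mut + n_wt))
    ones_m[0, :n_mut] = 1.0
    mean_m, var_m = _group_stats(ones_m, n_mut, stacked)
    mean_w, var_w = _group_stats(1.0 - ones_m, n_wt, stacked)
    se_obs = np.sqrt(var_m[0] / n_mut + var_w[0] / n_wt)
    s0 = float(np.nanmedian(se_obs))
    t_obs = _studentize(obs, var_m[0], var_w[0], s0)

    rng = substream(seed, "window_significance")
    total = n_mut + n_wt
    memb = np.zeros((n_permutations, total))
    for i in range(n_permutations):
        memb[i, rng.permutation(total)[:n_mut]] = 1.0
    # windows with any masked replicate are excluded from the pool entirely
    valid_cols = ~np.isnan(stacked).any(axis=0)
    outside = valid_cols.copy()
    for interval in exclude_intervals:
        outside &= ~_domain_mask(bins, interval)
    if not outside.any():  # degenerate: everything excluded, fall back to all windows
        outside = valid_cols
    data_out = stacked[:, outside]
    pm_m, pv_m = _group_stats(memb, n_mut, data_out)
    pm_w, pv_w = _group_stats(1.0 - memb, n_wt, data_out)
    null = _studentize(pm_m - pm_w, pv_m, pv_w, s0).ravel()

    if min(n_mut, n_wt) < 3:
        null = np.concatenate([null, t_obs[outside]])

    null_abs = np.sort(np.abs(null))
    tested = ~np.isnan(obs)
    p = np.full(len(obs), np.nan)
    # count of |null| >= |obs| via searchsorted on the sorted pool
    ge = null_abs.size - np.searchsorted(null_abs, np.abs(t_obs[tested]), side="left")
    p[tested] = (1.0 + ge) / (1.0 + null_abs.size)

    q = np.full(len(obs), np.nan)
    signif = np.zeros(len(obs), dtype=bool)
    if tested.any():
        rej, q_vals, _, _ = multipletests(p[tested], alpha=alpha, method="fdr_bh")
        q[tested] = q_vals
        signif[tested] = rej
    out = bins.copy()
    out["delta"] = obs
    out["p"] = p
    out["q"] = q
    out["significant"] = signif
    return out


def domain_advance_report(
    mutant_deltas: Sequence[RTProfile],
    wt_deltas: Sequence[RTProfile],
    domain: tuple[str, int, int],
    n_permutations: int = 1000,
    seed: int = 0,
    exclude_intervals: Sequence[tuple[str, int, int]] = (),
    alpha: float = 0.05,
) -> RTAdvance:
    """rt_advance plus per-window significance in one report."""
    adv = rt_advance(mutant_deltas, wt_deltas, domain)
    adv.per_window = window_significance(
        mutant_deltas,
        wt_deltas,
        n_permutations=n_permutations,
        seed=seed,
        exclude_intervals=exclude_intervals,
        alpha=alpha,
    )
    return adv


def classify_rt_domains(
    state1: RTProfile,
    state2: RTProfile,
    domains: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Classify domains as CE / DE / CL / DL from two-state reference RT.

    A domain is early in a state iff its mean RT there is > 0.  Signs
    agreeing gives a constitutive class (CE/CL); signs disagreeing gives a
    developmental class named by the second (differentiated) state: DE when
    it becomes early, DL when it becomes late.
    """
    if state1 is None or state2 is None:
        raise ConfigError("both cell-state profiles are required")
    if not state1.same_grid(state2):
        raise GridMismatchError("state profiles are not on the same grid")
    rows = []
    for domain in domains:
        mask = _domain_mask(state1.bins, domain)
        if not mask.any():
            raise ConfigError(f"domain {domain} contains no bins")
        m1 = float(np.nanmean(state1.values[mask]))
        m2 = float(np.nanmean(state2.values[mask]))
        early1, early2 = m1 > 0, m2 > 0
        if early1 == early2:
            cls = "CE" if early2 else "CL"
        else:
            cls = "DE" if early2 else "DL"
        rows.append({"chrom": domain[0], "start": domain[1], "end": domain[2],
                     "mean_rt_state1": m1, "mean_rt_state2": m2, "class": cls})
    return pd.DataFrame(rows)
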