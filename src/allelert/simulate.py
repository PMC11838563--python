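"""Synthetic hybrid-genome data with known ground truth.

The generator emulates the experimental design of an F1 hybrid (129 x
castaneus) mouse ESC line: dense diagnostic SNPs allow reads to be assigned
to parental alleles, one allele carries an engineered perturbation inside a
late-replicating domain, and the other allele serves as an internal control.
It produces

* a diagnostic SNP table with exponential inter-SNP spacing,
* allele-tagged binned early/late Repli-Seq counts with replicates,
* per-gene per-allele nascent-RNA (Bru-Seq-like) counts, and
* FASTQ reads carrying exact 16-nt reporter barcodes,

together with a :class:`SimTruth` record from which every downstream
estimator's expectation can be computed, so the analysis stages are testable
without external sequencing data.

Generative model for Repli-Seq counts
-------------------------------------
A latent replication-timing landscape ``true_rt(chrom, pos) in [-1, +1]``
(+1 = earliest) is mapped to the probability that an allele-assignable read
from a bin comes from the early fraction through a logistic link
``p = sigma(k * true_rt)``.  Total reads per bin per allele are Poisson; a
read is allele-assignable when it covers at least one diagnostic SNP, which
for exponential spacing with mean ``s`` and read length ``L`` happens with
probability ``1 - exp(-L/s)``.  Early counts are Binomial(assignable, p) and
late counts the complement, so marginally early and late counts are
independent Poissons -- which is what makes closed-form propagation of the
latent landscape through the sampling noise cheap (see
:func:`expected_rt_profile`).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import write_fastq
from .random import substream

__all__ = [
    "GenomeSpec",
    "Domain",
    "RTLandscape",
    "SimTruth",
    "simulate_snp_table",
    "simulate_repliseq",
    "simulate_bruseq",
    "simulate_barcode_fastq",
    "expected_log2_poisson",
    "expected_rt_profile",
    "expected_advance",
]

ALLELES = ("a1", "a2")  # a1 = musculus/129 (engineered), a2 = castaneus
FRACTIONS = ("early", "late")

# default latent RT level per domain label, ESC state
_LEVELS_ESC = {"constitutive_early": 0.75, "constitutive_late": -0.75, "switching": -0.75}
_LEVELS_NPC = {"constitutive_early": 0.75, "constitutive_late": -0.75, "switching": 0.75}


def _sigmoid(x):
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class GenomeSpec:
    """A miniature hybrid genome.

    snp_spacing_mean is the mean exponential inter-SNP distance in bp
    (~150 bp for a 129 x castaneus hybrid); ``None`` or ``inf`` means no
    SNPs, i.e. no read is allele-assignable.
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_spacing_mean: float | None = 150.0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigError("at least one chromosome is required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        spacing = self.snp_spacing_mean
        if spacing is not None and not math.isinf(spacing) and spacing <= 0:
            raise ConfigError(f"snp_spacing_mean must be > 0, got {spacing}")
        if self.read_length <= 0:
            raise ConfigError("read_length must be > 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def assignable_fraction(self) -> float:
        """P(read covers >= 1 SNP) = 1 - exp(-read_length / spacing)."""
        spacing = self.snp_spacing_mean
        if spacing is None or math.isinf(spacing):
            return 0.0
        return 1.0 - math.exp(-self.read_length / spacing)


def simulate_snp_table(genome_spec: GenomeSpec) -> pd.DataFrame:
    """Draw diagnostic SNP positions with exponential inter-SNP spacing.

    Returns columns (chrom, pos, allele1_base, allele2_base); positions are
    sorted and unique per chromosome, and the two base labels differ at
    every SNP.  Deterministic in ``genome_spec.seed``.
    """
    spacing = genome_spec.snp_spacing_mean
    rng = substream(genome_spec.seed, "snp_table")
    bases = np.array(list("ACGT"))
    frames = []
    if spacing is None or math.isinf(spacing):
        return pd.DataFrame(columns=["chrom", "pos", "allele1_base", "allele2_base"])
    for chrom, length in genome_spec.chromosomes:
        positions: list[np.ndarray] = []
        pos = 0.0
        # draw gaps in blocks until past the chromosome end
        expected = max(int(length / spacing * 1.2) + 16, 16)
        while pos < length:
            gaps = rng.exponential(spacing, size=expected)
            cum = pos + np.cumsum(gaps)
            positions.append(cum[cum < length])
            pos = cum[-1]
        all_pos = np.unique(np.floor(np.concatenate(positions)).astype(np.int64))
        all_pos = all_pos[(all_pos >= 0) & (all_pos < length)]
        a1 = rng.integers(0, 4, size=all_pos.size)
        a2 = (a1 + rng.integers(1, 4, size=all_pos.size)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": all_pos,
                    "allele1_base": bases[a1],
                    "allele2_base": bases[a2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class Domain:
    """An annotated replication-domain interval.

    label is one of constitutive_early / constitutive_late / switching;
    ``level`` overrides the default latent RT level for the label.
    """

    chrom: str
    start: int
    end: int
    label: str
    level: float | None = None

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class RTLandscape:
    """Per-allele piecewise-smooth latent RT landscape in [-1, +1].

    The background varies as a triangle wave along each chromosome, so bin
    values sweep the whole dynamic range and cover it uniformly (RT profiles
    ramp between early and late regions rather than sitting at the
    extremes); annotated domains override the background locally with
    logistic edge tapers of width ``transition_bp``.
    ``advance_delta`` (>= 0) is added to ``advance_allele`` inside
    ``advance_domain`` -- the engineered perturbation.  ``allelic_offset``
    models the natural tendency of the musculus allele to replicate slightly
    earlier inside the target domain and is added to allele a1 inside
    ``offset_domain`` (defaults to the advance domain) in *both* engineered
    and wild-type simulations, so the baseline-normalization step downstream
    has something real to remove.  ``state`` selects the cell state for
    switching domains ("esc": late, "npc": early).
    """

    genome: GenomeSpec
    domains: tuple[Domain, ...] = ()
    background_amplitude: float = 0.6
    background_period: float = 4e6
    transition_bp: float = 100_000.0
    advance_delta: float = 0.0
    advance_domain: tuple[str, int, int] | None = None
    advance_allele: str = "a1"
    allelic_offset: float = 0.0
    offset_domain: tuple[str, int, int] | None = None
    state: str = "esc"

    def __post_init__(self):
        if self.advance_delta < 0:
            raise ConfigError("advance_delta must be >= 0")
        if self.advance_delta > 0 and self.advance_domain is None:
            raise ConfigError("advance_delta > 0 requires an advance_domain")
        if self.advance_allele not in ALLELES:
            raise ConfigError(f"advance_allele must be one of {ALLELES}")
        if self.state not in ("esc", "npc"):
            raise ConfigError("state must be 'esc' or 'npc'")

    def npc_view(self) -> "RTLandscape":
        """The same landscape in the differentiated (NPC) state."""
        return replace(self, state="npc")

    def _taper(self, pos: np.ndarray, start: int, end: int) -> np.ndarray:
        w = max(self.transition_bp / 4.0, 1.0)
        return _sigmoid((pos - start) / w) * _sigmoid((end - pos) / w)

    def _phase(self, chrom: str) -> float:
        # deterministic per-chromosome phase so chromosomes are not in lockstep
        return (sum(ord(c) for c in chrom) % 17) / 17.0

    def true_rt(self, chrom: str, pos, allele: str) -> np.ndarray:
        """Evaluate the latent RT of ``allele`` at positions ``pos``."""
        if allele not in ALLELES:
            raise ConfigError(f"unknown allele {allele!r}")
        pos = np.asarray(pos, dtype=float)
        levels = _LEVELS_ESC if self.state == "esc" else _LEVELS_NPC
        t = pos / self.background_period + self._phase(chrom)
        value = self.background_amplitude * (4 * np.abs(t - np.floor(t + 0.5)) - 1)
        for dom in self.domains:
            if dom.chrom != chrom:
                continue
            level = dom.level if dom.level is not None else levels[dom.label]
            tap = self._taper(pos, dom.start, dom.end)
            value = value * (1 - tap) + level * tap
        if allele == self.advance_allele:
            offset_domain = self.offset_domain or self.advance_domain
            if self.allelic_offset != 0.0 and offset_domain is not None:
                dchrom, dstart, dend = offset_domain
                if dchrom == chrom:
                    value = value + self.allelic_offset * self._taper(pos, dstart, dend)
            if self.advance_delta != 0.0 and self.advance_domain is not None:
                dchrom, dstart, dend = self.advance_domain
                if dchrom == chrom:
                    value = value + self.advance_delta * self._taper(pos, dstart, dend)
        return np.clip(value, -1.0, 1.0)

    def switching_intervals(self) -> list[tuple[str, int, int]]:
        out = [d.as_tuple() for d in self.domains if d.label == "switching"]
        if self.advance_domain is not None and self.advance_domain not in out:
            out.append(self.advance_domain)
        return out


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    Sufficient to compute the expectation of every downstream estimator:
    per-bin latent RT and early-fraction probability per allele, the
    sampling depth and link steepness, plus (when the corresponding
    generator ran) transcription rates and barcode abundances.
    """

    bins: pd.DataFrame  # chrom, start, end
    true_rt: dict[str, np.ndarray]  # allele -> latent RT per bin
    p_early: dict[str, np.ndarray]  # allele -> P(early) per bin
    k: float
    depth_per_fraction: float
    assignable_fraction: float
    bin_size: int
    n_replicates: int
    advance_delta: float
    advance_domain: tuple[str, int, int] | None
    allelic_offset: float
    seed: int
    transcription_rates: pd.DataFrame | None = None
    barcode_abundance: pd.DataFrame | None = None

    def expected_library_size(self, fraction: str) -> float:
        """Expected total reads of one fraction library (all alleles, incl. unassigned)."""
        p_assign = self.assignable_fraction
        total = 0.0
        for allele in ALLELES:
            lam_tot = 2.0 * self.depth_per_fraction / p_assign
            p = self.p_early[allele]
            q = p if fraction == "early" else 1.0 - p
            total += float(np.sum(lam_tot * q))
        return total

    def expected_rt(self, allele: str, pseudocount: float = 0.1) -> np.ndarray:
        """Expected raw log2(E/L) per bin, numerically propagated (see module docs)."""
        return expected_rt_profile(
            self.p_early[allele],
            self.depth_per_fraction,
            pseudocount,
            self.expected_library_size("early"),
            self.expected_library_size("late"),
        )

    def domain_mask(self, domain: tuple[str, int, int]) -> np.ndarray:
        chrom, start, end = domain
        b = self.bins
        return ((b["chrom"] == chrom) & (b["start"] < end) & (b["end"] > start)).to_numpy()

    def to_text(self) -> str:
        buf = _io.StringIO()
        buf.write(f"# SimTruth seed={self.seed} k={self.k} depth={self.depth_per_fraction}")
        buf.write(f" assignable={self.assignable_fraction:.10g} bin_size={self.bin_size}")
        buf.write(f" advance_delta={self.advance_delta} allelic_offset={self.allelic_offset}\n")
        table = self.bins.copy()
        for allele in ALLELES:
            table[f"true_rt_{allele}"] = self.true_rt[allele]
            table[f"p_early_{allele}"] = self.p_early[allele]
        table.to_csv(buf, sep="\t", index=False, float_format="%.10g")
        return buf.getvalue()


def _bin_grid(genome: GenomeSpec, bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.chromosomes:
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def simulate_repliseq(
    rt_landscape: RTLandscape,
    depth_per_fraction: float = 30.0,
    n_replicates: int = 2,
    bin_size: int = 50_000,
    seed: int = 0,
    k: float = 2.0,
):
    """Simulate allele-tagged binned E/L Repli-Seq counts.

    depth_per_fraction is the expected number of allele-assignable reads per
    fraction per bin per allele at neutral RT.  Returns ``(counts, truth)``
    where ``counts`` is a :class:`allelert.rt.BinnedCounts` and ``truth`` a
    :class:`SimTruth`.  Unassignable reads (those covering no diagnostic
    SNP) are emitted under allele ``"unassigned"``; per bin,
    assignable + unassignable = total simulated reads.
    """
    from .rt import BinnedCounts  # local import to avoid a cycle

    if depth_per_fraction <= 0:
        raise ConfigError("depth_per_fraction must be > 0")
    if bin_size <= 0:
        raise ConfigError("bin_size must be > 0")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    genome = rt_landscape.genome
    p_assign = genome.assignable_fraction
    if p_assign <= 0:
        raise ConfigError("no diagnostic SNPs: assignable fraction is zero")

    rng = substream(seed, "repliseq")
    bins = _bin_grid(genome, bin_size)
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    chroms = bins["chrom"].to_numpy()

    true_rt: dict[str, np.ndarray] = {}
    p_early: dict[str, np.ndarray] = {}
    for allele in ALLELES:
        vals = np.empty(len(bins))
        for chrom, _ in genome.chromosomes:
            sel = chroms == chrom
            vals[sel] = rt_landscape.true_rt(chrom, mids[sel], allele)
        true_rt[allele] = vals
        p_early[allele] = _sigmoid(k * vals)

    lam_tot = 2.0 * depth_per_fraction / p_assign
    frames = []
    n_bins = len(bins)
    for rep in range(1, n_replicates + 1):
        unassigned = {"early": np.zeros(n_bins, dtype=np.int64),
                      "late": np.zeros(n_bins, dtype=np.int64)}
        for allele in ALLELES:
            p = p_early[allele]
            total = rng.poisson(lam_tot, size=n_bins)
            assignable = rng.binomial(total, p_assign)
            early = rng.binomial(assignable, p)
            late = assignable - early
            un = total - assignable
            un_early = rng.binomial(un, p)
            unassigned["early"] += un_early
            unassigned["late"] += un - un_early
            for fraction, counts in (("early", early), ("late", late)):
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": bins["chrom"],
                            "start": bins["start"],
                            "end": bins["end"],
                            "allele": allele,
                            "fraction": fraction,
                            "replicate": rep,
                            "count": counts,
                        }
                    )
                )
        for fraction in FRACTIONS:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": bins["chrom"],
                        "start": bins["start"],
                        "end": bins["end"],
                        "allele": "unassigned",
                        "fraction": fraction,
                        "replicate": rep,
                        "count": unassigned[fraction],
                    }
                )
            )
    counts = BinnedCounts(pd.concat(frames, ignore_index=True), bin_size=bin_size)
    truth = SimTruth(
        bins=bins,
        true_rt=true_rt,
        p_early=p_early,
        k=k,
        depth_per_fraction=depth_per_fraction,
        assignable_fraction=p_assign,
        bin_size=bin_size,
        n_replicates=n_replicates,
        advance_delta=rt_landscape.advance_delta,
        advance_domain=rt_landscape.advance_domain,
        allelic_offset=rt_landscape.allelic_offset,
        seed=seed,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# numeric propagation of the latent landscape through the sampling model

def expected_log2_poisson(lam, alpha: float) -> np.ndarray:
    """E[log2(X + alpha)] for X ~ Poisson(lam), computed by direct summation."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if alpha <= 0:
        raise ConfigError("alpha must be > 0 (log2 of zero otherwise)")
    xmax = int(np.max(lam) + 12 * math.sqrt(max(np.max(lam), 1.0)) + 25)
    x = np.arange(0, xmax + 1)
    pmf = stats.poisson.pmf(x[None, :], lam[:, None])
    return np.sum(pmf * np.log2(x[None, :] + alpha), axis=1)


def expected_rt_profile(
    p_early: np.ndarray,
    depth_per_fraction: float,
    pseudocount: float,
    lib_early: float,
    lib_late: float,
) -> np.ndarray:
    """Expected raw log2 CPM ratio per bin under the sampling model.

    Early and late counts are marginally independent Poissons with means
    2*d*p and 2*d*(1-p); the CPM pseudocount translates into read units
    through the expected library size of each fraction.
    """
    d = depth_per_fraction
    s_e = 1e6 / lib_early
    s_l = 1e6 / lib_late
    alpha_e = pseudocount / s_e
    alpha_l = pseudocount / s_l
    e_term = expected_log2_poisson(2 * d * np.asarray(p_early), alpha_e)
    l_term = expected_log2_poisson(2 * d * (1 - np.asarray(p_early)), alpha_l)
    return e_term - l_term + math.log2(s_e) - math.log2(s_l)


def expected_advance(
    truth_mut: SimTruth,
    truth_wt: SimTruth,
    domain: tuple[str, int, int],
    pseudocount: float = 0.1,
) -> float:
    """Expected RT-advance statistic, numerically propagated.

    Mean over domain bins of the engineered line's expected allelic
    difference minus the wild type's -- the same contrast the estimator
    computes on sampled counts.
    """
    mask = truth_mut.domain_mask(domain)
    if not mask.any():
        raise ConfigError("domain contains no bins")
    mut = truth_mut.expected_rt("a1", pseudocount) - truth_mut.expected_rt("a2", pseudocount)
    wt = truth_wt.expected_rt("a1", pseudocount) - truth_wt.expected_rt("a2", pseudocount)
    return float(np.mean(mut[mask] - wt[mask]))


# ---------------------------------------------------------------------------
# nascent transcription (Bru-Seq-like)

def simulate_bruseq(
    gene_annotations: pd.DataFrame,
    rates: Mapping[tuple[str, str], float],
    library_scale: float = 1.0,
    n_replicates: int = 2,
    seed: int = 0,
    readthrough: tuple[str, str, float] | None = None,
) -> pd.DataFrame:
    """Simulate per-gene per-allele nascent read counts.

    ``gene_annotations`` needs columns (gene, chrom, start, end, strand);
    ``rates`` maps (gene, allele) -> expected nascent reads per kb per unit
    library scale.  Counts are Poisson(rate * length_kb * library_scale).
    ``readthrough=(reporter, downstream, fraction)`` adds
    ``fraction * reporter_rate`` to the downstream interval's rate,
    emulating transcriptional read-through past the reporter's polyA site.
    Returns a tidy frame (gene, allele, replicate, count, rate).
    """
    if library_scale <= 0:
        raise ConfigError("library_scale must be > 0")
    rng = substream(seed, "bruseq")
    genes = gene_annotations.set_index("gene")
    eff: dict[tuple[str, str], float] = {}
    for (gene, allele), rate in rates.items():
        if rate < 0:
            raise ConfigError(f"negative rate for {(gene, allele)}")
        if gene not in genes.index:
            raise ConfigError(f"rate given for unannotated gene {gene!r}")
        eff[(gene, allele)] = float(rate)
    if readthrough is not None:
        reporter, downstream, fraction = readthrough
        if fraction < 0:
            raise ConfigError("readthrough fraction must be >= 0")
        for allele in ALLELES:
            base = eff.get((reporter, allele), 0.0)
            eff[(downstream, allele)] = eff.get((downstream, allele), 0.0) + fraction * base
    rows = []
    for (gene, allele), rate in sorted(eff.items()):
        length_kb = (genes.loc[gene, "end"] - genes.loc[gene, "start"]) / 1000.0
        lam = rate * length_kb * library_scale
        counts = rng.poisson(lam, size=n_replicates)
        for rep in range(1, n_replicates + 1):
            rows.append((gene, allele, rep, int(counts[rep - 1]), rate))
    return pd.DataFrame(rows, columns=["gene", "allele", "replicate", "count", "rate"])


# ---------------------------------------------------------------------------
# barcoded reporter reads

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_barcode_fastq(
    barcode_manifest: pd.DataFrame,
    abundances: Sequence[float],
    n_reads: int,
    seed: int = 0,
    path: str | None = None,
    read_length: int = 50,
    background_fraction: float = 0.3,
):
    """Simulate FASTQ reads carrying exact 16-nt barcodes.

    Non-background reads embed one manifest barcode at a random offset, at
    multinomial frequencies proportional to ``abundances``; each embedded
    read is rejection-checked to contain no *other* manifest barcode, and
    background reads are rejection-checked to contain none at all, so exact
    substring counting recovers the truth table exactly.

    Returns ``(records, truth_counts)`` where ``truth_counts`` is a Series
    of realized embedded counts per barcode_id.  If ``path`` is given the
    records are also written there.
    """
    seqs = barcode_manifest["sequence"].tolist()
    ids = barcode_manifest["barcode_id"].tolist()
    if len(set(seqs)) != len(seqs):
        raise ConfigError("duplicate barcode sequences in manifest")
    for s in seqs:
        if len(s) != 16 or set(s) - set("ACGT"):
            raise ConfigError(f"barcode {s!r} is not a 16-nt ACGT string")
    abundances = np.asarray(abundances, dtype=float)
    if abundances.size != len(seqs):
        raise ConfigError("abundances length must match manifest")
    if (abundances < 0).any():
        raise ConfigError("abundances must be >= 0")
    if not 0 <= background_fraction <= 1:
        raise ConfigError("background_fraction must be in [0, 1]")
    if read_length < 16:
        raise ConfigError("read_length must be >= 16")

    rng = substream(seed, "barcode_fastq")
    total = abundances.sum()
    if total == 0:
        probs = np.zeros(len(seqs) + 1)
        probs[-1] = 1.0
    else:
        probs = np.append(abundances / total * (1 - background_fraction), background_fraction)
    assignment = rng.choice(len(seqs) + 1, size=n_reads, p=probs)

    records = []
    truth = np.zeros(len(seqs), dtype=np.int64)
    qual = "I" * read_length
    for i, a in enumerate(assignment):
        if a < len(seqs):
            barcode = seqs[a]
            others = [s for j, s in enumerate(seqs) if j != a]
            while True:
                offset = int(rng.integers(0, read_length - 16 + 1))
                read = (
                    _random_seq(rng, offset)
                    + barcode
                    + _random_seq(rng, read_length - 16 - offset)
                )
                if not any(o in read for o in others):
                    break
            truth[a] += 1
            name = f"read{i}_bc_{ids[a]}"
        else:
            while True:
                read = _random_seq(rng, read_length)
                if not any(s in read for s in seqs):
                    break
            name = f"read{i}_bg"
        records.append((name, read, qual))
    if path is not None:
        write_fastq(records, path)
    truth_counts = pd.Series(truth, index=pd.Index(ids, name="barcode_id"), name="count")
    return records, truth_counts
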