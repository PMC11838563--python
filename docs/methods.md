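# Methods

This note documents the models, estimators and numerical choices in
`allelert`, and what the simulation-based tests do and do not establish.

## Experimental design being modeled

An F1 hybrid mESC line (129 × castaneus) carries diagnostic SNPs at a mean
spacing of ~150 bp. E/L Repli-Seq sorts BrdU-labeled cells into early- and
late-S fractions and sequences nascent DNA from each; Bru-Seq sequences
nascent RNA after a short bromouridine pulse, measuring transcription rate
rather than steady-state abundance. Engineering (promoter insertion,
inducible activation, promoter/enhancer deletion) is done on one allele —
by convention allele `a1`, the musculus/129 allele — while `a2`
(castaneus) remains an internal control in the same cells.

## Synthetic data generator

**Latent landscape.** `true_rt(chrom, pos) ∈ [−1, +1]` (+1 = earliest) is
a triangle-wave background (default amplitude 0.6, period 4 Mb) locally
overridden by annotated domains (constitutive early +0.75, late −0.75;
switching domains are late in the ESC state and early in the NPC state)
with logistic edge tapers (default 100 kb). The triangle background makes
bin values sweep the dynamic range with uniform coverage — RT profiles
ramp between early and late plateaus — which also keeps the rank map of
quantile normalization well conditioned at desk-scale genome sizes; a
value distribution piled at the extremes (e.g. a sinusoid's arcsine law)
starves the mid-range of reference quantiles and attenuates recovered
shifts when the perturbed domain is a non-negligible fraction of all bins.

**Perturbations.** `advance_delta ≥ 0` is added to `a1` inside the
designated domain (the engineered advance). A natural allelic offset
(default 0.1 latent units, matching the observation that the musculus
allele replicates slightly earlier) is added to `a1` inside the target
domain in *both* wild-type and engineered simulations, so the baseline
normalization downstream has something real to remove. Values are clipped
to [−1, 1].

**Sampling model.** Per bin, per allele, per replicate, total reads are
Poisson with mean `2·d / p_assign`, where `d` is the expected number of
assignable reads per fraction per bin at neutral RT (default 30; the
depth after allele-splitting is not something the assay fixes, so this is
a free parameter chosen to be informative without being generous) and
`p_assign = 1 − exp(−read_length/spacing)` is the analytic probability
that a read covers ≥ 1 SNP (≈ 0.487 at 100 bp / 150 bp). Assignable reads
are a binomial thinning of the total; early counts are
Binomial(assignable, p) with the logistic link `p = σ(k·true_rt)`
(default k = 2; the link is the simplest monotone map from a bounded
latent to a probability, and k sets how sharply RT differences separate
the fractions), and late counts are the complement. Unassignable reads
are emitted under allele `unassigned`, so assignable + unassignable =
total. The Poisson–binomial composition makes marginal early and late
counts independent Poissons — which is what the propagation oracle
exploits (below).

**Truth table.** `SimTruth` records per-bin latent RT and early
probability per allele plus all sampling parameters;
`SimTruth.expected_rt` propagates the latent landscape through the full
sampling + log2-CPM measurement numerically (`E[log2(X+α)]` by direct
Poisson summation), and `expected_advance` propagates it through the
advance contrast. Tests compare estimates to these propagated
expectations, never to hard-coded constants.

**Bru-Seq and barcodes.** Gene counts are Poisson(rate × length_kb ×
library_scale) per allele per replicate; an optional read-through mode
adds a configurable fraction of a reporter's rate to a downstream
interval. Barcode FASTQ reads embed exact 16-nt barcodes at multinomial
frequencies; embedded reads are rejection-checked to contain no *other*
manifest barcode and background reads to contain none at all, so exact
substring counting recovers the embedded truth exactly.

## Estimators

**RT profile.** Reads are binned by 5′ start (0-based half-open; 50-kb
windows for statistics, 5-kb for display). RT = log2((E_cpm + 0.1)/(L_cpm
+ 0.1)) with counts-per-million computed within each (fraction, replicate)
library across all alleles — allele splitting happens downstream of
sequencing. The 0.1-cpm pseudocount prevents infinities while leaving
high-coverage bins essentially unchanged; bins with E+L < 10 raw reads
per allele are masked. Fine-grained (5-kb) counts aggregate exactly to
the 50-kb model (Poisson sums), so display tracks and statistics can come
from one simulated dataset.

**Quantile normalization.** Each per-allele per-replicate profile is
mapped rank-for-rank onto the wild-type reference. The reference is the
average quantile function of the per-allele per-replicate WT profiles —
the standard multi-sample construction — rather than a profile of pooled
counts: pooling makes the reference's sampling noise narrower than any
single sample's, and rank-mapping onto a narrower distribution compresses
every sample's tails. Ties take the mean of the tied reference quantiles;
masked bins are excluded from ranks and stay masked. When sample and
reference have equally many unmasked bins, the output's sorted values
equal the reference's exactly.

**Display path.** 5-kb profiles are smoothed with a centered 300-kb
sliding mean (mask-aware, truncated at chromosome edges; a span names a
window, and an unweighted mean is the simplest span-parameterized
smoother) and linearly rescaled so the 99.5th percentile of |value| hits
3.0 — one concrete realization of bringing a ~(−7, 7) raw range to
~(−3, 3) for track display. A forward-only state machine (raw →
quantile_normalized → smoothed → scaled) makes it impossible to feed a
scaled track into the statistics path.

**RT advance.** Per replicate, the domain mean of
(a1 − a2) − baselineWT, where baselineWT is the per-window mean WT allelic
difference across WT replicates; the reported advance is the mean over
replicates and the error bar their (min, max) range, following the
replicate-range convention for this assay's error bars.

**Per-window significance.** The per-window effect is the difference of
group means. For testing, each window's difference is studentized,
`d = diff / (SE + s0)` with the Welch standard error over replicates and
`s0` the median SE across windows: windows differ in sampling variance
(a late bin's log2 ratio is noisier than a mid-S bin's), and pooling raw
differences into a common null would make the noisy windows
anti-conservative. The null is built by permuting replicate group labels
and pooling the permuted statistics across windows *outside* annotated
switching domains — windows that may carry a real group difference would
otherwise inject ±fractions of their shift into the null and put a floor
under every p-value. With fewer than three replicates per group the pool
is augmented with the observed outside-window statistics. Two-sided
p = (1 + #{|null| ≥ |obs|})/(1 + N), Benjamini–Hochberg across tested
windows, significant iff q < 0.05. Windows with any masked replicate are
not tested. A genuinely genome-wide shift is unidentifiable by any
label-permutation scheme (no exchangeable windows remain); the procedure
assumes the annotated domains delimit where real shifts can live.

**Transcription.** Interval counts are strand-aware 5′-end counts
(reverse-stranded by default, matching directional nascent-RNA
protocols). RPM = count·1e6/library; RPKM = RPM·1e3/length.
Read-through = downstream RPKM / reporter RPKM (0 when both are silent;
an error when only the reporter is). The differential test uses
median-of-ratios size factors (robust to a minority of truly changed
genes; plain totals would leak their signal into every null gene), log2FC
of size-factor-normalized means with pseudocount 1, and a two-sided
conditional-binomial exact Poisson rate test on summed counts with the
null proportion set by the summed size factors, BH-corrected. This is a
transparent presence-of-difference test, not a shrinkage estimator of
effect sizes; a negative-binomial reference implementation is used as an
independent cross-check in the test suite. Barcodes are counted by exact
substring match, forward-strand only by default (a flag adds the reverse
complement); a read matching two distinct barcodes counts for neither and
is logged.

**Association.** Spearman rank correlation of per-condition advance
against per-condition nascent expression (a dose response that plateaus
breaks linearity, so Pearson would be wrong on purpose); constant input
yields NA with a warning rather than an error. Plateau onset is the
smallest covariate beyond which successive advances differ by less than
10% of the maximum advance — descriptive only. The reversibility report
calls a withdrawal experiment reversible iff the withdrawn arm's
replicate range overlaps the never-induced baseline's range and its count
of significant windows within the assayed domain has returned to at most
the baseline's. The domain restriction is deliberate: the question is
whether the domain returned to baseline, and a genome-wide count would be
dominated by unrelated multiple-testing noise.

## Scenario choices and problem sizes

The canonical scenarios (`allelert.scenarios`) use one 20-Mb chromosome
with a 2-Mb switching domain (400 statistics windows, 40 in-domain),
~30 assignable reads/fraction/50-kb bin, k = 2, offset 0.1, and three
replicates — small enough to run in seconds while leaving per-window
noise realistic. Null calibration uses 10,000 windows (a 500-Mb
chromosome) and 1,000 permutations. The withdrawal scenario uses five
replicates per arm: the replicate-range overlap of two n-point ranges of
iid continuous estimates is 1 − 2/C(2n, n) regardless of noise scale —
only 2/3 at n = 2 — so a two-replicate design cannot support a
range-overlap reversibility call; n = 5 brings the false-irreversible
rate from range disjointness to ~0.8%.

## What the simulations do and do not show

The generator reproduces the design's statistical skeleton: allele
assignability, binomial/Poisson fraction sampling, replicate structure,
domain-shaped landscapes, a coupled or uncoupled transcription–advance
relationship, barcoded reporters with clean backgrounds. It deliberately
omits alignment artifacts, mappability and GC biases, PCR duplicates,
copy-number variation, cell-cycle sorting impurity, and any real genome
sequence. Passing tests therefore establish that the estimators recover
what this model generates at these depths — calibration and power claims
transfer to real data only to the extent the noise model does.

## Known limitations

- Quantile normalization on desk-scale genomes still attenuates large
  shifts slightly (the perturbed domain is 10% of all bins here versus
  ~0.1% genome-wide); recovery tests budget ±20% for this.
- With two replicates, per-window power is limited and the
  genome-wide-null augmentation (not pure permutation) carries the test.
- The exact-Poisson differential test is anti-conservative under
  biological overdispersion; it is meant for the simulator's Poisson
  counts and for presence/absence calls, not effect-size inference.
- Domain boundaries are inputs (BED intervals); there is no domain or
  initiation-zone calling.
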