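# allelert

Allele-resolved replication-timing (RT) and nascent-transcription analysis
for hybrid-genome E/L Repli-Seq and Bru-Seq experiments, with a
ground-truth simulator of the whole experimental design.

## The problem

In an F1 hybrid cell line (e.g. *Mus musculus* 129 × *castaneus* mESCs),
diagnostic SNPs occur roughly every 150 bp, so a sequencing read that
covers at least one SNP can be assigned to its parental allele. Engineering
one allele — say, inserting an inducible promoter upstream of a silent,
late-replicating gene — leaves the homologous allele in the same cells as
an internal control. This package quantifies whether (and by how much) the
engineered allele's replication timing advanced, and whether that advance
tracks the rate of nascent transcription.

For users: computational biologists analysing allele-phased binned
Repli-Seq counts, nascent-RNA (Bru-Seq) counts, and barcoded-reporter
FASTQ data — or anyone who wants a fully testable, simulated stand-in for
such an experiment.

## The statistics

Per 50-kb window *w*, allele *a*, replicate *r*:

```
RT_{a,r}(w) = log2( (E_cpm + c) / (L_cpm + c) )        c = 0.1 cpm
```

with E/L the early/late S-phase fraction coverages (counts per million
within each fraction library), masked below 10 reads of E+L coverage.
Each profile is quantile-normalized to the wild-type reference (the
average quantile function of the per-allele per-replicate WT profiles).
The domain-level **RT advance** normalizes the allelic difference to the
wild-type allelic baseline:

```
A_r   = mean_{w in domain} [ (RT_a1,r − RT_a2,r)(w) − deltaWT(w) ]
delta = mean_r A_r ,   error bar = (min_r A_r, max_r A_r)
```

where `deltaWT(w)` is the mean wild-type allelic difference per window —
the musculus allele naturally replicates slightly earlier in places, and
this subtraction removes that. Per-window significance uses a replicate
label-permutation test on studentized differences with a genome-wide
pooled null (annotated switching domains excluded from the pool) and
Benjamini–Hochberg correction at q < 0.05.

Nascent transcription is quantified as strand-aware 5′-end counts per
annotated interval (RPM/RPKM); reporter barcodes are counted by exact
16-nt substring matching; the association stage reports the Spearman rank
correlation of RT advance against nascent expression across conditions,
with a descriptive plateau onset, and a reversibility report for
inducer-withdrawal experiments.

The simulator draws binned counts from the generative model
`p(early) = σ(k · true_rt)` with independent-Poisson bin totals and
analytic allele-assignability `1 − exp(−read_length/snp_spacing)`, and
emits a truth table from which the expectation of every estimator can be
computed by numeric propagation.

## Worked example

`examples/02_rt_advance.py` simulates a wild type and a line whose
musculus allele is advanced by 1.0 latent units inside a 2-Mb late domain
(3 replicates, ~30 assignable reads/fraction/50-kb bin), then runs the full
statistics path:

```
RT advance (log2 E/L units): +2.796
replicate range:             (+2.738, +2.825)
propagated expectation:      +2.901
significant 50-kb windows:   36 / 40 in the domain (q < 0.05)
```

The estimate sits within a few percent of the numerically propagated
expectation of the generative model, and most domain windows are
individually significant. The other examples cover profile building and
display tracks (`01`), transcription quantification, read-through,
differential testing and barcode counting (`03`), and the dose-response /
reversibility scenarios (`04`). Each prints what it computes and what the
numbers mean.

A thin CLI mirrors the library (`allelert simulate | rt | advance |
bruquant | barcodes | associate | all`); run `allelert --help`.

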