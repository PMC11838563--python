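"""Simulate a hybrid-genome Repli-Seq experiment and build RT tracks.

A 20-Mb chromosome carries a 2-Mb late-replicating domain; the musculus
(a1) allele replicates slightly earlier inside it (the natural allelic
offset).  We simulate binned early/late counts, compute raw log2(E/L)
profiles per allele, quantile-normalize them to the wild-type reference,
and produce a smoothed, scaled display track.
"""

import numpy as np

import allelert as al
from allelert.pipeline import wt_reference

genome = al.GenomeSpec(chromosomes=(("chr6", 20_000_000),), snp_spacing_mean=150,
                       read_length=100, seed=0)
domain = ("chr6", 9_000_000, 11_000_000)
landscape = al.RTLandscape(
    genome=genome,
    domains=(al.Domain(*domain, label="switching"),),
    advance_domain=domain,
    allelic_offset=0.1,
)

print(f"fraction of reads covering >=1 diagnostic SNP: {genome.assignable_fraction:.3f}")

counts, truth = al.simulate_repliseq(landscape, depth_per_fraction=30,
                                     n_replicates=2, bin_size=50_000, seed=1)
profiles = al.compute_rt(counts, pseudocount=0.1, min_coverage=10)
print(f"profiles computed for (allele, replicate): {sorted(profiles)}")

reference = wt_reference(counts, 0.1, 10)
a1 = al.quantile_normalize(profiles[("a1", 1)], reference)
a2 = al.quantile_normalize(profiles[("a2", 1)], reference)

in_domain = truth.domain_mask(domain)
print(f"mean RT inside the late domain:  a1 {np.nanmean(a1.values[in_domain]):+.2f}, "
      f"a2 {np.nanmean(a2.values[in_domain]):+.2f}  (log2 E/L; negative = late)")
print(f"mean RT outside the domain:      a1 {np.nanmean(a1.values[~in_domain]):+.2f}, "
      f"a2 {np.nanmean(a2.values[~in_domain]):+.2f}")

# display path: 5-kb bins -> 300-kb sliding mean -> rescale to +-3
fine_counts, _ = al.simulate_repliseq(landscape, depth_per_fraction=3,
                                      n_replicates=1, bin_size=5_000, seed=2)
fine = al.compute_rt(fine_counts, min_coverage=1)[("a1", 1)]
fine_ref = wt_reference(fine_counts, 0.1, 1)
track = al.scale_rt(al.smooth_rt(al.quantile_normalize(fine, fine_ref)))
print(f"display track state: {track.state}; "
      f"99.5th percentile |value| = {np.nanpercentile(np.abs(track.values), 99.5):.2f}")
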