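"""Shared fixtures: small simulated hybrid-genome datasets."""

import numpy as np
import pandas as pd
import pytest

import allelert as al


@pytest.fixture(scope="session")
def genome():
    return al.GenomeSpec(
        chromosomes=(("chr1", 20_000_000),),
        snp_spacing_mean=150,
        read_length=100,
        seed=1,
    )


@pytest.fixture(scope="session")
def domain():
    return ("chr1", 9_000_000, 11_000_000)


def make_landscape(genome, domain, advance_delta=0.0, allelic_offset=0.1, **kwargs):
    return al.RTLandscape(
        genome=genome,
        domains=(al.Domain(*domain, label="switching"),),
        advance_domain=domain,
        allelic_offset=allelic_offset,
        advance_delta=advance_delta,
        **kwargs,
    )


@pytest.fixture(scope="session")
def wt_landscape(genome, domain):
    return make_landscape(genome, domain, advance_delta=0.0)


@pytest.fixture(scope="session")
def wt_dataset(wt_landscape):
    """Wild-type Repli-Seq counts + truth at the statistics bin size."""
    return al.simulate_repliseq(
        wt_landscape, depth_per_fraction=30, n_replicates=3, bin_size=50_000, seed=11
    )


@pytest.fixture(scope="session")
def wt_deltas(wt_dataset):
    """Quantile-normalized per-replicate WT allelic delta profiles + reference."""
    from allelert.pipeline import _normalized_deltas, wt_reference

    counts, _truth = wt_dataset
    reference = wt_reference(counts, 0.1, 10)
    _profiles, deltas = _normalized_deltas(counts, reference, 0.1, 10)
    return deltas, reference


@pytest.fixture(scope="session")
def barcode_manifest():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = set()
    while len(seqs) < 8:
        seqs.add("".join(bases[rng.integers(0, 4, 16)]))
    seqs = sorted(seqs)
    return pd.DataFrame(
        {"barcode_id": [f"bc{i:02d}" for i in range(len(seqs))], "sequence": seqs}
    )
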