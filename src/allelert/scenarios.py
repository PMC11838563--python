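"""Canonical simulation study scenarios.

Each function runs one complete in-silico experiment mirroring the hybrid
mESC study design -- a 2-Mb late-replicating target domain with the natural
allelic offset on the musculus allele, diagnostic SNPs every ~150 bp,
100-bp reads, ~30 assignable reads per fraction per 50-kb bin -- and
returns the estimates the corresponding analysis stage produces together
with their ground truth.  The scenarios are what the test suite and the
reproduction script exercise; they are deliberately small enough to run on
a laptop in seconds to minutes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import simulate as _sim
from .advance import domain_advance_report, rt_advance
from .association import (
    AssociationResult,
    Condition,
    ReversibilityReport,
    advance_vs_expression,
    reversibility_report,
)
from .pipeline import _normalized_deltas, wt_reference
from .random import child_seed
from .simulate import Domain, GenomeSpec, RTLandscape, expected_advance

__all__ = [
    "study_landscape",
    "recovery_sweep",
    "null_calibration",
    "dose_response",
    "uncoupled_run",
    "reversibility_trial",
    "reversibility_fraction",
]

PSEUDOCOUNT = 0.1
MIN_COVERAGE = 10
BIN_SIZE = 50_000
DEPTH = 30.0
K_LINK = 2.0
OFFSET = 0.1


def study_landscape(
    genome_mb: float = 20.0,
    domain=("chr6", 9_000_000, 11_000_000),
    advance_delta: float = 0.0,
) -> RTLandscape:
    """The study's genome in miniature: one chromosome, one target domain."""
    genome = GenomeSpec(
        chromosomes=((domain[0], int(genome_mb * 1e6)),),
        snp_spacing_mean=150,
        read_length=100,
    )
    return RTLandscape(
        genome=genome,
        domains=(Domain(*domain, label="switching"),),
        advance_domain=domain,
        allelic_offset=OFFSET,
        advance_delta=advance_delta,
    )


def _wt_and_reference(landscape, n_replicates, seed):
    counts, truth = _sim.simulate_repliseq(
        dataclasses.replace(landscape, advance_delta=0.0),
        DEPTH, n_replicates, BIN_SIZE, seed, K_LINK,
    )
    reference = wt_reference(counts, PSEUDOCOUNT, MIN_COVERAGE)
    _, deltas = _normalized_deltas(counts, reference, PSEUDOCOUNT, MIN_COVERAGE)
    return counts, truth, reference, deltas


def recovery_sweep(
    seed: int,
    deltas: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Recover engineered advances of increasing size.

    Returns one row per simulated latent advance with the estimated
    domain-level statistic, its replicate range, and the numerically
    propagated expectation.
    """
    landscape = study_landscape()
    domain = landscape.advance_domain
    _, wt_truth, reference, wt_deltas = _wt_and_reference(
        landscape, n_replicates, child_seed(seed, "recovery/wt")
    )
    rows = []
    for delta in deltas:
        counts, truth = _sim.simulate_repliseq(
            dataclasses.replace(landscape, advance_delta=float(delta)),
            DEPTH, n_replicates, BIN_SIZE,
            child_seed(seed, f"recovery/delta{delta}"), K_LINK,
        )
        _, mut = _normalized_deltas(counts, reference, PSEUDOCOUNT, MIN_COVERAGE)
        adv = rt_advance(mut, wt_deltas, domain)
        rows.append(
            {
                "latent_delta": float(delta),
                "estimate": adv.delta,
                "range_lo": adv.replicate_range[0],
                "range_hi": adv.replicate_range[1],
                "expected": expected_advance(truth, wt_truth, domain, PSEUDOCOUNT),
            }
        )
    return pd.DataFrame(rows)


def null_calibration(
    seed: int,
    n_windows: int = 10_000,
    n_permutations: int = 1000,
    n_replicates: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the per-window test when nothing is engineered.

    Two wild-type-like lines (natural allelic offset only, no advance) are
    compared across ``n_windows`` 50-kb windows; returns the fraction of
    windows flagged at q < alpha.
    """
    genome_mb = n_windows * BIN_SIZE / 1e6
    # a 2-Mb target domain placed mid-genome
    mid = int(genome_mb * 1e6 // 2)
    domain = ("chr6", mid, mid + 2_000_000)
    landscape = study_landscape(genome_mb=genome_mb, domain=domain)
    _, _, reference, wt_deltas = _wt_and_reference(
        landscape, n_replicates, child_seed(seed, "null/wt")
    )
    counts, _ = _sim.simulate_repliseq(
        landscape, DEPTH, n_replicates, BIN_SIZE, child_seed(seed, "null/mut"), K_LINK
    )
    _, mut = _normalized_deltas(counts, reference, PSEUDOCOUNT, MIN_COVERAGE)
    report = domain_advance_report(
        mut, wt_deltas, domain,
        n_permutations=n_permutations,
        seed=child_seed(seed, "null/perm"),
        exclude_intervals=[domain],
        alpha=alpha,
    )
    tested = report.per_window.dropna(subset=["p"])
    return {
        "fpr": float(tested["significant"].mean()),
        "n_windows": int(len(tested)),
        "domain_delta": report.delta,
    }


_GENE = {"name": "Ptn", "start": 9_450_000, "end": 9_546_000}  # 96-kb gene in the domain


def _expression_estimate(rate: float, seed: int, n_replicates: int = 2,
                         library_scale: float = 1.0) -> float:
    genes = pd.DataFrame(
        [{"gene": _GENE["name"], "chrom": "chr6", "start": _GENE["start"],
          "end": _GENE["end"], "strand": "+"}]
    )
    counts = _sim.simulate_bruseq(
        genes, {(_GENE["name"], "a1"): rate, (_GENE["name"], "a2"): 0.0},
        library_scale, n_replicates, seed,
    )
    a1 = counts[counts["allele"] == "a1"]
    length_kb = (_GENE["end"] - _GENE["start"]) / 1000.0
    return float(a1["count"].mean() / (length_kb * library_scale))


def dose_response(
    seed: int,
    doses: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    coupled: bool = True,
    max_advance: float = 1.0,
    max_rate: float = 100.0,
    half_dose: float = 0.5,
    n_replicates: int = 3,
    n_permutations: int = 300,
) -> tuple[AssociationResult, list[Condition]]:
    """An inducible-promoter dose series with saturating transcription.

    With ``coupled=True`` the engineered advance saturates with the
    transcription rate (advance = max_advance * d/(d+half_dose)); with
    ``coupled=False`` transcription is never induced (the promoter-deletion
    scenario) while the advance still occurs, so expression stays at zero
    across all doses.
    """
    landscape = study_landscape()
    domain = landscape.advance_domain
    _, _, reference, wt_deltas = _wt_and_reference(
        landscape, n_replicates, child_seed(seed, "dose/wt")
    )
    conditions = []
    for dose in doses:
        sat = dose / (dose + half_dose) if dose > 0 else 0.0
        adv_delta = max_advance * sat
        rate = max_rate * sat if coupled else 0.0
        counts, _ = _sim.simulate_repliseq(
            dataclasses.replace(landscape, advance_delta=adv_delta),
            DEPTH, n_replicates, BIN_SIZE,
            child_seed(seed, f"dose/rt{dose}"), K_LINK,
        )
        _, mut = _normalized_deltas(counts, reference, PSEUDOCOUNT, MIN_COVERAGE)
        report = domain_advance_report(
            mut, wt_deltas, domain, n_permutations=n_permutations,
            seed=child_seed(seed, f"dose/perm{dose}"),
            exclude_intervals=[domain],
        )
        conditions.append(
            Condition(
                label=f"dox_{dose}",
                covariate=float(dose),
                advance=report,
                expression_rpkm=_expression_estimate(
                    rate, child_seed(seed, f"dose/bru{dose}")
                ),
            )
        )
    return advance_vs_expression(conditions), conditions


def uncoupled_run(seed: int, advance_delta: float = 0.8) -> dict:
    """Promoter deleted, RT still advances: advance without transcription."""
    landscape = study_landscape(advance_delta=advance_delta)
    domain = landscape.advance_domain
    _, wt_truth, reference, wt_deltas = _wt_and_reference(
        landscape, 3, child_seed(seed, "uncoupled/wt")
    )
    counts, truth = _sim.simulate_repliseq(
        landscape, DEPTH, 3, BIN_SIZE, child_seed(seed, "uncoupled/mut"), K_LINK
    )
    _, mut = _normalized_deltas(counts, reference, PSEUDOCOUNT, MIN_COVERAGE)
    adv = rt_advance(mut, wt_deltas, domain)
    return {
        "advance": adv.delta,
        "expected_advance": expected_advance(truth, wt_truth, domain, PSEUDOCOUNT),
        "expression": _expression_estimate(0.0, child_seed(seed, "uncoupled/bru")),
    }


def reversibility_trial(
    seed: int,
    induced_delta: float = 0.8,
    n_replicates: int = 5,
    n_permutations: int = 200,
) -> ReversibilityReport:
    """One induction/withdrawal experiment on a compact genome.

    Five replicates per arm: the ranges of two n-point samples of iid
    continuous estimates overlap with probability 1 - 2/C(2n, n) -- only
    2/3 at n = 2 -- so a two-replicate design cannot support a
    range-overlap reversibility call; five replicates make the overlap
    informative (P(disjoint) ~ 0.8% under full reversal).
    """
    domain = ("chr6", 2_000_000, 3_000_000)
    landscape = study_landscape(genome_mb=5.0, domain=domain)
    _, _, reference, wt_deltas = _wt_and_reference(
        landscape, n_replicates, child_seed(seed, "rev/wt")
    )
    arms = {}
    for arm, delta in (("induced", induced_delta), ("withdrawn", 0.0), ("baseline", 0.0)):
        counts, _ = _sim.simulate_repliseq(
            dataclasses.replace(landscape, advance_delta=delta),
            DEPTH, n_replicates, BIN_SIZE, child_seed(seed, f"rev/{arm}"), K_LINK,
        )
        _, mut = _normalized_deltas(counts, reference, PSEUDOCOUNT, MIN_COVERAGE)
        arms[arm] = domain_advance_report(
            mut, wt_deltas, domain, n_permutations=n_permutations,
            seed=child_seed(seed, f"rev/perm/{arm}"),
            exclude_intervals=[domain],
        )
    return reversibility_report(arms["induced"], arms["withdrawn"], arms["baseline"])


def reversibility_fraction(seed: int, n_trials: int = 100) -> dict:
    """Fraction of independent withdrawal experiments called reversible."""
    reversible = 0
    induced_sig = 0
    for trial in range(n_trials):
        report = reversibility_trial(child_seed(seed, f"rev/trial{trial}"))
        reversible += report.reversible
        induced_sig += report.significant_windows["induced"] > 0
    return {
        "reversible_fraction": reversible / n_trials,
        "induced_detected_fraction": induced_sig / n_trials,
        "n_trials": n_trials,
    }
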