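"""End-to-end orchestration: simulate -> profiles -> advance -> association.

A single flat YAML config drives the run; all randomness flows from one
root seed through named substreams (one per stage and condition), so a
rerun with the same config and seed reproduces every output byte for byte.
The run writes counts tables, RT tracks (bedGraph), the advance and
per-window reports, the condition series, and a manifest with a sha256
checksum per output plus the config hash.
"""

from __future__ import annotations

import hashlib
import os
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import advance as _advance
from . import association as _association
from . import io as _io
from . import rt as _rt
from . import simulate as _sim
from .errors import AllelertError, ConfigError
from .random import child_seed

__all__ = ["run_pipeline", "demo_config", "load_config", "validate_config", "PipelineError"]


class PipelineError(AllelertError):
    """A stage failed; the message names the stage and the cause."""


_REQUIRED = {
    "genome": ("chromosomes",),
    "landscape": ("domain",),
    "repliseq": (),
    "conditions": (),
}


def demo_config() -> dict:
    """A small end-to-end demonstration configuration.

    One 10-Mb chromosome, a 2-Mb late-replicating target domain carrying
    the natural allelic offset, three doxycycline-dose conditions with a
    saturating coupling of advance to transcription rate.
    """
    return {
        "seed": 0,
        "genome": {
            "chromosomes": [["chr6", 10_000_000]],
            "snp_spacing_mean": 150,
            "read_length": 100,
        },
        "landscape": {
            "domain": ["chr6", 4_000_000, 6_000_000],
            "allelic_offset": 0.1,
            "background_amplitude": 0.6,
            "background_period": 4_000_000,
        },
        "repliseq": {
            "depth_per_fraction": 30,
            "n_replicates": 2,
            "bin_size": 50_000,
            "display_bin_size": 5_000,
            "k": 2.0,
            "pseudocount": 0.1,
            "min_coverage": 10,
        },
        "display": {"smooth_span": 300_000, "target_halfrange": 3.0},
        "advance": {"n_permutations": 300, "alpha": 0.05},
        "bruseq": {
            "gene": {
                "name": "Ptn",
                "chrom": "chr6",
                "start": 4_900_000,
                "end": 4_996_000,
                "strand": "+",
            },
            "library_scale": 1.0,
            "n_replicates": 2,
        },
        "conditions": [
            {"label": "dox_0", "covariate": 0.0, "advance_delta": 0.0, "rate": 0.0},
            {"label": "dox_0.5", "covariate": 0.5, "advance_delta": 0.5, "rate": 40.0},
            {"label": "dox_2", "covariate": 2.0, "advance_delta": 0.8, "rate": 80.0},
        ],
    }


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: Mapping[str, Any]) -> None:
    """Fail fast -- before any compute -- on a structurally invalid config."""
    for section, keys in _REQUIRED.items():
        if section not in config:
            raise ConfigError(f"config is missing required section {section!r}")
        for key in keys:
            if key not in config[section]:
                raise ConfigError(f"config section {section!r} is missing key {key!r}")
    if not config["conditions"]:
        raise ConfigError("config lists no conditions")
    dom = config["landscape"]["domain"]
    if len(dom) != 3 or dom[1] >= dom[2]:
        raise ConfigError("landscape.domain must be [chrom, start, end] with start < end")
    for cond in config["conditions"]:
        for key in ("label", "covariate", "advance_delta", "rate"):
            if key not in cond:
                raise ConfigError(f"condition {cond} is missing key {key!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def wt_reference(counts: _rt.BinnedCounts, pseudocount: float, min_coverage: int):
    """Wild-type reference quantile function, pooled over alleles.

    The per-allele per-replicate WT profiles are combined by averaging
    their quantile functions (see :func:`allelert.rt.quantile_reference`),
    so the reference's noise width matches each sample normalized to it.
    """
    profiles = _rt.compute_rt(counts, pseudocount, min_coverage)
    keep = [p for (allele, _rep), p in sorted(profiles.items()) if allele in ("a1", "a2")]
    return _rt.quantile_reference(keep)


def _normalized_deltas(counts, reference, pseudocount, min_coverage):
    """Per-replicate allelic delta profiles, quantile-normalized to reference."""
    profiles = _rt.compute_rt(counts, pseudocount, min_coverage)
    deltas = []
    for rep in counts.replicates:
        a1 = _rt.quantile_normalize(profiles[("a1", rep)], reference)
        a2 = _rt.quantile_normalize(profiles[("a2", rep)], reference)
        deltas.append(_advance.allele_delta(a1, a2))
    return profiles, deltas


def run_pipeline(config: Mapping[str, Any] | str | os.PathLike, outdir: str | os.PathLike):
    """Execute the full analysis described by ``config`` under ``outdir``.

    Returns a dict with the advance reports, the association result and the
    manifest path.  Idempotent: identical config + seed give byte-identical
    outputs and manifest.
    """
    if isinstance(config, (str, os.PathLike)):
        config = load_config(config)
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        _io.write_tsv(df, path)
        written.append(path)

    seed = int(config.get("seed", 0))
    gcfg = config["genome"]
    genome = _stage("genome")(
        _sim.GenomeSpec,
        chromosomes=tuple((str(c), int(l)) for c, l in gcfg["chromosomes"]),
        snp_spacing_mean=gcfg.get("snp_spacing_mean", 150),
        read_length=gcfg.get("read_length", 100),
        seed=seed,
    )
    lcfg = config["landscape"]
    domain = tuple(lcfg["domain"])
    domain = (str(domain[0]), int(domain[1]), int(domain[2]))
    base_landscape = _sim.RTLandscape(
        genome=genome,
        domains=(_sim.Domain(*domain, label="switching"),),
        background_amplitude=float(lcfg.get("background_amplitude", 0.6)),
        background_period=float(lcfg.get("background_period", 4e6)),
        advance_domain=domain,
        allelic_offset=float(lcfg.get("allelic_offset", 0.1)),
    )

    rcfg = config["repliseq"]
    bin_size = int(rcfg.get("bin_size", 50_000))
    display_bin = int(rcfg.get("display_bin_size", 0)) or None
    pseudocount = float(rcfg.get("pseudocount", 0.1))
    min_coverage = int(rcfg.get("min_coverage", 10))
    k = float(rcfg.get("k", 2.0))
    depth = float(rcfg.get("depth_per_fraction", 30))
    n_reps = int(rcfg.get("n_replicates", 2))
    acfg = config.get("advance", {})
    n_perm = int(acfg.get("n_permutations", 300))
    alpha = float(acfg.get("alpha", 0.05))

    def simulate(delta: float, name: str):
        import dataclasses

        landscape = dataclasses.replace(base_landscape, advance_delta=float(delta))
        if display_bin is not None:
            fine, truth = _sim.simulate_repliseq(
                landscape, depth * display_bin / bin_size, n_reps,
                display_bin, child_seed(seed, f"repliseq/{name}"), k,
            )
            coarse = _rt.aggregate_bins(fine, bin_size // display_bin)
            return fine, coarse, truth
        coarse, truth = _sim.simulate_repliseq(
            landscape, depth, n_reps, bin_size, child_seed(seed, f"repliseq/{name}"), k
        )
        return None, coarse, truth

    # wild type
    wt_fine, wt_counts, wt_truth = _stage("simulate_wt")(simulate, 0.0, "wt")
    save_tsv(wt_counts.df, "wt_counts.tsv")
    (outdir / "wt_truth.txt").write_text(wt_truth.to_text())
    written.append(outdir / "wt_truth.txt")
    reference = _stage("reference")(wt_reference, wt_counts, pseudocount, min_coverage)
    wt_profiles, wt_deltas = _stage("wt_profiles")(
        _normalized_deltas, wt_counts, reference, pseudocount, min_coverage
    )

    # display tracks for wild type replicate 1
    if wt_fine is not None:
        dcfg = config.get("display", {})
        fine_profiles = _rt.compute_rt(wt_fine, pseudocount, min_coverage=1)
        fine_ref = wt_reference(wt_fine, pseudocount, min_coverage=1)
        for allele in ("a1", "a2"):
            prof = _rt.quantile_normalize(fine_profiles[(allele, 1)], fine_ref)
            prof = _rt.smooth_rt(prof, int(dcfg.get("smooth_span", 300_000)))
            prof = _rt.scale_rt(prof, float(dcfg.get("target_halfrange", 3.0)))
            path = outdir / f"wt_{allele}_rep1_display.bedGraph"
            _io.write_bedgraph(prof, path)
            written.append(path)
            written.append(Path(f"{path}.meta"))

    # conditions
    bcfg = config.get("bruseq", {})
    gene = bcfg.get("gene")
    gene_frame = None
    if gene is not None:
        gene_frame = pd.DataFrame(
            [
                {
                    "gene": gene["name"],
                    "chrom": gene["chrom"],
                    "start": int(gene["start"]),
                    "end": int(gene["end"]),
                    "strand": gene.get("strand", "+"),
                }
            ]
        )
    series = []
    advance_rows = []
    reports = {}
    for cond in config["conditions"]:
        label = str(cond["label"])
        _fine, counts, truth = _stage(f"simulate/{label}")(
            simulate, cond["advance_delta"], label
        )
        save_tsv(counts.df, f"{label}_counts.tsv")
        _profiles, deltas = _stage(f"profiles/{label}")(
            _normalized_deltas, counts, reference, pseudocount, min_coverage
        )
        report = _stage(f"advance/{label}")(
            _advance.domain_advance_report,
            deltas,
            wt_deltas,
            domain,
            n_permutations=n_perm,
            seed=child_seed(seed, f"significance/{label}"),
            exclude_intervals=[domain],
            alpha=alpha,
        )
        reports[label] = report
        save_tsv(report.per_window, f"{label}_windows.tsv")
        advance_rows.append(report.to_frame().assign(label=label))

        expression = float("nan")
        if gene_frame is not None:
            scale = float(bcfg.get("library_scale", 1.0))
            bru = _stage(f"bruseq/{label}")(
                _sim.simulate_bruseq,
                gene_frame,
                {(gene["name"], "a1"): float(cond["rate"]), (gene["name"], "a2"): 0.0},
                scale,
                int(bcfg.get("n_replicates", 2)),
                child_seed(seed, f"bruseq/{label}"),
            )
            save_tsv(bru, f"{label}_bruseq.tsv")
            length_kb = (int(gene["end"]) - int(gene["start"])) / 1000.0
            a1 = bru[bru["allele"] == "a1"]
            expression = float(a1["count"].mean() / (length_kb * scale))
        series.append(
            _association.Condition(
                label=label,
                covariate=float(cond["covariate"]),
                advance=report,
                expression_rpkm=expression,
            )
        )

    save_tsv(pd.concat(advance_rows, ignore_index=True), "advance_report.tsv")

    association = None
    if len(series) >= 3:
        association = _stage("association")(_association.advance_vs_expression, series)
        save_tsv(association.table, "association.tsv")

    manifest_path = outdir / "manifest.tsv"
    lines = [
        f"# allelert pipeline manifest",
        f"# config_sha256\t{_config_hash(dict(config))}",
        f"# seed\t{seed}",
    ]
    for path in sorted(written):
        lines.append(f"{path.name}\t{_sha256(path)}")
    manifest_path.write_text("\n".join(lines) + "\n")

    return {
        "reports": reports,
        "association": association,
        "manifest": manifest_path,
        "wt_truth": wt_truth,
        "outdir": outdir,
    }
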