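"""End-to-end orchestration: simulate -> callable -> filter -> rates -> WCD -> Ne.

`run_pipeline` executes every stage in memory on a synthetic pedigree and
returns one machine-readable report; given an output directory it also
writes the report, the resolved configuration, and the main tables.  Runs
are deterministic: identical configuration and seed give byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Sequence

from . import __version__
from .callable_sites import callable_mask_strict
from .denovo_filter import find_denovo_candidates, sensitivity_sweep
from .ne_estimation import effective_population_size
from .rate_stats import classify_spectrum, mutation_rate, wcd_rate
from .synthetic_data import SyntheticConfig, generate_reference, simulate_pedigree
from .wcd_detection import count_duplication_events, detect_duplications, window_coverage

__all__ = ["PipelineThresholds", "run_pipeline"]


@dataclasses.dataclass(frozen=True)
class PipelineThresholds:
    """Analysis thresholds with their conventional defaults."""

    min_depth: int = 10          # ">9x" callable cutoff
    alpha: float = 0.05
    window_size: int = 5000
    dup_threshold: float = 1.9
    ambiguous_threshold: float = 1.5
    fraction_threshold: float = 1.0
    sweep_thresholds: tuple = (0.9, 1.0)


def run_pipeline(
    config: SyntheticConfig,
    thresholds: PipelineThresholds = PipelineThresholds(),
    pi_s: Optional[Dict[str, float]] = None,
    outdir: Optional[Path] = None,
) -> dict:
    """Run the full synthetic-pedigree analysis and return the report.

    Parameters
    ----------
    config
        Synthetic study conditions (includes the seed).
    thresholds
        Filtering/detection thresholds.
    pi_s
        Optional mapping region -> neutral diversity for Ne estimation
        using the estimated rate.
    outdir
        When given, `report.json`, `resolved_config.json` and candidate /
        callable tables are written there.
    """
    reference = generate_reference(config)
    sim = simulate_pedigree(config, reference)
    design = sim.design

    summary = callable_mask_strict(
        sim.tracks, design.required_individuals, thresholds.min_depth
    )
    candidates = find_denovo_candidates(
        sim.variants, summary.mask, design,
        fraction_threshold=thresholds.fraction_threshold,
    )
    accepted = [c for c in candidates if c.accepted]

    rate = mutation_rate(
        len(accepted), summary.G_star, design.n_progeny, design.generations,
        alpha=thresholds.alpha,
    )
    snv_accepted = [
        (c.record.ref, c.record.alt)
        for c in accepted
        if c.record.var_class == "SNV"
        and len(c.record.ref) == 1 and len(c.record.alt) == 1
    ]
    spectrum = classify_spectrum(snv_accepted)
    sweep = sensitivity_sweep(
        sim.variants, summary.mask, design, thresholds.sweep_thresholds
    )

    # duplication detection per progeny
    all_calls = []
    for prog in design.progeny:
        wc = window_coverage(sim.tracks[prog], thresholds.window_size)
        all_calls.extend(
            detect_duplications(
                wc, thresholds.dup_threshold, thresholds.ambiguous_threshold
            )
        )
    n_events = count_duplication_events(all_calls)
    per_chrom_rate, per_cell_rate = wcd_rate(
        n_events, config.n_chromosomes, design.n_progeny, design.generations
    )

    # truth audit
    truth_keys = {
        (ind, chrom, pos) for ind, chrom, pos, _r, _a in sim.truth.true_mutations
    }
    accepted_keys = {(c.carrier, c.record.chrom, c.record.pos) for c in accepted}
    true_at_callable = sum(
        1
        for _ind, chrom, pos, _r, _a in sim.truth.true_mutations
        if bool(summary.mask[chrom][pos - 1])
    )
    dup_calls = [
        {"individual": c.individual, "chromosome": c.chromosome,
         "ratio": round(c.ratio, 4), "status": c.status}
        for c in all_calls if c.status != "normal"
    ]

    report = {
        "haplomu_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "thresholds": dataclasses.asdict(thresholds),
        "callable": {
            "scheme": summary.scheme,
            "G_star": summary.G_star,
            "genome_length": summary.genome_length,
            "callable_fraction": summary.callable_fraction,
        },
        "filtering": {
            "n_variant_records": len(sim.variants),
            "n_accepted": len(accepted),
            "rejections": {
                r: sum(1 for c in candidates if c.reason == r)
                for r in ("not_callable", "shared_carriers", "partial_fraction", "alt_in_others")
            },
            "sensitivity_sweep": {str(k): v for k, v in sweep.items()},
        },
        "rate": {
            "n": rate.n, "G_star": rate.G_star, "I": rate.I, "g": rate.g,
            "T": rate.T, "mu": rate.mu,
            "ci_low": rate.ci_low, "ci_high": rate.ci_high, "alpha": rate.alpha,
        },
        "spectrum": {
            "counts": dict(sorted(spectrum.counts.items())),
            "n_transitions": spectrum.n_transitions,
            "n_transversions": spectrum.n_transversions,
        },
        "wcd": {
            "n_events": n_events,
            "per_chromosome_rate": per_chrom_rate,
            "per_cell_rate": per_cell_rate,
            "calls": dup_calls,
        },
        "truth_audit": {
            "n_true_mutations": len(sim.truth.true_mutations),
            "n_true_at_callable_sites": true_at_callable,
            "n_true_recovered": len(truth_keys & accepted_keys),
            "n_false_positives": len(accepted_keys - truth_keys),
            "mu_true": config.mu_true,
            "mu_true_within_ci": bool(rate.ci_low <= config.mu_true <= rate.ci_high),
        },
    }
    if pi_s:
        report["ne"] = {
            region: {
                "pi_s": value,
                "ne": effective_population_size(value, rate, region=region).ne,
            }
            for region, value in pi_s.items()
        }

    if outdir is not None:
        from .io import write_callable_summary, write_candidates

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "resolved_config.json").write_text(
            json.dumps(
                {"config": dataclasses.asdict(config),
                 "thresholds": dataclasses.asdict(thresholds)},
                indent=2, sort_keys=True,
            ) + "\n"
        )
        write_candidates(candidates, outdir / "candidates.tsv")
        write_callable_summary(summary, outdir / "callable_summary.tsv")
    return report
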