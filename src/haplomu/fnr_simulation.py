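"""Spike-in false-negative simulation.

Known mutations are planted into a reference region, the dataset is
regenerated so one designated progeny carries them, detection is rerun,
and every miss is classified by cause.  On clean synthetic data the only
legitimate cause of a miss is a non-callable site, so the experiment
measures the callability loss rather than filter defects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .callable_sites import callable_mask_strict
from .denovo_filter import MutationCandidate, find_denovo_candidates
from .synthetic_data import Reference, SimulatedPedigree, SyntheticConfig, simulate_pedigree

__all__ = [
    "SpikeSet",
    "RecoveryReport",
    "spike_mutations",
    "evaluate_recovery",
    "run_spike_experiment",
]


@dataclass(frozen=True)
class SpikeSet:
    """Planted mutations: positions, the base written, and the originals."""

    positions: Tuple[Tuple[str, int], ...]  # (chrom, 1-based pos)
    target_base: str
    original_bases: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("spiked positions must be unique")
        if any(b == self.target_base for b in self.original_bases):
            raise ValueError("target base equals original at a spiked site")


@dataclass
class RecoveryReport:
    """Outcome of re-detecting spiked mutations."""

    n_spiked: int
    n_recovered: int
    n_missed: int
    misses: List[Tuple[str, int, str]]  # chrom, pos, cause
    fnr: float
    by_cause: "Counter[str]" = field(default_factory=Counter)


def spike_mutations(
    reference: Reference,
    chrom: str,
    n_mutations: int,
    start: int,
    end: int,
    target_base: str = "G",
    seed: Optional[int] = None,
) -> Tuple[Reference, SpikeSet]:
    """Write ``n_mutations`` copies of ``target_base`` into a region.

    Positions are 1-based inclusive over ``[start, end]``.  Placement is a
    deterministic even grid by default; passing ``seed`` draws positions
    uniformly at random instead.  Sites already equal to the target base
    are nudged to the next differing site, so every spike is a real change
    and the returned :class:`SpikeSet` can revert the reference exactly.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    if chrom not in reference.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = reference.sequences[chrom]
    if end > seq.size:
        raise ValueError(f"region end {end} beyond chromosome length {seq.size}")
    tb = target_base.encode()
    eligible = np.flatnonzero(seq[start - 1 : end] != tb) + start  # 1-based
    if n_mutations > eligible.size:
        raise ValueError(
            f"region holds only {eligible.size} sites differing from {target_base}"
        )

    if n_mutations == 0:
        return reference.copy(), SpikeSet((), target_base, ())

    if seed is None:
        grid = np.linspace(start, end, n_mutations).round().astype(np.int64)
        chosen: List[int] = []
        used = set()
        for p in grid:
            q = int(p)
            while q <= end and (seq[q - 1] == tb or q in used):
                q += 1
            if q > end:  # fall back to the nearest earlier eligible site
                q = int(p)
                while seq[q - 1] == tb or q in used:
                    q -= 1
            used.add(q)
            chosen.append(q)
        positions = sorted(chosen)
    else:
        rng = np.random.default_rng(seed)
        positions = sorted(
            int(p) for p in rng.choice(eligible, size=n_mutations, replace=False)
        )

    modified = reference.copy()
    originals = []
    for p in positions:
        originals.append(modified.sequences[chrom][p - 1].decode())
        modified.sequences[chrom][p - 1] = tb
    return modified, SpikeSet(
        tuple((chrom, p) for p in positions), target_base, tuple(originals)
    )


def evaluate_recovery(
    detected: Sequence[MutationCandidate],
    truth: SpikeSet,
    mask: Optional[Mapping[str, np.ndarray]],
) -> RecoveryReport:
    """Compare detected candidates with the spiked truth.

    Recovery demands an *accepted* candidate at the exact (chrom, pos)
    with alt equal to the spiked target base.  Misses are classified
    ``non_callable`` when the mask excludes the site, otherwise
    ``filtered:<reason>`` from the rejected candidate (``filtered:not_detected``
    if no record exists at the site at all).
    """
    if not truth.positions:
        raise ValueError("truth contains no spiked positions")
    verdicts: Dict[Tuple[str, int], MutationCandidate] = {}
    for cand in detected:
        if cand.record.alt == truth.target_base:
            verdicts[(cand.record.chrom, cand.record.pos)] = cand

    recovered = 0
    misses: List[Tuple[str, int, str]] = []
    for chrom, pos in truth.positions:
        cand = verdicts.get((chrom, pos))
        if cand is not None and cand.accepted:
            recovered += 1
            continue
        callable_here = mask is None or (
            chrom in mask and pos - 1 < mask[chrom].size and bool(mask[chrom][pos - 1])
        )
        if not callable_here:
            cause = "non_callable"
        elif cand is not None:
            cause = f"filtered:{cand.reason}"
        else:
            cause = "filtered:not_detected"
        misses.append((chrom, pos, cause))

    n = len(truth.positions)
    return RecoveryReport(
        n_spiked=n,
        n_recovered=recovered,
        n_missed=len(misses),
        misses=misses,
        fnr=len(misses) / n,
        by_cause=Counter(cause for _c, _p, cause in misses),
    )


def run_spike_experiment(
    config: SyntheticConfig,
    reference: Reference,
    chrom: Optional[str] = None,
    n_mutations: int = 100,
    start: int = 60,
    end: Optional[int] = None,
    target_base: str = "G",
    carrier: Optional[str] = None,
    min_depth: int = 10,
) -> Tuple[RecoveryReport, SpikeSet, SimulatedPedigree]:
    """End-to-end spike-in experiment on a synthetic pedigree.

    Plants ``n_mutations`` target-base mutations into one chromosome
    region, regenerates the dataset so one progeny carries them as
    germline events, recomputes the strict callable mask, reruns the
    filter and reports recovery.
    """
    design = config.design()
    chrom = chrom or list(config.chrom_names)[-1]
    end = end or reference.chrom_lengths[chrom]
    carrier = carrier or design.progeny[0]
    _modified, spikes = spike_mutations(
        reference, chrom, n_mutations, start, end, target_base
    )
    planted = [
        (carrier, c, p, target_base) for (c, p) in spikes.positions
    ]
    sim = simulate_pedigree(config, reference, extra_mutations=planted)
    summary = callable_mask_strict(
        sim.tracks, design.required_individuals, min_depth=min_depth
    )
    candidates = find_denovo_candidates(sim.variants, summary.mask, design)
    report = evaluate_recovery(candidates, spikes, summary.mask)
    return report, spikes, sim
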