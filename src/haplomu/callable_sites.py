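"""Callable-site masks and totals G* under strict and quorum schemes.

A *callable* position is one with enough read depth to confidently assert
presence or absence of a variant.  Two accounting schemes are implemented:

strict
    A position is callable iff depth >= ``min_depth`` in *all* required
    individuals (parents and every progeny).  ``G*`` is the number of such
    positions; each progeny shares the same callable total, so the rate
    exposure multiplies by ``I`` downstream.

quorum
    For each position, ``i`` is the number of individuals with depth >=
    ``min_depth``; ``N_i`` the number of positions with exactly that ``i``.
    ``G* = sum_{i >= min_individuals} i x N_i`` folds the per-individual
    exposure directly into the total (so downstream ``I = 1``), and the
    distinct callable-position count ``sum N_i`` is reported separately for
    the genome-fraction statistic.

Coverage is carried as per-base depth arrays per chromosome (0-based),
inter-convertible with BED-style run-length intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CoverageTrack",
    "CallableSummary",
    "callable_mask_strict",
    "callable_total_quorum",
]

Interval = Tuple[str, int, int, int]  # chrom, start, end (0-based half-open), depth


@dataclass
class CoverageTrack:
    """Per-base read depth for one individual.

    ``depths`` maps chromosome name to an integer depth array indexed by
    0-based position.  Conversion to/from BED-style half-open intervals is
    run-length encoding, so interval arithmetic and per-position logic are
    the same computation by construction.
    """

    individual: str
    depths: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"depth array for {chrom} must be 1-D")
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative depth on {chrom}")
            self.depths[chrom] = arr

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: int(a.size) for c, a in self.depths.items()}

    def to_intervals(self) -> Iterator[Interval]:
        """Run-length encode depths into (chrom, start, end, depth) intervals."""
        for chrom in self.depths:
            arr = self.depths[chrom]
            if arr.size == 0:
                continue
            # breakpoints where depth changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                yield chrom, int(s), int(e), int(arr[s])

    @classmethod
    def from_intervals(
        cls,
        individual: str,
        intervals: Iterable[Interval],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ) -> "CoverageTrack":
        """Build a track from BED-style intervals; uncovered bases get depth 0."""
        items = list(intervals)
        lengths: Dict[str, int] = dict(chrom_lengths or {})
        for chrom, _s, e, _d in items:
            lengths[chrom] = max(lengths.get(chrom, 0), e)
        depths = {c: np.zeros(n, dtype=np.int32) for c, n in lengths.items()}
        for chrom, s, e, d in items:
            if s < 0 or e < s:
                raise ValueError(f"bad interval {chrom}:{s}-{e}")
            depths[chrom][s:e] = d
        return cls(individual=individual, depths=depths)


@dataclass
class CallableSummary:
    """Result of a callable-site computation.

    ``G_star`` is the rate denominator; under the quorum scheme it is
    individual-weighted and ``distinct_positions`` counts callable sites
    once each.  ``mask`` (when present) maps chromosome to a boolean
    per-position callability array.
    """

    scheme: str
    G_star: int
    genome_length: int
    callable_fraction: float
    min_depth: int
    min_individuals: int
    distinct_positions: int
    per_i_counts: Optional[Dict[int, int]] = None
    mask: Optional[Dict[str, np.ndarray]] = field(default=None, repr=False, compare=False)


def _common_chroms(tracks: Sequence[CoverageTrack], exclude: Sequence[str]) -> List[str]:
    chroms = list(tracks[0].depths)
    for t in tracks[1:]:
        if list(t.depths) != chroms:
            # tolerate ordering differences but demand the same set
            if set(t.depths) != set(chroms):
                raise ValueError(
                    f"track {t.individual} covers different chromosomes than {tracks[0].individual}"
                )
    return [c for c in chroms if c not in set(exclude)]


def callable_mask_strict(
    tracks: Mapping[str, CoverageTrack],
    required_individuals: Sequence[str],
    min_depth: int,
    exclude_chroms: Sequence[str] = (),
) -> CallableSummary:
    """Strict callable mask: depth >= min_depth in every required individual.

    Parameters
    ----------
    tracks
        Mapping individual -> :class:`CoverageTrack`.
    required_individuals
        Individuals that must all reach ``min_depth`` (e.g. both parents
        plus every progeny).
    min_depth
        Integer depth threshold; a stated cutoff of ">9x" is depth >= 10.
    exclude_chroms
        Chromosome names dropped entirely (unplaced-contig bins).
    """
    required = list(required_individuals)
    if not required:
        raise ValueError("required_individuals must not be empty")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    missing = [ind for ind in required if ind not in tracks]
    if missing:
        raise KeyError(f"no coverage track for individual(s): {', '.join(missing)}")

    sel = [tracks[ind] for ind in required]
    chroms = _common_chroms(sel, exclude_chroms)
    mask: Dict[str, np.ndarray] = {}
    g_star = 0
    genome = 0
    for chrom in chroms:
        m = sel[0].depths[chrom] >= min_depth
        for t in sel[1:]:
            m &= t.depths[chrom] >= min_depth
        mask[chrom] = m
        g_star += int(m.sum())
        genome += int(m.size)
    return CallableSummary(
        scheme="strict",
        G_star=g_star,
        genome_length=genome,
        callable_fraction=(g_star / genome if genome else 0.0),
        min_depth=min_depth,
        min_individuals=len(required),
        distinct_positions=g_star,
        mask=mask,
    )


def callable_total_quorum(
    tracks: Mapping[str, CoverageTrack],
    min_depth: int,
    min_individuals: int,
    exclude_chroms: Sequence[str] = (),
) -> CallableSummary:
    """Quorum callable total ``G* = sum_{i >= k} i x N_i``.

    ``i`` counts individuals with depth >= ``min_depth`` at a position and
    ``N_i`` the positions with exactly that count; positions reaching the
    quorum ``k = min_individuals`` contribute ``i`` site-generations each.
    """
    if min_individuals < 1:
        raise ValueError("min_individuals must be >= 1")
    all_tracks = list(tracks.values())
    if not all_tracks:
        raise ValueError("no coverage tracks supplied")
    if min_individuals > len(all_tracks):
        raise ValueError(
            f"min_individuals={min_individuals} exceeds the {len(all_tracks)} available tracks"
        )
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")

    chroms = _common_chroms(all_tracks, exclude_chroms)
    per_i: Dict[int, int] = {}
    mask: Dict[str, np.ndarray] = {}
    genome = 0
    for chrom in chroms:
        counts = np.zeros(all_tracks[0].depths[chrom].size, dtype=np.int32)
        for t in all_tracks:
            counts += t.depths[chrom] >= min_depth
        mask[chrom] = counts >= min_individuals
        genome += int(counts.size)
        hist = np.bincount(counts, minlength=len(all_tracks) + 1)
        for i, n_i in enumerate(hist):
            if n_i:
                per_i[i] = per_i.get(i, 0) + int(n_i)
    g_star = sum(i * n_i for i, n_i in per_i.items() if i >= min_individuals)
    distinct = sum(n_i for i, n_i in per_i.items() if i >= min_individuals)
    return CallableSummary(
        scheme="quorum",
        G_star=g_star,
        genome_length=genome,
        callable_fraction=(distinct / genome if genome else 0.0),
        min_depth=min_depth,
        min_individuals=min_individuals,
        distinct_positions=distinct,
        per_i_counts={i: n for i, n in sorted(per_i.items()) if i >= min_individuals},
        mask=mask,
    )
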