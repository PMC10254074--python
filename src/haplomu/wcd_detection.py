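"""Whole-chromosome duplication detection and dosage-ratio analysis.

A duplicated chromosome in a haploid individual doubles its copy number
and therefore its read depth.  Depth is summarised in fixed windows
(5 kb by default); each chromosome's mean window depth is compared with a
baseline, the median window depth over all *other* chromosomes — robust
against the duplicated chromosomes themselves without knowing them in
advance.  A ratio >= 1.9 is called duplicated, a ratio in [1.5, 1.9) is
flagged ambiguous (an early somatic duplication shared by most cells
cannot be excluded there), anything lower is normal.

Dosage analysis asks whether transcription tracks copy number: after
dropping genes below a TPM floor, each gene's expression ratio
(test strain over control strain) is aggregated within duplicated-region
genes and within the rest; the ratio of the two aggregates is the fold.
A fold near the depth ratio indicates absent dosage compensation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .callable_sites import CoverageTrack

__all__ = [
    "WindowCoverage",
    "DuplicationCall",
    "window_coverage",
    "detect_duplications",
    "count_duplication_events",
    "dosage_ratio",
]


@dataclass
class WindowCoverage:
    """Mean depth per fixed-size window for one individual.

    ``windows`` has columns ``chrom, start, end, mean_depth`` with 0-based
    half-open coordinates; windows tile each chromosome and only the
    terminal window may be short.
    """

    individual: str
    window_size: int
    windows: pd.DataFrame


@dataclass(frozen=True)
class DuplicationCall:
    individual: str
    chromosome: str
    ratio: float
    status: str  # duplicated | ambiguous | normal


def window_coverage(
    track: CoverageTrack,
    window_size: int = 5000,
    exclude_chroms: Sequence[str] = (),
) -> WindowCoverage:
    """Tile each chromosome into windows and average depth within each.

    Unknown names in ``exclude_chroms`` raise a warning rather than an
    error (the unplaced-contig bin may simply be absent from a track).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    unknown = set(exclude_chroms) - set(track.depths)
    if unknown:
        warnings.warn(f"excluded chromosome(s) not in track: {sorted(unknown)}")
    rows: List[Tuple[str, int, int, float]] = []
    for chrom, arr in track.depths.items():
        if chrom in exclude_chroms or arr.size == 0:
            continue
        starts = np.arange(0, arr.size, window_size)
        sums = np.add.reduceat(arr.astype(np.float64), starts)
        ends = np.minimum(starts + window_size, arr.size)
        means = sums / (ends - starts)
        rows.extend(
            (chrom, int(s), int(e), float(m)) for s, e, m in zip(starts, ends, means)
        )
    return WindowCoverage(
        individual=track.individual,
        window_size=window_size,
        windows=pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth"]),
    )


def detect_duplications(
    wc: WindowCoverage,
    dup_threshold: float = 1.9,
    ambiguous_threshold: float = 1.5,
    chrom_agg: str = "median",
) -> List[DuplicationCall]:
    """Call chromosome duplications from windowed coverage ratios.

    For each chromosome, baseline = median window mean over all other
    chromosomes; ratio = aggregate of the chromosome's own window means
    over that baseline.  The default aggregate is the median: like the
    baseline, it is insensitive to low-coverage (non-callable) windows,
    which otherwise drag a truly duplicated chromosome's mean ratio below
    the 1.9 call threshold.  ``chrom_agg="mean"`` restores plain averaging.
    """
    if not 0 < ambiguous_threshold <= dup_threshold:
        raise ValueError("need 0 < ambiguous_threshold <= dup_threshold")
    if chrom_agg not in ("median", "mean"):
        raise ValueError("chrom_agg must be 'median' or 'mean'")
    df = wc.windows
    chroms = df["chrom"].unique()
    if len(chroms) < 2:
        raise ValueError("duplication detection needs >= 2 chromosomes for a baseline")
    calls: List[DuplicationCall] = []
    for chrom in chroms:
        own = df.loc[df["chrom"] == chrom, "mean_depth"]
        rest = df.loc[df["chrom"] != chrom, "mean_depth"]
        baseline = float(rest.median())
        if baseline <= 0:
            raise ValueError("zero baseline coverage; cannot form ratios")
        ratio = float(own.median() if chrom_agg == "median" else own.mean()) / baseline
        if ratio >= dup_threshold:
            status = "duplicated"
        elif ratio >= ambiguous_threshold:
            status = "ambiguous"
        else:
            status = "normal"
        calls.append(DuplicationCall(wc.individual, str(chrom), ratio, status))
    return calls


def count_duplication_events(
    calls: Sequence[DuplicationCall], per_chromosome: bool = False
) -> int:
    """Number of duplication events behind a set of calls.

    Co-duplicated chromosomes within one individual arise from a single
    meiotic mis-segregation, so they count as one event by default;
    ``per_chromosome=True`` counts each duplicated chromosome instead.
    """
    dup = [c for c in calls if c.status == "duplicated"]
    if per_chromosome:
        return len(dup)
    return len({c.individual for c in dup})


def dosage_ratio(
    expr: pd.DataFrame,
    duplicated_chromosomes: Sequence[str],
    tpm_min: float = 1.0,
    test_cols: Optional[Sequence[str]] = None,
    control_cols: Optional[Sequence[str]] = None,
    agg: str = "mean",
) -> Tuple[float, pd.DataFrame]:
    """Expression fold of duplicated-chromosome genes over the rest.

    Parameters
    ----------
    expr
        Table with ``gene`` and ``chrom`` columns plus TPM replicate
        columns; test/control columns are inferred from the ``test_`` /
        ``control_`` prefixes unless given explicitly.
    duplicated_chromosomes
        Chromosomes considered duplicated in the test strain.
    tpm_min
        Genes whose mean TPM is not above this floor in either strain are
        dropped before forming ratios.
    agg
        ``"mean"`` or ``"median"`` aggregation of per-gene ratios within
        each partition.

    Returns
    -------
    (fold, per_gene) where ``fold`` is the aggregate duplicated-genes
    ratio divided by the aggregate other-genes ratio, and ``per_gene``
    holds the filtered per-gene table with a ``ratio`` column.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    test_cols = list(test_cols or [c for c in expr.columns if c.startswith("test")])
    control_cols = list(
        control_cols or [c for c in expr.columns if c.startswith("control")]
    )
    if not test_cols or not control_cols:
        raise ValueError("could not identify test/control TPM columns")

    df = expr.copy()
    df["test_mean"] = df[test_cols].mean(axis=1)
    df["control_mean"] = df[control_cols].mean(axis=1)
    df = df[(df["test_mean"] > tpm_min) & (df["control_mean"] > tpm_min)].copy()
    df["ratio"] = df["test_mean"] / df["control_mean"]
    df["duplicated"] = df["chrom"].isin(list(duplicated_chromosomes))

    dup = df.loc[df["duplicated"], "ratio"]
    rest = df.loc[~df["duplicated"], "ratio"]
    if dup.empty or rest.empty:
        raise ValueError(
            "need expressed genes both on and off the duplicated chromosomes"
        )
    aggfun = np.mean if agg == "mean" else np.median
    fold = float(aggfun(dup)) / float(aggfun(rest))
    keep = ["gene", "chrom", "test_mean", "control_mean", "ratio", "duplicated"]
    return fold, df[keep].reset_index(drop=True)
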