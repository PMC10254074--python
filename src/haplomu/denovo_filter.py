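"""Haploid de novo mutation candidate filtering.

A germline mutation arising in a single meiosis is expected to satisfy, in
a haploid pedigree:

1. the site is callable (enough depth in every required individual);
2. exactly one progeny shows any alternative-allele evidence (shared
   variants reflect standing variation in the parents or earlier events);
3. in that carrier the alternative allele accounts for 100% of the site's
   coverage — a haploid genome cannot be heterozygous, so a partial allele
   fraction indicates somatic mosaicism;
4. no other individual (progeny, parent or check individual) has any
   alternative read, *even at low quality* — low-level alt reads in several
   individuals are the signature of mis-mapping from repeats.

Structural-variant candidates additionally fail when another individual
carries a same-class variant nearby (imprecise breakpoint replication).

Every record receives exactly one status; a rejected record carries the
first failing criterion in the fixed order
``not_callable -> shared_carriers -> partial_fraction -> alt_in_others ->
proximity`` so reports are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .rate_stats import PedigreeDesign

__all__ = [
    "ReadSupport",
    "VariantRecord",
    "MutationCandidate",
    "REJECTION_ORDER",
    "find_denovo_candidates",
    "filter_structural_candidates",
    "sensitivity_sweep",
    "decompose_multiallelic",
]

REJECTION_ORDER = (
    "not_callable",
    "shared_carriers",
    "partial_fraction",
    "alt_in_others",
    "proximity",
)


class ReadSupport(NamedTuple):
    """Read support of one individual at one site.

    ``depth`` is total read depth, ``alt_depth`` the high-quality
    alt-supporting reads within it, and ``low_quality_alt`` counts
    additional alt-supporting reads that failed quality thresholds (kept
    separately because the filter inspects them).
    """

    depth: int
    alt_depth: int
    low_quality_alt: int = 0

    @property
    def has_alt_evidence(self) -> bool:
        return self.alt_depth > 0 or self.low_quality_alt > 0


@dataclass(frozen=True)
class VariantRecord:
    """One multi-sample variant site (1-based position, single alt allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str = "SNV"  # SNV | indel | SV
    support: Mapping[str, ReadSupport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        for ind, s in self.support.items():
            if not 0 <= s.alt_depth <= s.depth:
                raise ValueError(
                    f"alt_depth out of range for {ind} at {self.chrom}:{self.pos}"
                )


@dataclass(frozen=True)
class MutationCandidate:
    """A filtering verdict for one variant record.

    ``carrier`` is the single progeny with alt evidence when one exists
    (None when zero or several do).  ``status`` is ``"accepted"`` or
    ``"rejected"``; rejections carry the first failing ``reason``.
    """

    record: VariantRecord
    carrier: Optional[str]
    status: str
    reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def decompose_multiallelic(records: Iterable[VariantRecord]) -> List[VariantRecord]:
    """Split comma-separated alt alleles into per-allele records.

    The filtering criteria are per-allele; alt support of a decomposed
    record is attributed to each alt in turn (the caller's allele-specific
    depths, when available, should be applied upstream instead).
    """
    out: List[VariantRecord] = []
    for rec in records:
        if "," not in rec.alt:
            out.append(rec)
            continue
        for alt in rec.alt.split(","):
            out.append(replace(rec, alt=alt))
    return out


def _is_callable(mask: Optional[Mapping[str, np.ndarray]], chrom: str, pos: int) -> bool:
    if mask is None:
        return True
    m = mask.get(chrom)
    if m is None or pos - 1 >= m.size:
        return False
    return bool(m[pos - 1])


def _classify_one(
    rec: VariantRecord,
    mask: Optional[Mapping[str, np.ndarray]],
    design: PedigreeDesign,
    fraction_threshold: float,
    include_checks: bool,
) -> MutationCandidate:
    unknown = set(rec.support) - set(design.all_individuals)
    if unknown:
        raise KeyError(
            f"individual(s) {sorted(unknown)} at {rec.chrom}:{rec.pos} absent from pedigree design"
        )
    missing = [i for i in design.required_individuals if i not in rec.support]
    if missing:
        raise KeyError(
            f"record {rec.chrom}:{rec.pos} lacks support fields for {missing}"
        )
    if "," in rec.alt:
        raise ValueError(
            f"multi-allelic record at {rec.chrom}:{rec.pos}; decompose_multiallelic first"
        )

    carriers = [p for p in design.progeny if rec.support[p].has_alt_evidence]
    carrier = carriers[0] if len(carriers) == 1 else None

    if not _is_callable(mask, rec.chrom, rec.pos):
        return MutationCandidate(rec, carrier, "rejected", "not_callable")
    if len(carriers) != 1:
        return MutationCandidate(rec, carrier, "rejected", "shared_carriers")

    s = rec.support[carrier]
    # denominator includes every read the caller counted at the site
    if s.depth == 0 or s.alt_depth / s.depth < fraction_threshold:
        return MutationCandidate(rec, carrier, "rejected", "partial_fraction")

    others = [i for i in design.required_individuals if i != carrier]
    if include_checks:
        others += [i for i in design.check_individuals if i in rec.support]
    if any(rec.support[i].has_alt_evidence for i in others):
        return MutationCandidate(rec, carrier, "rejected", "alt_in_others")

    return MutationCandidate(rec, carrier, "accepted")


def find_denovo_candidates(
    variants: Iterable[VariantRecord],
    mask: Optional[Mapping[str, np.ndarray]],
    design: PedigreeDesign,
    fraction_threshold: float = 1.0,
    include_checks: bool = True,
) -> List[MutationCandidate]:
    """Classify every variant record against the haploid de novo criteria.

    Parameters
    ----------
    variants
        Multi-sample variant records (single alt allele each).
    mask
        Callable-position mask per chromosome (boolean, 0-based), e.g.
        ``CallableSummary.mask``; ``None`` treats every position callable.
    design
        Pedigree structure; uniqueness is evaluated over ``design.progeny``
        and the zero-alt criterion over everyone else.
    fraction_threshold
        Minimum carrier alt-allele fraction; 1.0 demands the alternative
        allele be 100% of the coverage (haploid germline expectation).
    include_checks
        Whether check individuals present in a record also count toward
        the zero-alt-read criterion.
    """
    if not 0 < fraction_threshold <= 1:
        raise ValueError("fraction_threshold must lie in (0, 1]")
    return [
        _classify_one(rec, mask, design, fraction_threshold, include_checks)
        for rec in variants
    ]


def filter_structural_candidates(
    sv_variants: Sequence[VariantRecord],
    design: PedigreeDesign,
    mask: Optional[Mapping[str, np.ndarray]] = None,
    proximity_window: int = 1000,
    fraction_threshold: float = 1.0,
) -> List[MutationCandidate]:
    """Apply the de novo criteria to SV records plus a proximity exclusion.

    A candidate surviving the base criteria is rejected (``proximity``)
    when any other individual shows alt evidence for a same-class variant
    within ``proximity_window`` nt — imprecise SV callers replicate the
    same event at slightly different coordinates across individuals.
    """
    if proximity_window < 0:
        raise ValueError("proximity_window must be non-negative")
    for rec in sv_variants:
        if rec.var_class != "SV":
            raise ValueError(f"non-SV record at {rec.chrom}:{rec.pos} in SV filter")

    base = find_denovo_candidates(
        sv_variants, mask, design, fraction_threshold=fraction_threshold
    )
    out: List[MutationCandidate] = []
    for cand in base:
        if not cand.accepted:
            out.append(cand)
            continue
        rec = cand.record
        near = False
        for other in sv_variants:
            if other is rec or other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > proximity_window:
                continue
            if any(
                other.support[i].has_alt_evidence
                for i in other.support
                if i != cand.carrier
            ):
                near = True
                break
        if near:
            out.append(MutationCandidate(rec, cand.carrier, "rejected", "proximity"))
        else:
            out.append(cand)
    return out


def sensitivity_sweep(
    variants: Sequence[VariantRecord],
    mask: Optional[Mapping[str, np.ndarray]],
    design: PedigreeDesign,
    thresholds: Sequence[float] = (0.9, 1.0),
) -> Dict[float, int]:
    """Accepted-candidate counts as the carrier-fraction threshold is relaxed.

    Rerunning acceptance at e.g. 0.9 instead of 1.0 checks stringency
    robustness: on clean haploid data the counts should not change, while
    somatic mosaics enter as the threshold drops.
    """
    out: Dict[float, int] = {}
    for thr in thresholds:
        cands = find_denovo_candidates(variants, mask, design, fraction_threshold=thr)
        out[float(thr)] = sum(c.accepted for c in cands)
    return out
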