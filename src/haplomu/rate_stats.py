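"""Mutation-rate point estimates, exact Poisson intervals, and spectrum summaries.

The rate model is the standard pedigree / mutation-accumulation estimator:
observed de novo mutations are a Poisson count ``n`` over an exposure of
``T = G* x I x g`` site-generations, where ``G*`` is the number of callable
sites, ``I`` the number of sequenced progeny and ``g`` the number of
generations separating them from the focal parent.  The per-site
per-generation rate is ``mu = n / T`` and its confidence interval is the
exact (Garwood) Poisson interval obtained from chi-square quantiles.

Two accounting schemes are supported.  Under the *strict* scheme every
progeny shares one callable-site total, so ``I`` enters the exposure
explicitly.  Under the *quorum* scheme the callable total is already summed
over individuals (``G* = sum_i i x N_i``), so callers pass ``I = 1``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

from scipy.stats import chi2

__all__ = [
    "PedigreeDesign",
    "RateEstimate",
    "SpectrumSummary",
    "mutation_rate",
    "poisson_ci",
    "classify_spectrum",
    "wcd_rate",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PedigreeDesign:
    """Individuals and structure of a haploid pedigree sequencing design.

    Parameters
    ----------
    parents
        Identifiers of the (haploid) parent pair.
    progeny
        Identifiers of the ``I`` meiotic progeny used for rate estimation.
    check_individuals
        Optional extra individuals sequenced only to corroborate candidates
        (grand-parent or sibling lineages); they contribute to the
        zero-alt-read criterion when enabled but are never counted in ``I``.
    generations
        Generations per progeny separating them from the focal parent
        (``g``; 1 for a direct parent-offspring design).
    scheme
        Callable-site accounting scheme, ``"strict"`` or ``"quorum"``.
    """

    parents: Tuple[str, ...]
    progeny: Tuple[str, ...]
    check_individuals: Tuple[str, ...] = ()
    generations: int = 1
    scheme: str = "strict"

    def __post_init__(self) -> None:
        if len(self.progeny) < 1:
            raise ValueError("pedigree needs at least one progeny individual")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.scheme not in ("strict", "quorum"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        everyone = self.parents + self.progeny + self.check_individuals
        if len(set(everyone)) != len(everyone):
            raise ValueError("duplicate individual identifiers in design")

    @property
    def n_progeny(self) -> int:
        return len(self.progeny)

    @property
    def required_individuals(self) -> Tuple[str, ...]:
        """Individuals whose coverage defines strict callability."""
        return self.parents + self.progeny

    @property
    def all_individuals(self) -> Tuple[str, ...]:
        return self.parents + self.progeny + self.check_individuals


@dataclass(frozen=True)
class RateEstimate:
    """A mutation-rate point estimate with its exact Poisson interval.

    ``mu = n / T`` with ``T = G_star x I x g`` site-generations; bounds are
    the equal-tailed Garwood interval at level ``alpha``.
    """

    n: int
    G_star: int
    I: int
    g: int
    T: float
    mu: float
    ci_low: float
    ci_high: float
    alpha: float


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts of base substitutions partitioned into transitions/transversions."""

    counts: "Counter[str]"
    n_transitions: int
    n_transversions: int

    @property
    def total(self) -> int:
        return self.n_transitions + self.n_transversions


def poisson_ci(n: int, T: float, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson rate.

    For an observed count ``n`` over exposure ``T``, the equal-tailed
    interval on the rate is::

        low  = chi2.ppf(alpha/2, 2n) / 2 / T        (0 when n == 0)
        high = chi2.ppf(1 - alpha/2, 2n + 2) / 2 / T

    Parameters
    ----------
    n
        Observed event count (>= 0).
    T
        Exposure (site-generations); must be positive.
    alpha
        Two-sided significance level in (0, 1).

    Returns
    -------
    (low, high) on the per-exposure-unit rate scale.
    """
    if T <= 0:
        raise ValueError("exposure T must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if n < 0:
        raise ValueError("count n must be non-negative")
    low = 0.0 if n == 0 else chi2.ppf(alpha / 2, 2 * n) / 2.0 / T
    high = chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0 / T
    return float(low), float(high)


def mutation_rate(
    n: int,
    G_star: int,
    individuals: int,
    generations: int = 1,
    alpha: float = 0.05,
) -> RateEstimate:
    """Per-site per-generation mutation rate ``n / (G* x I x g)`` with CI.

    Parameters
    ----------
    n
        Number of accepted de novo mutations.
    G_star
        Callable-site total.  Under the quorum scheme this already sums over
        individuals; pass ``individuals=1`` there.
    individuals
        Number of progeny ``I`` sharing the callable total (strict scheme).
    generations
        Generations per progeny ``g``.
    alpha
        Significance level of the Poisson interval.
    """
    if G_star <= 0:
        raise ValueError("G_star must be positive: rate undefined on zero callable sites")
    if individuals < 1 or generations < 1:
        raise ValueError("individuals and generations must be >= 1")
    if n < 0:
        raise ValueError("mutation count must be non-negative")
    T = float(G_star) * individuals * generations
    mu = n / T
    low, high = poisson_ci(n, T, alpha)
    return RateEstimate(
        n=n, G_star=G_star, I=individuals, g=generations,
        T=T, mu=mu, ci_low=low, ci_high=high, alpha=alpha,
    )


def classify_spectrum(mutations: Iterable[Tuple[str, str]]) -> SpectrumSummary:
    """Classify single-base substitutions into transitions and transversions.

    A substitution is a transition when ref and alt are both purines (A/G)
    or both pyrimidines (C/T), and a transversion otherwise.  Per-type
    counts are kept as ``"R>A"`` keys.
    """
    counts: Counter[str] = Counter()
    ts = tv = 0
    for ref, alt in mutations:
        ref, alt = ref.upper(), alt.upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(f"not a single-nucleotide substitution: {ref!r}>{alt!r}")
        if ref == alt:
            raise ValueError(f"ref and alt are identical: {ref!r}")
        counts[f"{ref}>{alt}"] += 1
        if {ref, alt} <= _PURINES or {ref, alt} <= _PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    return SpectrumSummary(counts=counts, n_transitions=ts, n_transversions=tv)


def wcd_rate(
    n_events: int,
    n_chromosomes: int,
    individuals: int,
    generations: int = 1,
) -> Tuple[float, float]:
    """Whole-chromosome duplication rates per chromosome and per cell.

    ``per_chromosome = n_events / (n_chromosomes x I x g)`` and
    ``per_cell = n_events / (I x g)``.  Co-duplicated chromosomes within one
    individual are conventionally counted as a single event upstream (see
    :func:`haplomu.wcd_detection.count_duplication_events`).
    """
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    if n_chromosomes < 1 or individuals < 1 or generations < 1:
        raise ValueError("denominator terms must be >= 1")
    denom = individuals * generations
    return n_events / (n_chromosomes * denom), n_events / denom


def format_sig(x: float, sig: int = 3) -> str:
    """Format a number at ``sig`` significant figures (display only)."""
    if x == 0:
        return "0"
    return f"{x:.{sig}g}"
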