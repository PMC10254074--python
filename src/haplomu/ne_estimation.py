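"""Effective population size from neutral diversity and the mutation rate.

Under neutrality the expected pairwise synonymous diversity of a diploid
autosomal locus is ``pi_s = 4 Ne mu``, so ``Ne = pi_s / (4 mu)``.  When the
rate carries a confidence interval, its bounds propagate reciprocally:
the upper rate bound gives the lower Ne bound and vice versa.  Estimates
ignore demographic history and should be read as order-of-magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .rate_stats import RateEstimate

__all__ = ["NeEstimate", "effective_population_size"]


@dataclass(frozen=True)
class NeEstimate:
    """An Ne point estimate (individuals) with optional propagated bounds."""

    region: str
    pi_s: float
    mu: float
    ne: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def effective_population_size(
    pi_s: float,
    mu: Union[float, RateEstimate],
    region: str = "autosomes",
) -> NeEstimate:
    """Estimate ``Ne = pi_s / (4 mu)``.

    Parameters
    ----------
    pi_s
        Neutral (synonymous) nucleotide diversity; must be >= 0.
    mu
        Mutation rate per site per generation, either a plain float or a
        :class:`~haplomu.rate_stats.RateEstimate` whose CI is propagated.
    region
        Label carried through to the output (autosomes, PAR, SDR, ...).
    """
    if pi_s < 0:
        raise ValueError("pi_s must be non-negative")
    if isinstance(mu, RateEstimate):
        rate = mu
        if rate.mu <= 0:
            raise ValueError("mutation rate must be positive to estimate Ne")
        low = pi_s / (4.0 * rate.ci_high) if rate.ci_high > 0 else None
        high = pi_s / (4.0 * rate.ci_low) if rate.ci_low > 0 else None
        return NeEstimate(region, pi_s, rate.mu, pi_s / (4.0 * rate.mu), low, high)
    if mu <= 0:
        raise ValueError("mutation rate must be positive to estimate Ne")
    return NeEstimate(region, pi_s, float(mu), pi_s / (4.0 * mu))
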