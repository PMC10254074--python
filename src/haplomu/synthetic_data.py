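"""Synthetic haploid-pedigree datasets with known ground truth.

Emulates the sequencing design of a haploid-diploid pedigree experiment:
one haploid parent pair whose cross yields ``I`` meiotic haploid progeny,
each sequenced to a mean depth, with

* true de novo mutations at rate ``mu_true`` per site per generation,
  private to one progeny and supported by 100% of its reads;
* standing variants heterozygous in the parent pair, inherited by a random
  (>= 2) subset of progeny;
* somatic mosaic variants with partial alt-allele fraction in one progeny;
* repeat-driven mapping artifacts — low-quality alt reads scattered over
  several individuals at repeat-region sites;
* occasional whole-chromosome duplications doubling a progeny's coverage
  on a random chromosome subset;
* contiguous low-coverage (dropout) regions shared across individuals,
  producing realistic non-callable runs.

Depth is modelled per site as independent Poisson draws (the downstream
pipeline consumes depths and allele counts, not reads).  Confounders are
constructed so that none can satisfy all de novo acceptance criteria
simultaneously, which makes the expected false-positive count on clean
synthetic data exactly zero.  All randomness derives deterministically
from one seed: identical config implies byte-identical output.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import poisson as _poisson_dist

from .callable_sites import CoverageTrack
from .denovo_filter import ReadSupport, VariantRecord
from .rate_stats import PedigreeDesign

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "Reference",
    "SimulatedPedigree",
    "generate_reference",
    "simulate_pedigree",
    "simulate_expression",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_DROPOUT_BLOCK = 2000      # nt, mean length of a shared non-callable run
_DROPOUT_MEAN_DEPTH = 1.0  # residual depth inside dropout runs
_REPEAT_BLOCK = 500        # nt, granularity of the repeat annotation


# ---------------------------------------------------------------------------
# fast exact Poisson sampling
#
# Generator.poisson is the bottleneck at genome scale; site depths are
# instead drawn by inverse-CDF lookup: a 16-bit bin table resolves most
# uniforms in O(1) and the ~0.1% of draws landing on a CDF boundary bin are
# finished at full precision.  Distributionally exact to 2^-32.

@functools.lru_cache(maxsize=16)
def _poisson_tables(lam: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    hi = int(_poisson_dist.isf(1e-12, lam)) + 2
    cdf = _poisson_dist.cdf(np.arange(hi), lam)
    grid = np.arange(65537, dtype=np.float64) / 65536.0
    edge = np.searchsorted(cdf, grid, side="right")
    lo = edge[:-1].astype(np.int32)
    ambiguous = edge[:-1] != edge[1:]
    return cdf, lo, ambiguous


def _sample_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    cdf, lo, ambiguous = _poisson_tables(float(lam))
    u = rng.integers(0, 1 << 32, size=size, dtype=np.uint32)
    out = lo[(u >> 16)]
    fix = ambiguous[(u >> 16)]
    if fix.any():
        uf = u[fix].astype(np.float64) / 4294967296.0
        out[fix] = np.searchsorted(cdf, uf, side="right")
    return out.astype(np.int32)


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic pedigree dataset.

    Defaults describe the scaled-down reference condition exercised by the
    test-bed: a 1-Mb genome in 28 chromosomes, 30 meiotic progeny, mean
    depth 30x, and a true rate of 1e-5 mutations/site/generation (about
    300 expected mutations), with every confounder class enabled at a
    realistic low rate.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 28
    repeat_fraction: float = 0.10
    n_progeny: int = 30
    mu_true: float = 1e-5
    mean_depth: float = 30.0
    depth_dropout_fraction: float = 0.05
    error_rate: float = 1e-6
    n_standing_variants: int = 200
    somatic_rate: float = 2e-6
    artifact_rate: float = 5e-4
    wcd_probability: float = 0.033
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "repeat_fraction",
            "mu_true",
            "depth_dropout_fraction",
            "error_rate",
            "somatic_rate",
            "artifact_rate",
            "wcd_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.genome_length < self.n_chromosomes:
            raise ValueError("genome_length must be >= n_chromosomes")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_standing_variants < 0:
            raise ValueError("n_standing_variants must be >= 0")
        if self.mu_true * self.n_progeny > 1.0:
            raise ValueError(
                "mu_true so high that expected mutations per site exceed 1"
            )

    @property
    def chrom_names(self) -> Tuple[str, ...]:
        return tuple(f"chr{i:02d}" for i in range(1, self.n_chromosomes + 1))

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lengths = {name: base for name in self.chrom_names}
        lengths[self.chrom_names[-1]] += self.genome_length - base * self.n_chromosomes
        return lengths

    def design(self) -> PedigreeDesign:
        return PedigreeDesign(
            parents=("parent_f", "parent_m"),
            progeny=tuple(f"progeny_{i:02d}" for i in range(1, self.n_progeny + 1)),
            generations=1,
            scheme="strict",
        )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class Reference:
    """A reference genome as per-chromosome byte arrays plus repeat intervals."""

    sequences: Dict[str, np.ndarray]  # chrom -> array of dtype 'S1'
    repeats: List[Tuple[str, int, int]]  # 0-based half-open intervals

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: int(a.size) for c, a in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[chrom][pos - 1].decode()

    def copy(self) -> "Reference":
        return Reference(
            {c: a.copy() for c, a in self.sequences.items()}, list(self.repeats)
        )


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset, for recall/precision audits."""

    true_mutations: List[Tuple[str, str, int, str, str]]  # individual, chrom, pos, ref, alt
    standing_variants: List[Tuple[str, int, Tuple[str, ...]]]  # chrom, pos, carriers
    somatic_events: List[Tuple[str, str, int, float]]  # individual, chrom, pos, alt_fraction
    artifacts: List[Tuple[str, int, Tuple[str, ...]]]  # chrom, pos, affected individuals
    duplicated_chromosomes: Dict[str, List[str]]
    error_sites: List[Tuple[str, str, int]] = field(default_factory=list)


@dataclass
class SimulatedPedigree:
    """Variant table, coverage tracks and truth for one simulated pedigree."""

    variants: List[VariantRecord]
    tracks: Dict[str, CoverageTrack]
    truth: TruthTable
    design: PedigreeDesign
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(config: SyntheticConfig) -> Reference:
    """Random reference partitioned into chromosomes, with repeat annotation.

    Repeat intervals are contiguous blocks of ``_REPEAT_BLOCK`` nt chosen
    uniformly per chromosome so that their total length approximates
    ``repeat_fraction x genome_length`` to within block granularity.
    """
    rng = config._rng(0)
    sequences: Dict[str, np.ndarray] = {}
    repeats: List[Tuple[str, int, int]] = []
    for chrom, length in config.chrom_lengths.items():
        sequences[chrom] = rng.choice(_BASES, size=length)
        if config.repeat_fraction > 0:
            n_blocks = max(1, length // _REPEAT_BLOCK)
            n_pick = int(round(config.repeat_fraction * n_blocks))
            picked = np.sort(rng.choice(n_blocks, size=n_pick, replace=False))
            # merge adjacent blocks into maximal runs
            run_start = None
            prev = None
            for b in picked:
                if run_start is None:
                    run_start = b
                elif b != prev + 1:
                    repeats.append(
                        (chrom, run_start * _REPEAT_BLOCK, min((prev + 1) * _REPEAT_BLOCK, length))
                    )
                    run_start = b
                prev = b
            if run_start is not None:
                repeats.append(
                    (chrom, run_start * _REPEAT_BLOCK, min((prev + 1) * _REPEAT_BLOCK, length))
                )
    return Reference(sequences=sequences, repeats=repeats)


# ---------------------------------------------------------------------------
# pedigree simulation


def _dropout_blocks(rng: np.random.Generator, length: int, fraction: float) -> List[Tuple[int, int]]:
    """Contiguous dropout runs totalling about ``fraction x length``."""
    if fraction <= 0 or length == 0:
        return []
    n_blocks = max(1, int(round(fraction * length / _DROPOUT_BLOCK)))
    starts = np.sort(rng.integers(0, max(1, length - _DROPOUT_BLOCK), size=n_blocks))
    blocks: List[Tuple[int, int]] = []
    for s in starts:
        e = min(int(s) + _DROPOUT_BLOCK, length)
        if blocks and s <= blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], max(blocks[-1][1], e))
        else:
            blocks.append((int(s), e))
    return blocks


def _global_to_chrom(config: SyntheticConfig, gpos: int) -> Tuple[str, int]:
    """Map a 0-based global offset to (chrom, 1-based position)."""
    for chrom, length in config.chrom_lengths.items():
        if gpos < length:
            return chrom, gpos + 1
        gpos -= length
    raise IndexError("global position beyond genome")


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, len(choices)))]


def simulate_pedigree(
    config: SyntheticConfig,
    reference: Reference,
    extra_mutations: Optional[Sequence[Tuple[str, str, int, str]]] = None,
) -> SimulatedPedigree:
    """Simulate coverage tracks, a multi-sample variant table and its truth.

    Parameters
    ----------
    config
        Study conditions; must match the reference's partitioning.
    reference
        Output of :func:`generate_reference` for the same config.
    extra_mutations
        Optional planted de novo mutations as ``(individual, chrom, pos,
        alt_base)`` tuples — used by the spike-in false-negative
        experiment.  They are appended to the truth table's true
        mutations and receive carrier alt support like any germline event.

    Notes
    -----
    The per-site expected true-mutation count is ``genome_length x
    n_progeny x mu_true``; the realised count is a Poisson draw.  Dropout
    runs are shared across individuals (they model mappability, which is a
    property of the genome, not of a library).
    """
    if reference.chrom_lengths != config.chrom_lengths:
        raise ValueError("reference was generated from a different config")
    design = config.design()
    individuals = list(design.required_individuals)
    n_ind = len(individuals)
    L = config.genome_length
    chrom_names = list(config.chrom_names)
    chrom_lengths = config.chrom_lengths
    offsets: Dict[str, int] = {}
    acc = 0
    for c in chrom_names:
        offsets[c] = acc
        acc += chrom_lengths[c]

    rng_depth = config._rng(1)
    rng_events = config._rng(2)
    rng_wcd = config._rng(3)

    # --- whole-chromosome duplications -----------------------------------
    duplicated: Dict[str, List[str]] = {}
    for prog in design.progeny:
        if rng_wcd.random() < config.wcd_probability:
            k = int(rng_wcd.integers(1, min(4, config.n_chromosomes) + 1))
            chosen = rng_wcd.choice(config.n_chromosomes, size=k, replace=False)
            duplicated[prog] = sorted(chrom_names[i] for i in chosen)

    # --- shared dropout runs (global coordinates) ------------------------
    dropout = _dropout_blocks(rng_depth, L, config.depth_dropout_fraction)

    # --- depth matrix ------------------------------------------------------
    depth = np.empty((n_ind, L), dtype=np.int32)
    for row, ind in enumerate(individuals):
        depth[row] = _sample_poisson(rng_depth, config.mean_depth, L)
        for chrom in duplicated.get(ind, ()):
            s = offsets[chrom]
            e = s + chrom_lengths[chrom]
            depth[row, s:e] = _sample_poisson(rng_depth, 2.0 * config.mean_depth, e - s)
    for s, e in dropout:
        depth[:, s:e] = _sample_poisson(
            rng_depth, _DROPOUT_MEAN_DEPTH, (e - s) * n_ind
        ).reshape(n_ind, e - s)

    # --- event site selection (all categories disjoint) -------------------
    extra = list(extra_mutations or [])
    extra_gpos = {offsets[c] + p - 1 for _ind, c, p, _a in extra}

    n_true = int(rng_events.poisson(L * config.n_progeny * config.mu_true))
    n_som = int(rng_events.poisson(L * config.n_progeny * config.somatic_rate))
    n_err = int(rng_events.poisson(L * n_ind * config.error_rate))
    n_other = n_true + config.n_standing_variants + n_som + n_err
    pool = rng_events.choice(L, size=min(n_other, L), replace=False)
    pool = pool[~np.isin(pool, np.fromiter(extra_gpos, dtype=np.int64, count=len(extra_gpos)))] \
        if extra_gpos else pool
    # partition the pool
    true_g = pool[:n_true]
    standing_g = pool[n_true : n_true + config.n_standing_variants]
    som_g = pool[n_true + config.n_standing_variants : n_true + config.n_standing_variants + n_som]
    err_g = pool[n_true + config.n_standing_variants + n_som :]

    repeat_positions: List[np.ndarray] = []
    for chrom, s, e in reference.repeats:
        repeat_positions.append(np.arange(s, e) + offsets[chrom])
    repeat_g_all = (
        np.concatenate(repeat_positions) if repeat_positions else np.empty(0, dtype=np.int64)
    )
    n_art = int(rng_events.poisson(repeat_g_all.size * config.artifact_rate))
    taken = np.concatenate(
        [pool, np.fromiter(extra_gpos, dtype=np.int64, count=len(extra_gpos))]
    )
    eligible = np.setdiff1d(repeat_g_all, taken, assume_unique=False)
    art_g = (
        rng_events.choice(eligible, size=min(n_art, eligible.size), replace=False)
        if eligible.size
        else np.empty(0, dtype=np.int64)
    )

    truth = TruthTable([], [], [], [], duplicated)
    events: List[Tuple[int, VariantRecord]] = []
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    def base_support(gpos: int) -> Dict[str, ReadSupport]:
        return {
            ind: ReadSupport(int(depth[i, gpos]), 0, 0) for ind, i in ind_index.items()
        }

    def record_at(gpos: int, alt: str, support: Dict[str, ReadSupport], var_class: str = "SNV"):
        chrom, pos = _global_to_chrom(config, int(gpos))
        ref = reference.base(chrom, pos)
        events.append(
            (int(gpos), VariantRecord(chrom, pos, ref, alt, var_class, support))
        )
        return chrom, pos, ref

    # true de novo mutations: carrier alt reads == total reads at the site
    for gpos in true_g:
        prog = design.progeny[int(rng_events.integers(0, config.n_progeny))]
        sup = base_support(int(gpos))
        dp = sup[prog].depth
        chrom, pos = _global_to_chrom(config, int(gpos))
        ref = reference.base(chrom, pos)
        alt = _alt_base(rng_events, ref)
        sup[prog] = ReadSupport(dp, dp, 0)
        record_at(int(gpos), alt, sup)
        truth.true_mutations.append((prog, chrom, pos, ref, alt))

    # planted (spike-in) mutations behave exactly like true mutations
    for ind, chrom, pos, alt in extra:
        gpos = offsets[chrom] + pos - 1
        sup = base_support(gpos)
        dp = sup[ind].depth
        sup[ind] = ReadSupport(dp, dp, 0)
        ref = reference.base(chrom, pos)
        if alt == ref:
            raise ValueError(f"planted alt equals reference base at {chrom}:{pos}")
        events.append((gpos, VariantRecord(chrom, pos, ref, alt, "SNV", sup)))
        truth.true_mutations.append((ind, chrom, pos, ref, alt))

    # standing variants: heterozygous parent pair, >= 2 progeny carriers
    for gpos in standing_g:
        parent = design.parents[int(rng_events.integers(0, 2))]
        carriers = rng_events.random(config.n_progeny) < 0.5
        while carriers.sum() < 2:
            carriers = rng_events.random(config.n_progeny) < 0.5
        sup = base_support(int(gpos))
        chrom, pos = _global_to_chrom(config, int(gpos))
        ref = reference.base(chrom, pos)
        alt = _alt_base(rng_events, ref)
        names = [design.progeny[i] for i in np.flatnonzero(carriers)]
        for who in names + [parent]:
            dp = sup[who].depth
            sup[who] = ReadSupport(dp, dp, 0)
        record_at(int(gpos), alt, sup)
        truth.standing_variants.append((chrom, pos, tuple(names)))

    # somatic mosaics: binomial alt support conditioned strictly inside (0, dp)
    for gpos in som_g:
        prog = design.progeny[int(rng_events.integers(0, config.n_progeny))]
        frac = float(rng_events.uniform(0.2, 0.8))
        sup = base_support(int(gpos))
        dp = sup[prog].depth
        chrom, pos = _global_to_chrom(config, int(gpos))
        truth.somatic_events.append((prog, chrom, pos, frac))
        if dp < 2:
            continue  # no resolvable mosaic signal; site never becomes a record
        ad = int(rng_events.binomial(dp, frac))
        while not 0 < ad < dp:
            ad = int(rng_events.binomial(dp, frac))
        ref = reference.base(chrom, pos)
        alt = _alt_base(rng_events, ref)
        sup[prog] = ReadSupport(dp, ad, 0)
        record_at(int(gpos), alt, sup)

    # repeat artifacts: 1-2 low-quality alt reads in >= 2 individuals
    for gpos in art_g:
        k = int(rng_events.integers(2, min(4, n_ind) + 1))
        who = rng_events.choice(n_ind, size=k, replace=False)
        sup = base_support(int(gpos))
        names = []
        for i in who:
            ind = individuals[int(i)]
            names.append(ind)
            dp = sup[ind].depth
            sup[ind] = ReadSupport(dp, 0, int(rng_events.integers(1, 3)))
        chrom, pos = _global_to_chrom(config, int(gpos))
        ref = reference.base(chrom, pos)
        alt = _alt_base(rng_events, ref)
        record_at(int(gpos), alt, sup)
        truth.artifacts.append((chrom, pos, tuple(sorted(names))))

    # isolated sequencing-error alts: one read, never the full column
    for gpos in err_g:
        ind = individuals[int(rng_events.integers(0, n_ind))]
        sup = base_support(int(gpos))
        dp = sup[ind].depth
        chrom, pos = _global_to_chrom(config, int(gpos))
        truth.error_sites.append((ind, chrom, pos))
        if dp < 2:
            continue
        ref = reference.base(chrom, pos)
        alt = _alt_base(rng_events, ref)
        sup[ind] = ReadSupport(dp, 1, 0)
        record_at(int(gpos), alt, sup)

    events.sort(key=lambda t: t[0])
    variants = [rec for _g, rec in events]

    # coverage tracks are views into the depth matrix, per chromosome
    tracks: Dict[str, CoverageTrack] = {}
    for row, ind in enumerate(individuals):
        depths = {}
        for chrom in chrom_names:
            s = offsets[chrom]
            depths[chrom] = depth[row, s : s + chrom_lengths[chrom]]
        tracks[ind] = CoverageTrack(individual=ind, depths=depths)

    return SimulatedPedigree(
        variants=variants, tracks=tracks, truth=truth, design=design, config=config
    )


# ---------------------------------------------------------------------------
# expression table for the dosage analysis


def simulate_expression(
    chromosomes: Sequence[str],
    duplicated_chromosomes: Sequence[str],
    n_genes: int = 500,
    fold: float = 1.71,
    sigma: float = 0.2,
    n_replicates: int = 3,
    base_tpm_log_mean: float = 3.0,
    base_tpm_log_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic TPM table with a known dosage fold on duplicated chromosomes.

    Each gene gets a lognormal baseline TPM; control replicates multiply it
    by lognormal noise ``exp(N(0, sigma))`` and test replicates by the same
    noise times ``fold`` when the gene sits on a duplicated chromosome.
    The multiplicative noise bias cancels between the two gene partitions,
    so the group fold ratio recovers ``fold``.

    Returns a DataFrame with columns ``gene``, ``chrom``, ``test_1..n``
    and ``control_1..n``.
    """
    rng = np.random.default_rng(seed)
    chroms = rng.choice(list(chromosomes), size=n_genes)
    base = np.exp(rng.normal(base_tpm_log_mean, base_tpm_log_sd, size=n_genes))
    dup = np.isin(chroms, list(duplicated_chromosomes))
    data: Dict[str, object] = {
        "gene": [f"gene_{i:05d}" for i in range(n_genes)],
        "chrom": chroms,
    }
    for r in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(0.0, sigma, size=n_genes))
        data[f"test_{r}"] = base * np.where(dup, fold, 1.0) * noise
    for r in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(0.0, sigma, size=n_genes))
        data[f"control_{r}"] = base * noise
    return pd.DataFrame(data)
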