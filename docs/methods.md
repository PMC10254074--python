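# Methods

`haplomu` estimates spontaneous mutation rates from haploid pedigree
sequencing designs of the kind used for haploid–diploid organisms such as
brown algae: a diploid sporophyte undergoes meiosis, a set of haploid
gametophyte progeny is isolated and sequenced together with the haploid
parent pair, and every variant private to a single progeny is a candidate
de novo mutation. This note records the models, parameter choices and
numerical decisions behind the package; nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Rate model

Observed de novo mutations are treated as a Poisson count `n` over an
exposure of `T = G* × I × g` site-generations, where `G*` is the number of
callable sites, `I` the number of progeny and `g` the generations per
progeny. The point estimate is `µ = n / T`. The confidence interval is the
exact (Garwood) Poisson interval from chi-square quantiles:

    low  = χ²(α/2, 2n) / 2T      (0 when n = 0)
    high = χ²(1 − α/2, 2n + 2) / 2T

The exact interval is used because pedigree counts are tiny (single
digits); normal approximations are badly anticonservative there. The
Garwood interval is conservative — its empirical coverage at small means
sits slightly above the nominal 95%, which the test suite verifies over
2,000 simulated draws.

Two callable-site accounting schemes are supported:

* **strict** — a site counts iff depth ≥ `min_depth` in *every* required
  individual (parents plus all progeny); every progeny shares the same
  `G*`, so `I` enters the exposure explicitly. A published cutoff phrased
  as "coverage > 9×" is integer depth ≥ 10 — depths are integers, so the
  two are identical.
* **quorum** — for designs with lower or uneven coverage: per site, `i` is
  the number of individuals at depth ≥ `min_depth`, `N_i` the number of
  sites with exactly that `i`, and `G* = Σ_{i≥k} i × N_i` for quorum `k`.
  The individual exposure is folded into `G*`, so downstream `I = 1`. The
  distinct-site count `Σ N_i` is reported separately because the
  genome-fraction statistic uses sites, not site-individuals.

Both schemes are positionwise definitions; the interval (BED) pathway is
run-length encoding of the same arrays and the tests hold it equal to a
per-base brute-force oracle.

## Filtering criteria

A candidate is accepted iff, in this order: (1) the site is callable; (2)
exactly one progeny shows any alt evidence — high- or low-quality; (3) the
carrier's alt reads equal its total depth (alt fraction 1.0 — a haploid
genome cannot be heterozygous, so partial fractions indicate somatic
mosaicism); (4) no other individual, parents and optional check
individuals included, has a single alt read *even at low quality*
(low-level alt reads scattered over individuals are the signature of
repeat mis-mapping). Rejections always carry the first failing criterion,
so reports are deterministic. A record with *zero* alt-bearing progeny
(e.g. parent-only alt evidence) fails criterion (2) and is reported as
`shared_carriers`, the uniqueness reason.

Decisions within this scheme:

* Low-quality alt reads count toward carrier identification (a progeny
  with only low-quality alt evidence is a carrier for the uniqueness test)
  but not toward the fraction numerator; the fraction denominator is the
  caller's total depth. This is the conservative reading of "100% of the
  coverage".
* Multi-allelic records are decomposed into per-alt records before
  filtering; the criteria are per-allele.
* Indels and SNVs share identical logic; structural variants additionally
  fail (`proximity`) when another individual carries a same-class variant
  within `proximity_window` nt (default 1000 — SV callers replicate one
  imprecise event at shifted coordinates). The window is a flag because no
  principled universal value exists.
* `sensitivity_sweep` reruns acceptance at relaxed alt-fraction thresholds
  (default 0.9 and 1.0) as a stringency-robustness check: clean haploid
  mutations are insensitive to the threshold, somatic mosaics enter as it
  drops.

## Synthetic pedigree generator

The generator produces the inputs the pipeline consumes — per-site depths
and allele counts — not reads. Defaults define the package's reference
study condition: genome 1 Mb in 28 chromosomes, 30 progeny, mean depth
30×, `µ_true = 1e-5` per site per generation (≈ 300 expected mutations per
dataset, enough for tight parameter-recovery statistics at tractable
cost), repeat fraction 0.10, 5% dropout, 200 standing variants, somatic
rate 2e-6, artifact rate 5e-4 per repeat site, whole-chromosome
duplication probability 0.033 per progeny (one expected event per 30
progeny). Every random quantity derives from one seed through named
`SeedSequence` streams, so identical configurations are byte-identical.

Model choices:

* **Depth** is independent Poisson per site. Real short-read depth is
  overdispersed and GC-biased; Poisson is the stated simplification, since
  only threshold crossings and window means matter downstream. Sampling
  uses an exact inverse-CDF lookup table (16-bit bins, boundary bins
  resolved at full precision) because genome-scale `Generator.poisson`
  dominates runtime otherwise; the table is distributionally exact to
  2⁻³².
* **Dropout** (non-callable) runs of mean length 2 kb are drawn once per
  dataset and shared by all individuals, modelling mappability — a
  property of the genome. Independent per-individual dropout at 5% across
  32 individuals would leave only ~20% of the genome strictly callable,
  which resembles no real design.
* **Confounders are separated by construction**, making the expected
  false-positive count exactly zero: standing variants always have ≥ 2
  progeny carriers plus an alt-bearing parent; somatic alt support is a
  binomial draw conditioned on 1 ≤ alt < depth (alt fraction drawn from
  U(0.2, 0.8)); artifacts place only low-quality alt reads in ≥ 2
  individuals at repeat sites; isolated sequencing-error alts are a single
  read at sites with depth ≥ 2. All event categories occupy disjoint
  sites. Consequently, a zero-false-positive test on synthetic data
  validates the filter logic, *not* robustness to confounders the
  generator does not produce (e.g. a somatic mosaic whose binomial draw
  happens to reach 100% — excluded here by conditioning, possible in real
  data at low depth, and the reason the real protocol adds orthogonal PCR
  validation).
* **Duplications** double the Poisson mean over a random subset of 1–4
  chromosomes (one mis-segregation event can involve several
  chromosomes).

What passing tests therefore show: the estimator is unbiased and its
intervals cover under the generator's assumptions, and the filters
implement their definitions exactly. What they do not show: performance
under alignment artifacts, overdispersed coverage, index hopping, or
caller-specific quirks of real data.

## Spike-in false-negative experiment

`n` mutations toward a target base (default G, default 100) are planted on
a deterministic even grid across a chromosome region; grid points whose
base already equals the target shift to the next eligible site, so every
spike is a real change and is exactly revertible. The even grid is an
assumption — the original protocol's placement rule is not specified
beyond its range. The planted sites become germline mutations of one
designated progeny; the dataset is regenerated, filtered, and each miss is
classified `non_callable` (mask excludes the site) or `filtered:<reason>`.
Recovery requires an exact (chrom, pos, alt) match. On clean synthetic
data every miss is `non_callable`, so the measured FNR is the callability
loss of the spiked region.

## Duplication detection and dosage

Depth is averaged in fixed 5-kb windows (terminal windows short). For
each chromosome the baseline is the *median* window mean over all other
chromosomes, and the ratio is the chromosome's own *median* window mean
over that baseline. The median on both sides is deliberate: dropout or
otherwise non-callable windows drag a truly duplicated chromosome's mean
toward 2 × (1 − dropout) ≈ 1.9, exactly at the call threshold, while the
median is insensitive to them (a mean aggregate remains available via
`chrom_agg="mean"`). Thresholds: ratio ≥ 1.9 → duplicated; 1.5 ≤ ratio
< 1.9 → ambiguous (an early somatic duplication carried by most cells
cannot be excluded, so such chromosomes are flagged, not counted);
otherwise normal. Co-duplicated chromosomes in one individual count as
one event by default (single mis-segregation), with per-chromosome
counting behind a flag.

Dosage: genes with mean TPM above the floor (default 1) in *both* strains
form per-gene ratios (mean test TPM / mean control TPM); the reported fold
is the aggregate ratio of duplicated-chromosome genes over the rest.
Aggregation is the mean by default and the median by option — the choice
is not standardised, so it is exposed; under multiplicative lognormal
noise the bias term cancels between the partitions either way.

## Effective population size

`Ne = π_s / 4µ` under neutral equilibrium, with the rate interval
propagated reciprocally (upper µ bound → lower Ne bound). The unrounded
`n/T` rate is used; display rounding is cosmetic. These estimates inherit
every caveat of equilibrium diversity — demographic history is ignored —
and should be read as order-of-magnitude.

## Problem sizes and numerical notes

The reference synthetic condition (1 Mb × 32 individuals) keeps a full
parameter-recovery study of 200 seeded pedigrees, the spike-in experiment
and the duplication study inside a few minutes on one CPU; the recovery
study asserts empirical CI coverage ≥ 0.92, i.e. the nominal 95% minus
two binomial standard errors for 200 draws. Depth matrices are int32;
coverage tracks expose per-chromosome views without copying. Degenerate
inputs fail loudly: zero callable sites, empty required-individual sets,
single-chromosome duplication baselines, empty dosage partitions and
saturating mutation rates (`µ_true × I > 1` expected mutations per site)
all raise with the offending field named.

## Known limitations

Read-level phenomena (quality modelling, mapping, caller behaviour) are
out of scope — the variant table is the input. Recombination, selection
during propagation, and sub-chromosomal CNVs are not modelled. The quorum
scheme assumes exchangeable individuals when folding `i` into `G*`. The
dosage analysis compares one test strain against one control and does not
test individual genes for differential expression.
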