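import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from haplomu import (
    PedigreeDesign,
    ReadSupport,
    SyntheticConfig,
    VariantRecord,
    generate_reference,
    simulate_pedigree,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small, fast study condition: 60-kb genome, 4 chromosomes, 6 progeny."""
    return SyntheticConfig(
        genome_length=60_000,
        n_chromosomes=4,
        n_progeny=6,
        mu_true=2e-4,
        n_standing_variants=30,
        somatic_rate=5e-5,
        artifact_rate=2e-3,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    reference = generate_reference(tiny_config)
    return simulate_pedigree(tiny_config, reference)


@pytest.fixture
def design() -> PedigreeDesign:
    return PedigreeDesign(
        parents=("mother", "father"),
        progeny=("p1", "p2", "p3"),
        generations=1,
    )


def make_record(
    design: PedigreeDesign,
    carrier: str | None = "p1",
    carrier_depth: int = 12,
    carrier_alt: int = 12,
    other_depth: int = 15,
    pos: int = 5,
    chrom: str = "chr01",
    lqa: dict | None = None,
    extra_alt: dict | None = None,
    var_class: str = "SNV",
    ref: str = "A",
    alt: str = "T",
) -> VariantRecord:
    """One variant record with uniform background support plus overrides."""
    support = {}
    for ind in design.all_individuals:
        support[ind] = ReadSupport(other_depth, 0, 0)
    if carrier is not None:
        support[carrier] = ReadSupport(carrier_depth, carrier_alt, 0)
    for ind, n in (lqa or {}).items():
        s = support[ind]
        support[ind] = ReadSupport(s.depth, s.alt_depth, n)
    for ind, ad in (extra_alt or {}).items():
        s = support[ind]
        support[ind] = ReadSupport(s.depth, ad, s.low_quality_alt)
    return VariantRecord(chrom, pos, ref, alt, var_class, support)


@pytest.fixture
def full_mask():
    def _make(design=None, size=1000, chroms=("chr01",)):
        return {c: np.ones(size, dtype=bool) for c in chroms}

    return _make
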