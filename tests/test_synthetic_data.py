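"""Generator properties: determinism, truth-table structure, signal recoverability."""

import dataclasses

import numpy as np
import pytest

from haplomu import (
    SyntheticConfig,
    generate_reference,
    simulate_expression,
    simulate_pedigree,
)


class TestReference:
    def test_equal_partition_into_chromosomes(self):
        cfg = SyntheticConfig(genome_length=280_000, n_chromosomes=28, seed=1)
        ref = generate_reference(cfg)
        assert len(ref.sequences) == 28
        assert all(arr.size == 10_000 for arr in ref.sequences.values())

    def test_zero_repeat_fraction_empty_annotation(self):
        cfg = SyntheticConfig(genome_length=50_000, n_chromosomes=2,
                              repeat_fraction=0.0, seed=1)
        assert generate_reference(cfg).repeats == []

    def test_repeat_annotation_totals_requested_fraction(self):
        cfg = SyntheticConfig(genome_length=100_000, n_chromosomes=4,
                              repeat_fraction=0.2, seed=5)
        ref = generate_reference(cfg)
        total = sum(e - s for _c, s, e in ref.repeats)
        # granularity: one block per chromosome either way
        assert abs(total - 20_000) <= 4 * 500

    def test_sequence_is_acgt(self):
        cfg = SyntheticConfig(genome_length=4_000, n_chromosomes=2, seed=2)
        ref = generate_reference(cfg)
        for arr in ref.sequences.values():
            assert set(np.unique(arr)) <= {b"A", b"C", b"G", b"T"}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("repeat_fraction", 1.5),
            ("mu_true", -1e-9),
            ("wcd_probability", 2.0),
            ("depth_dropout_fraction", -0.1),
        ],
    )
    def test_rate_fields_validated_by_name(self, field, value):
        with pytest.raises(ValueError, match=field):
            SyntheticConfig(**{field: value})

    def test_saturating_mutation_rate_refused(self):
        with pytest.raises(ValueError, match="mu_true"):
            SyntheticConfig(mu_true=0.1, n_progeny=30)

    def test_genome_shorter_than_chromosome_count_refused(self):
        with pytest.raises(ValueError):
            SyntheticConfig(genome_length=10, n_chromosomes=28)


class TestSimulation:
    def test_zero_rate_yields_no_true_mutations(self):
        cfg = SyntheticConfig(genome_length=40_000, n_chromosomes=2, n_progeny=4,
                              mu_true=0.0, seed=3)
        sim = simulate_pedigree(cfg, generate_reference(cfg))
        assert sim.truth.true_mutations == []

    def test_deterministic_given_seed(self, tiny_config):
        ref = generate_reference(tiny_config)
        a = simulate_pedigree(tiny_config, ref)
        b = simulate_pedigree(tiny_config, ref)
        assert a.variants == b.variants
        assert a.truth.true_mutations == b.truth.true_mutations
        assert a.truth.duplicated_chromosomes == b.truth.duplicated_chromosomes
        for ind in a.tracks:
            for chrom in a.tracks[ind].depths:
                assert np.array_equal(
                    a.tracks[ind].depths[chrom], b.tracks[ind].depths[chrom]
                )

    def test_mismatched_reference_refused(self, tiny_config):
        other = dataclasses.replace(tiny_config, genome_length=80_000)
        with pytest.raises(ValueError, match="different config"):
            simulate_pedigree(other, generate_reference(tiny_config))

    def test_true_mutations_recoverable_in_principle(self, tiny_sim):
        """Carrier alt fraction 1.0 and zero alt evidence in all others."""
        by_pos = {(r.chrom, r.pos): r for r in tiny_sim.variants}
        assert tiny_sim.truth.true_mutations
        for ind, chrom, pos, ref, alt in tiny_sim.truth.true_mutations:
            rec = by_pos[(chrom, pos)]
            assert rec.alt == alt
            s = rec.support[ind]
            assert s.alt_depth == s.depth
            for other, sup in rec.support.items():
                if other != ind:
                    assert sup.alt_depth == 0 and sup.low_quality_alt == 0

    def test_confounders_structurally_separated(self, tiny_sim):
        by_pos = {(r.chrom, r.pos): r for r in tiny_sim.variants}
        for chrom, pos, carriers in tiny_sim.truth.standing_variants:
            assert len(carriers) >= 2
        for ind, chrom, pos, frac in tiny_sim.truth.somatic_events:
            assert 0.0 < frac < 1.0
            rec = by_pos.get((chrom, pos))
            if rec is not None:
                s = rec.support[ind]
                assert 0 < s.alt_depth < s.depth
        assert tiny_sim.truth.artifacts
        for chrom, pos, affected in tiny_sim.truth.artifacts:
            assert len(affected) >= 2
            rec = by_pos[(chrom, pos)]
            for who in affected:
                assert rec.support[who].low_quality_alt >= 1
                assert rec.support[who].alt_depth == 0

    def test_mutation_count_matches_poisson_expectation(self):
        """Mean true-mutation count over seeds within 3 SE of L*I*mu."""
        L, I, mu, n_seeds = 100_000, 10, 1e-4, 40
        expected = L * I * mu  # 100 per replicate
        counts = []
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                genome_length=L, n_chromosomes=4, n_progeny=I, mu_true=mu,
                n_standing_variants=0, somatic_rate=0.0, artifact_rate=0.0,
                wcd_probability=0.0, seed=seed,
            )
            sim = simulate_pedigree(cfg, generate_reference(cfg))
            counts.append(len(sim.truth.true_mutations))
        se = np.sqrt(expected / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_forced_duplication_doubles_coverage(self):
        cfg = SyntheticConfig(
            genome_length=200_000, n_chromosomes=8, n_progeny=3,
            wcd_probability=1.0, depth_dropout_fraction=0.0, seed=9,
        )
        sim = simulate_pedigree(cfg, generate_reference(cfg))
        assert set(sim.truth.duplicated_chromosomes) == set(sim.design.progeny)
        for ind, chroms in sim.truth.duplicated_chromosomes.items():
            assert chroms
            normal = [c for c in cfg.chrom_names if c not in chroms]
            base = np.mean(
                [sim.tracks[ind].depths[c].mean() for c in normal]
            )
            for c in chroms:
                ratio = sim.tracks[ind].depths[c].mean() / base
                assert ratio == pytest.approx(2.0, abs=0.1)


class TestExpressionTable:
    def test_exact_twofold_without_noise(self):
        expr = simulate_expression(
            ["c1", "c2"], ["c2"], n_genes=100, fold=2.0, sigma=0.0, seed=1
        )
        from haplomu import dosage_ratio

        fold, _per_gene = dosage_ratio(expr, ["c2"])
        assert fold == pytest.approx(2.0)

    def test_columns_and_determinism(self):
        a = simulate_expression(["c1"], [], n_genes=10, seed=4)
        b = simulate_expression(["c1"], [], n_genes=10, seed=4)
        assert list(a.columns[:2]) == ["gene", "chrom"]
        assert a.equals(b)
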