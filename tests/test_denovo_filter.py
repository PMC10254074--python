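"""Haploid de novo filtering criteria, rejection ordering, SV proximity."""

import numpy as np
import pytest

from haplomu import (
    decompose_multiallelic,
    filter_structural_candidates,
    find_denovo_candidates,
    sensitivity_sweep,
)
from haplomu.denovo_filter import REJECTION_ORDER

from conftest import make_record


@pytest.fixture
def mask():
    return {"chr01": np.ones(100, dtype=bool)}


class TestCoreCriteria:
    def test_clean_unique_full_fraction_accepted(self, design, mask):
        rec = make_record(design, carrier="p1", carrier_depth=12, carrier_alt=12)
        (cand,) = find_denovo_candidates([rec], mask, design)
        assert cand.accepted
        assert cand.carrier == "p1"

    def test_partial_fraction_rejected_as_somatic(self, design, mask):
        rec = make_record(design, carrier_depth=12, carrier_alt=11)
        (cand,) = find_denovo_candidates([rec], mask, design)
        assert cand.reason == "partial_fraction"

    def test_shared_between_progeny_rejected(self, design, mask):
        rec = make_record(design, extra_alt={"p2": 5})
        (cand,) = find_denovo_candidates([rec], mask, design)
        assert cand.reason == "shared_carriers"

    def test_low_quality_alt_in_other_individual_rejected(self, design, mask):
        rec = make_record(
            design, carrier_depth=10, carrier_alt=10, lqa={"father": 1}
        )
        (cand,) = find_denovo_candidates([rec], mask, design)
        assert cand.reason == "alt_in_others"

    def test_parent_alt_reads_rejected(self, design, mask):
        rec = make_record(design, extra_alt={"mother": 3})
        (cand,) = find_denovo_candidates([rec], mask, design)
        assert cand.reason == "alt_in_others"

    def test_uncallable_site_rejected_first(self, design):
        empty = {"chr01": np.zeros(100, dtype=bool)}
        # fails callability AND uniqueness; order fixes the reported reason
        rec = make_record(design, extra_alt={"p2": 4})
        (cand,) = find_denovo_candidates([rec], empty, design)
        assert cand.reason == "not_callable"

    def test_no_alt_evidence_anywhere_fails_uniqueness(self, design, mask):
        rec = make_record(design, carrier="p1", carrier_alt=0, carrier_depth=12)
        (cand,) = find_denovo_candidates([rec], mask, design)
        assert cand.reason == "shared_carriers"

    def test_check_individual_alt_is_vetoed_only_when_enabled(self, mask, design):
        import dataclasses

        with_check = dataclasses.replace(design, check_individuals=("g0",))
        rec = make_record(with_check, extra_alt={"g0": 2})
        (cand,) = find_denovo_candidates([rec], mask, with_check)
        assert cand.reason == "alt_in_others"
        (cand,) = find_denovo_candidates(
            [rec], mask, with_check, include_checks=False
        )
        assert cand.accepted


class TestBookkeeping:
    def test_every_record_gets_exactly_one_status(self, design, mask):
        recs = [
            make_record(design, pos=1),
            make_record(design, pos=2, carrier_alt=6, carrier_depth=12),
            make_record(design, pos=3, extra_alt={"p3": 2}),
        ]
        cands = find_denovo_candidates(recs, mask, design)
        assert len(cands) == len(recs)
        statuses = [(c.status, c.reason) for c in cands]
        assert all(
            s == "accepted" and r is None or s == "rejected" and r in REJECTION_ORDER
            for s, r in statuses
        )

    def test_unknown_individual_in_record_raises(self, design, mask):
        rec = make_record(design)
        rec.support["stranger"] = rec.support["p1"]
        with pytest.raises(KeyError, match="stranger"):
            find_denovo_candidates([rec], mask, design)

    def test_missing_support_for_required_individual_raises(self, design, mask):
        rec = make_record(design)
        del rec.support["p2"]
        with pytest.raises(KeyError, match="p2"):
            find_denovo_candidates([rec], mask, design)

    def test_multiallelic_must_be_decomposed(self, design, mask):
        rec = make_record(design, alt="T,G")
        with pytest.raises(ValueError, match="decompose"):
            find_denovo_candidates([rec], mask, design)
        parts = decompose_multiallelic([rec])
        assert [p.alt for p in parts] == ["T", "G"]
        assert all(p.pos == rec.pos for p in parts)


class TestStructural:
    def test_isolated_sv_accepted(self, design, mask):
        sv = make_record(design, pos=10, var_class="SV")
        far = make_record(
            design, carrier="p2", pos=90, var_class="SV", chrom="chr02"
        )
        cands = filter_structural_candidates(
            [sv, far], design, mask={"chr01": np.ones(100, bool), "chr02": np.ones(100, bool)},
            proximity_window=50,
        )
        assert all(c.accepted for c in cands)

    def test_nearby_same_class_variant_in_other_individual_rejected(self, design, mask):
        sv = make_record(design, pos=40, var_class="SV")
        near = make_record(design, carrier="p2", pos=60, var_class="SV")
        cands = filter_structural_candidates([sv, near], design, mask, proximity_window=50)
        assert {c.reason for c in cands} == {"proximity"}

    def test_window_arithmetic_boundary(self, design, mask):
        sv = make_record(design, pos=10, var_class="SV")
        just_outside = make_record(design, carrier="p2", pos=62, var_class="SV")
        cands = filter_structural_candidates(
            [sv, just_outside], design, mask, proximity_window=51
        )
        assert all(c.accepted for c in cands)

    def test_empty_sv_list(self, design, mask):
        assert filter_structural_candidates([], design, mask) == []

    def test_negative_window_rejected(self, design, mask):
        with pytest.raises(ValueError):
            filter_structural_candidates([], design, mask, proximity_window=-1)

    def test_non_sv_record_rejected(self, design, mask):
        with pytest.raises(ValueError, match="non-SV"):
            filter_structural_candidates([make_record(design)], design, mask)


class TestSensitivitySweep:
    def test_threshold_one_reproduces_strict_filter(self, design, mask):
        recs = [
            make_record(design, pos=1),
            make_record(design, pos=2, carrier_depth=20, carrier_alt=19),
        ]
        counts = sensitivity_sweep(recs, mask, design, thresholds=(1.0,))
        strict = sum(c.accepted for c in find_denovo_candidates(recs, mask, design))
        assert counts[1.0] == strict == 1

    def test_somatic_fraction_enters_at_relaxed_threshold(self, design, mask):
        # 19/20 = 0.95: counted at threshold 0.9, excluded at 1.0
        rec = make_record(design, pos=2, carrier_depth=20, carrier_alt=19)
        counts = sensitivity_sweep([rec], mask, design, thresholds=(0.9, 1.0))
        assert counts[0.9] == 1
        assert counts[1.0] == 0

    def test_clean_mutations_insensitive_to_stringency(self, design, mask):
        recs = [make_record(design, pos=p) for p in (1, 5, 9)]
        counts = sensitivity_sweep(recs, mask, design, thresholds=(0.9, 1.0))
        assert counts[0.9] == counts[1.0] == 3

    def test_invalid_threshold_rejected(self, design, mask):
        with pytest.raises(ValueError):
            find_denovo_candidates([], mask, design, fraction_threshold=0.0)
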