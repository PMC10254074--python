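"""Windowed coverage, duplication calling, event counting, dosage folds."""

import numpy as np
import pandas as pd
import pytest

from haplomu import (
    CoverageTrack,
    count_duplication_events,
    detect_duplications,
    dosage_ratio,
    simulate_expression,
    window_coverage,
)
from haplomu.wcd_detection import DuplicationCall, WindowCoverage


def make_track(chrom_depths, ind="x"):
    return CoverageTrack(
        ind, {c: np.asarray(d, dtype=np.int32) for c, d in chrom_depths.items()}
    )


def wc_from_ratios(ratios, baseline=30.0, n_windows=20):
    """WindowCoverage with chromosomes at given coverage ratios to baseline."""
    rows = []
    for i, r in enumerate(ratios, 1):
        for w in range(n_windows):
            rows.append((f"c{i}", w * 5000, (w + 1) * 5000, baseline * r))
    return WindowCoverage("x", 5000, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mean_depth"]
    ))


class TestWindowCoverage:
    def test_uniform_depth_uniform_windows(self):
        wc = window_coverage(make_track({"c1": [30] * 20_000}), 5000)
        assert (wc.windows["mean_depth"] == 30).all()

    def test_terminal_window_is_short(self):
        wc = window_coverage(make_track({"c1": [10] * 12_000}), 5000)
        spans = list(zip(wc.windows["start"], wc.windows["end"]))
        assert spans == [(0, 5000), (5000, 10_000), (10_000, 12_000)]

    def test_window_mean_is_weighted_average(self):
        depths = [30] * 2500 + [10] * 2500
        wc = window_coverage(make_track({"c1": depths}), 5000)
        assert wc.windows["mean_depth"].iloc[0] == pytest.approx(20.0)

    def test_partition_completeness(self):
        wc = window_coverage(make_track({"c1": [5] * 13_333, "c2": [5] * 7_001}), 5000)
        for chrom, grp in wc.windows.groupby("chrom"):
            lengths = (grp["end"] - grp["start"]).sum()
            assert lengths == {"c1": 13_333, "c2": 7_001}[chrom]
            assert (grp["start"].values[1:] == grp["end"].values[:-1]).all()

    def test_excluded_chromosome_absent_with_warning_on_unknown(self):
        track = make_track({"c1": [5] * 6000, "Chr_00": [5] * 6000})
        wc = window_coverage(track, 5000, exclude_chroms=["Chr_00"])
        assert set(wc.windows["chrom"]) == {"c1"}
        with pytest.warns(UserWarning, match="nope"):
            window_coverage(track, 5000, exclude_chroms=["nope"])

    def test_bad_window_size_rejected(self):
        with pytest.raises(ValueError):
            window_coverage(make_track({"c1": [5]}), 0)


class TestDetectDuplications:
    def test_reported_ratio_tiers(self):
        # four duplicated chromosomes and ten normal ones
        wc = wc_from_ratios([2.0, 1.9, 1.9, 2.1] + [1.0] * 10)
        calls = {c.chromosome: c for c in detect_duplications(wc)}
        for dup in ("c1", "c2", "c3", "c4"):
            assert calls[dup].status == "duplicated"
        assert all(calls[f"c{i}"].status == "normal" for i in range(5, 15))

    def test_ratio_1_8_is_ambiguous_not_duplicated(self):
        wc = wc_from_ratios([1.8] + [1.0] * 10)
        calls = {c.chromosome: c for c in detect_duplications(wc)}
        assert calls["c1"].status == "ambiguous"
        assert count_duplication_events(list(calls.values())) == 0

    def test_all_normal(self):
        calls = detect_duplications(wc_from_ratios([1.0] * 6))
        assert all(c.status == "normal" for c in calls)

    def test_scaling_invariance(self):
        wc1 = wc_from_ratios([2.0] + [1.0] * 8, baseline=30.0)
        wc2 = wc_from_ratios([2.0] + [1.0] * 8, baseline=90.0)
        r1 = [c.ratio for c in detect_duplications(wc1)]
        r2 = [c.ratio for c in detect_duplications(wc2)]
        assert r1 == pytest.approx(r2)

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            detect_duplications(wc_from_ratios([1.0]))

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            detect_duplications(wc_from_ratios([1.0] * 3), 1.5, 1.9)


class TestEventCounting:
    def test_co_duplication_is_one_event(self):
        calls = [
            DuplicationCall("L27", c, 2.0, "duplicated")
            for c in ("c14", "c16", "c18", "c19")
        ] + [DuplicationCall("L31", "c19", 1.8, "ambiguous")]
        assert count_duplication_events(calls) == 1
        assert count_duplication_events(calls, per_chromosome=True) == 4


class TestDosage:
    def test_identical_expression_fold_one(self):
        expr = simulate_expression(["c1", "c2"], [], n_genes=80, sigma=0.0, seed=2)
        fold, per_gene = dosage_ratio(expr, ["c2"])
        assert fold == pytest.approx(1.0)
        assert set(per_gene.columns) >= {"gene", "chrom", "ratio", "duplicated"}

    def test_monte_carlo_fold_recovery(self):
        """Injected 1.7-fold with lognormal noise recovers to within 0.05."""
        folds = []
        for seed in range(20):
            expr = simulate_expression(
                [f"c{i}" for i in range(1, 11)], ["c1", "c2"],
                n_genes=500, fold=1.7, sigma=0.2, seed=seed,
            )
            fold, _ = dosage_ratio(expr, ["c1", "c2"])
            folds.append(fold)
        assert np.mean(folds) == pytest.approx(1.7, abs=0.05)

    def test_tpm_floor_drops_low_expression_genes(self):
        expr = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "chrom": ["c1", "c2", "c2"],
                "test_1": [10.0, 0.5, 8.0],
                "control_1": [10.0, 0.5, 4.0],
            }
        )
        fold, per_gene = dosage_ratio(expr, ["c2"], tpm_min=1.0)
        assert list(per_gene["gene"]) == ["g1", "g3"]
        assert fold == pytest.approx(2.0)

    def test_median_aggregation_supported(self):
        expr = simulate_expression(["c1", "c2"], ["c2"], n_genes=60, sigma=0.0, seed=3)
        fold, _ = dosage_ratio(expr, ["c2"], agg="median")
        assert fold == pytest.approx(1.71, abs=0.01)

    def test_empty_partition_rejected(self):
        expr = simulate_expression(["c1"], [], n_genes=10, sigma=0.0, seed=1)
        with pytest.raises(ValueError):
            dosage_ratio(expr, ["c9"])
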