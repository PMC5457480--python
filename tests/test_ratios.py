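"""Ratio scores, window medians, histograms, summaries, compensation calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dosagescan as ds
from dosagescan.ratios import round_half_up_pct


def make_pair(records):
    df = pd.DataFrame(records, columns=["control", "variant"],
                      index=[f"g{i}" for i in range(len(records))])
    return ds.ExpressionPair.from_frame(df)


def make_catalog(n, chrom="Chr1", start0=100, spacing=1000):
    return ds.GeneCatalog(
        [
            ds.GeneModel(f"g{i}", chrom, start0 + i * spacing,
                         start0 + i * spacing + 10)
            for i in range(n)
        ]
    )


class TestComputeRatios:
    def test_six_gene_toy_classification(self):
        pair = make_pair([(1, 1), (1, 2), (2, 1), (0, 1), (1, 0), (0, 0)])
        table = ds.compute_ratios(pair)
        assert list(table.data["dosage_class"]) == [
            "neutral", "up", "down", "up", "down", "both_zero"
        ]
        assert len(table.defined) == 3

    def test_thresholds_inclusive(self):
        pair = make_pair([(1.0, 2.0), (2.0, 1.0)])
        table = ds.compute_ratios(pair)
        assert list(table.data["dosage_class"]) == ["up", "down"]

    def test_strict_threshold_option(self):
        pair = make_pair([(1.0, 2.0), (2.0, 1.0)])
        table = ds.compute_ratios(pair, inclusive=False)
        assert list(table.data["dosage_class"]) == ["neutral", "neutral"]

    def test_zero_classes_recorded(self):
        pair = make_pair([(0, 1), (1, 0), (0, 0)])
        table = ds.compute_ratios(pair)
        assert list(table.data["zero_class"]) == [
            "control_zero", "variant_zero", "both_zero"
        ]
        assert table.data["ratio"].isna().all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False, width=32),
                st.floats(0, 100, allow_nan=False, width=32),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_class_partition_property(self, records):
        table = ds.compute_ratios(make_pair(records))
        counts = table.data["dosage_class"].value_counts()
        assert counts.sum() == len(records)
        expressed = table.data["expressed"].sum()
        assert expressed + (table.data["zero_class"] == "both_zero").sum() == len(records)


class TestWindowMedian:
    def test_constant_ratios_give_constant_medians(self):
        pair = make_pair([(2.0, 2.0)] * 10)
        table = ds.compute_ratios(pair)
        prof = ds.sliding_window_median(table, make_catalog(10), window=4)
        assert (prof.data["median"] == 1.0).all()
        assert len(prof) == 7

    def test_small_example_order_statistic(self):
        pair = make_pair([(1, 1), (1, 1), (1, 1), (1, 5)])
        table = ds.compute_ratios(pair)
        prof = ds.sliding_window_median(table, make_catalog(4), window=3)
        assert list(prof.data["median"]) == [1.0, 1.0]

    def test_windows_do_not_span_chromosomes(self):
        genes = [
            ds.GeneModel("g0", "Chr1", 100, 110),
            ds.GeneModel("g1", "Chr1", 200, 210),
            ds.GeneModel("g2", "Chr2", 100, 110),
            ds.GeneModel("g3", "Chr2", 200, 210),
        ]
        pair = make_pair([(1, 1)] * 4)
        prof = ds.sliding_window_median(
            ds.compute_ratios(pair), ds.GeneCatalog(genes), window=2
        )
        spans = set(zip(prof.data["chrom"], prof.data["first_gene"]))
        assert ("Chr1", "g2") not in spans
        assert len(prof) == 2

    def test_short_chromosome_yields_no_windows(self):
        pair = make_pair([(1, 1)] * 3)
        prof = ds.sliding_window_median(
            ds.compute_ratios(pair), make_catalog(3), window=5
        )
        assert len(prof) == 0

    def test_undefined_ratio_genes_do_not_perturb_profile(self):
        base = [(1.0, float(v)) for v in (1, 2, 3, 4, 5)]
        table_a = ds.compute_ratios(make_pair(base))
        prof_a = ds.sliding_window_median(table_a, make_catalog(5), window=3)
        # interleave zero-expression genes: same defined sequence
        with_zeros = base[:2] + [(0.0, 1.0)] + base[2:] + [(1.0, 0.0)]
        table_b = ds.compute_ratios(make_pair(with_zeros))
        prof_b = ds.sliding_window_median(table_b, make_catalog(7), window=3)
        assert list(prof_a.data["median"]) == list(prof_b.data["median"])

    @pytest.mark.parametrize("kwargs", [{"window": 0}, {"step": 0}])
    def test_bad_parameters_rejected(self, kwargs):
        table = ds.compute_ratios(make_pair([(1, 1)] * 5))
        with pytest.raises(ValueError):
            ds.sliding_window_median(table, make_catalog(5), **kwargs)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.01, 50, allow_nan=False), min_size=4, max_size=40),
        st.integers(min_value=1, max_value=6),
    )
    def test_median_bounded_by_window_extremes(self, variants, window):
        pair = make_pair([(1.0, v) for v in variants])
        table = ds.compute_ratios(pair)
        prof = ds.sliding_window_median(table, make_catalog(len(variants)), window=window)
        vals = table.defined.to_numpy()
        for row in prof.data.itertuples():
            seg = vals[row.start_index: row.end_index + 1]
            assert seg.min() <= row.median <= seg.max()


class TestHistogram:
    def test_edge_assignment_right_open(self):
        pair = make_pair([(1.0, 1.0)])
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        k = int(np.argmax(hist.counts))
        assert np.isclose(k * 0.05, 1.00)

    def test_direct_binning_small_values(self):
        pair = make_pair([(1, 0.02), (1, 0.04), (1, 0.06)])
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        assert hist.counts[0] == 2
        assert hist.counts[1] == 1

    def test_overflow_and_mass_conservation(self):
        pair = make_pair([(1, 0.2), (1, 4.99), (1, 5.0), (1, 100.0), (0, 1)])
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        assert hist.overflow == 2
        assert hist.counts.sum() + hist.overflow == hist.n_total == 4

    def test_region_restriction(self):
        pair = make_pair([(1, 1), (1, 2), (1, 3)])
        hist = ds.bin_ratio_distribution(
            ds.compute_ratios(pair), region_genes=["g0", "g2"]
        )
        assert hist.n_total == 2

    def test_cap_must_be_multiple_of_width(self):
        pair = make_pair([(1, 1)])
        with pytest.raises(ValueError):
            ds.bin_ratio_distribution(ds.compute_ratios(pair), cap=5.02)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.001, 20, allow_nan=False), min_size=1, max_size=80))
    def test_mass_conservation_property(self, variants):
        pair = make_pair([(1.0, v) for v in variants])
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        assert hist.counts.sum() + hist.overflow == len(variants)


class TestSummaries:
    def test_reference_counts_reproduced(self, reference_results):
        row = reference_results.summary_table.set_index("region_id").loc["11S-2"]
        assert (row["n_expressed"], row["n_up"], row["n_down"]) == (211, 73, 8)
        assert (row["up_pct"], row["down_pct"]) == (34.60, 3.79)

    def test_total_row_percentages(self, reference_results):
        row = reference_results.summary_table.set_index("region_id").loc["Total"]
        assert (row["n_expressed"], row["n_up"], row["n_down"]) == (23604, 1311, 986)
        assert (row["up_pct"], row["down_pct"]) == (5.55, 4.18)

    def test_empty_region_flagged(self):
        pair = make_pair([(0.0, 0.0), (1.0, 1.0)])
        table = ds.compute_ratios(pair)
        summary = ds.summarize_regions(table, {"g0": "empty", "g1": "full"})
        row = summary.set_index("region_id").loc["empty"]
        assert row["n_expressed"] == 0 and row["up_pct"] == 0.0 and row["empty"]

    def test_rounding_half_up(self):
        # 34.595... rounds up; banker's rounding would disagree on .005 ties
        assert round_half_up_pct(73, 211) == 34.60
        assert round_half_up_pct(1, 16) == 6.25
        assert round_half_up_pct(4005, 100000) == 4.01  # 4.005 -> half-up


class TestCompensation:
    def test_all_ratios_one(self):
        pair = make_pair([(1.0, 1.0)] * 20)
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        call = ds.assess_compensation(hist)
        assert call.has_peak_at_one and not call.has_peak_at_two

    def test_all_ratios_two_single_bin(self):
        pair = make_pair([(2.0, 4.0)] * 15)
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        call = ds.assess_compensation(hist)
        assert call.modal_bin_center == pytest.approx(2.025)
        assert call.has_peak_at_two and not call.has_peak_at_one

    def test_tie_broken_toward_smaller_center(self):
        pair = make_pair([(1.0, 0.97)] * 5 + [(1.0, 2.02)] * 5)
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        call = ds.assess_compensation(hist)
        assert call.modal_bin_center == pytest.approx(0.975)

    def test_empty_histogram_rejected(self):
        pair = make_pair([(0.0, 1.0)])
        hist = ds.bin_ratio_distribution(ds.compute_ratios(pair))
        with pytest.raises(ValueError):
            ds.assess_compensation(hist)


class TestDosageFraction:
    def test_reference_fractions(self, reference_results):
        k, n, frac = reference_results.dosage_fractions["11S-2"]
        assert (k, n) == (73, 211)
        assert round_half_up_pct(k, n) == 34.60
        k, n, _ = reference_results.dosage_fractions["11L"]
        assert (k, n) == (60, 646)
        assert round_half_up_pct(k, n) == 9.29

    def test_zero_up_region(self):
        pair = make_pair([(1.0, 1.0)] * 10)
        table = ds.compute_ratios(pair)
        k, n, frac = ds.dosage_effect_fraction(table, [f"g{i}" for i in range(10)])
        assert (k, n, frac) == (0, 10, 0.0)

    def test_unexpressed_region_rejected(self):
        pair = make_pair([(0.0, 0.0)])
        table = ds.compute_ratios(pair)
        with pytest.raises(ValueError):
            ds.dosage_effect_fraction(table, ["g0"])
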