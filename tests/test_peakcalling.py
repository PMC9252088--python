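"""Binomial null, BH correction, bin testing, merging, end-to-end calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagpeaks import (
    BinomialModel,
    CallParams,
    ChromSizes,
    SimConfig,
    TruthRegion,
    bh_adjust,
    bin_pvalue,
    call_peaks,
    count_fragments,
    estimate_model,
    make_bins,
    merge_significant,
    simulate,
)
from tagpeaks import test_bins as evaluate_bins

from conftest import make_fragment_set


def brute_force_upper_tail(x, n, p):
    """Direct summation of C(n,k) p^k (1-p)^(n-k) for k >= x."""
    return sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1)
    )


class TestEstimateModel:
    def test_printed_estimator_arithmetic(self):
        model = estimate_model(np.array([0, 0, 2, 4, 6]), n=12)
        assert model.n == 12
        assert model.p == pytest.approx((2 + 4 + 6) / 3 / 12)

    def test_constant_counts(self):
        model = estimate_model(np.array([5, 5, 5, 5]), n=50)
        assert model.p == pytest.approx(5 / 50)

    def test_all_zero_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="no signal"):
            estimate_model(np.zeros(10), n=100)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            BinomialModel(n=0, p=0.1)
        with pytest.raises(ValueError):
            BinomialModel(n=10, p=0.0)
        with pytest.raises(ValueError):
            BinomialModel(n=10, p=1.0)


class TestBinPvalue:
    def test_zero_count_covers_whole_distribution(self):
        assert bin_pvalue(0, BinomialModel(10, 0.3)) == 1.0

    def test_all_successes_closed_form(self):
        assert bin_pvalue(10, BinomialModel(10, 0.5)) == pytest.approx(
            0.5**10, rel=1e-12
        )

    def test_matches_brute_force_summation(self):
        model = BinomialModel(20, 0.1)
        for x in range(0, 21):
            assert bin_pvalue(x, model) == pytest.approx(
                brute_force_upper_tail(x, 20, 0.1), rel=1e-10, abs=1e-300
            )

    def test_count_above_n_is_an_error(self):
        with pytest.raises(ValueError):
            bin_pvalue(11, BinomialModel(10, 0.5))


class TestBHAdjust:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_adjusted_values_dominate_raw_and_are_capped(self, pvals):
        adjusted = bh_adjust(pvals)
        # >= up to one ulp of floating-point rounding in p * m / i
        assert np.all(adjusted >= np.asarray(pvals) * (1 - 1e-12))
        assert np.all(adjusted <= 1.0)

    def test_matches_independent_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(50):
            pvals = rng.uniform(size=rng.integers(1, 60))
            _, expected, _, _ = multipletests(pvals, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(pvals), expected, rtol=1e-12)


class TestTestBins:
    def _counts(self, raw, total):
        grid = make_bins(ChromSizes({"c": len(raw) * 100}), 100, 100)
        frags = []
        for i, c in enumerate(raw):
            frags.extend([("c", i * 100 + 10, i * 100 + 20)] * c)
        # pad depth with fragments outside the grid? keep depth = len(frags)
        return count_fragments(grid, make_fragment_set(frags))

    def test_minreads_threshold_is_strict(self):
        counts = self._counts([15, 16, 3], total=34)
        frame = evaluate_bins(counts, CallParams(minreads=15))
        assert frame["count"].tolist() == [16]
        assert frame["start"].tolist() == [100]

    def test_significance_uses_adjusted_p(self):
        counts = self._counts([40, 16, 2], total=58)
        frame = evaluate_bins(counts, CallParams(minreads=15, pthresh=0.05))
        assert set(frame["count"]) == {40, 16}
        assert frame["significant"].dtype == bool
        assert np.all(frame["qvalue"] >= frame["pvalue"])

    def test_no_testable_bins_yields_empty_family(self):
        counts = self._counts([3, 2, 5], total=10)
        frame = evaluate_bins(counts, CallParams(minreads=15))
        assert frame.shape[0] == 0


def brute_force_merge(intervals, mdist):
    """Connected-components oracle: edge iff gap <= mdist (overlap included)."""
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(range(len(intervals)))
    for i, (s1, e1) in enumerate(intervals):
        for j, (s2, e2) in enumerate(intervals):
            if i >= j:
                continue
            gap = max(s1, s2) - min(e1, e2)
            if gap <= mdist:
                graph.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(graph):
        starts = [intervals[i][0] for i in comp]
        ends = [intervals[i][1] for i in comp]
        merged.append((min(starts), max(ends)))
    return sorted(merged)


def _bins_frame(intervals, chrom="c"):
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(intervals),
            "start": [s for s, _ in intervals],
            "end": [e for _, e in intervals],
            "count": [20] * len(intervals),
            "qvalue": [0.01] * len(intervals),
        }
    )


class TestMergeSignificant:
    def test_gap_within_mdist_merges(self):
        peaks = merge_significant(
            _bins_frame([(0, 100), (150, 250)]), mdist=150, minwidth=150
        )
        assert [(p.start, p.end) for p in peaks] == [(0, 250)]
        assert peaks.peaks[0].n_bins == 2

    def test_gap_beyond_mdist_then_minwidth_drops_both(self):
        peaks = merge_significant(
            _bins_frame([(0, 100), (300, 400)]), mdist=150, minwidth=150
        )
        assert len(peaks) == 0

    def test_single_wide_bin_passes_through(self):
        peaks = merge_significant(
            _bins_frame([(0, 200)]), mdist=150, minwidth=150
        )
        assert [(p.start, p.end) for p in peaks] == [(0, 200)]

    def test_different_chromosomes_never_merge(self):
        frame = pd.concat(
            [_bins_frame([(0, 100)], "c1"), _bins_frame([(100, 200)], "c2")]
        )
        peaks = merge_significant(frame, mdist=10_000, minwidth=1)
        assert {(p.chrom, p.start, p.end) for p in peaks} == {
            ("c1", 0, 100),
            ("c2", 100, 200),
        }

    def test_peak_statistics_aggregate_over_merged_bins(self):
        frame = _bins_frame([(0, 100), (50, 150)])
        frame["qvalue"] = [0.04, 0.002]
        frame["count"] = [18, 33]
        peak = merge_significant(frame, mdist=150, minwidth=150).peaks[0]
        assert peak.min_qvalue == 0.002
        assert peak.max_count == 33
        assert peak.n_bins == 2

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 2000), st.integers(1, 300)),
            min_size=1,
            max_size=25,
        ),
        mdist=st.integers(0, 400),
    )
    def test_matches_connected_components_oracle(self, intervals, mdist):
        ivs = [(s, s + l) for s, l in intervals]
        peaks = merge_significant(
            _bins_frame(ivs), mdist=mdist, minwidth=1
        )
        assert [(p.start, p.end) for p in peaks] == brute_force_merge(ivs, mdist)


class TestCallPeaks:
    def test_single_enriched_region_yields_one_overlapping_peak(self):
        """One 1-kb region at 20x background, depth 5e4, seed 7."""
        config = SimConfig(
            chrom_sizes=ChromSizes({"chr1": 5_000_000}),
            background_rate=2.0,
            regions=[TruthRegion("chr1", 2_000_000, 2_001_000, "narrow", 20.0)],
            depth=50_000,
            seed=7,
        )
        out = simulate(config)
        peaks = call_peaks(out.sample, None, config.chrom_sizes, CallParams())
        assert len(peaks) == 1
        peak = peaks.peaks[0]
        assert peak.start < 2_001_000 and peak.end > 2_000_000

    def test_uniform_background_yields_no_peaks(self):
        config = SimConfig(
            chrom_sizes=ChromSizes({"chr1": 1_000_000}),
            background_rate=2.0,
            regions=[],
            depth=2_000,
            seed=3,
        )
        out = simulate(config)
        peaks = call_peaks(out.sample, None, config.chrom_sizes, CallParams())
        assert len(peaks) == 0

    def test_sample_as_its_own_control_yields_no_peaks(self):
        config = SimConfig(
            chrom_sizes=ChromSizes({"chr1": 1_000_000}),
            background_rate=2.0,
            regions=[TruthRegion("chr1", 500_000, 501_000, "narrow", 30.0)],
            depth=20_000,
            seed=5,
        )
        out = simulate(config)
        peaks = call_peaks(
            out.sample, out.sample, config.chrom_sizes, CallParams()
        )
        assert len(peaks) == 0

    def test_byte_identical_bed_output_across_runs(self, tmp_path):
        config = SimConfig(
            chrom_sizes=ChromSizes({"chr1": 2_000_000}),
            background_rate=2.0,
            regions=[TruthRegion("chr1", 1_000_000, 1_001_000, "narrow", 20.0)],
            depth=30_000,
            seed=11,
        )
        beds = []
        for run in range(2):
            out = simulate(config)
            peaks = call_peaks(
                out.sample, None, config.chrom_sizes, CallParams()
            )
            path = tmp_path / f"run{run}.bed"
            peaks.write_bed(path)
            beds.append(path.read_bytes())
        assert beds[0] == beds[1] and len(beds[0]) > 0

    def test_adding_fragments_inside_a_peak_never_removes_it(self):
        config = SimConfig(
            chrom_sizes=ChromSizes({"chr1": 2_000_000}),
            background_rate=2.0,
            regions=[TruthRegion("chr1", 1_000_000, 1_001_000, "narrow", 20.0)],
            depth=30_000,
            seed=13,
        )
        out = simulate(config)
        peaks = call_peaks(out.sample, None, config.chrom_sizes, CallParams())
        assert len(peaks) >= 1
        target = peaks.peaks[0]
        boosted = make_fragment_set(
            [(f.chrom, f.start, f.end) for f in out.sample]
            + [("chr1", target.start + 10, target.start + 210)] * 25
        )
        again = call_peaks(boosted, None, config.chrom_sizes, CallParams())
        assert any(
            p.chrom == target.chrom
            and p.start < target.end
            and p.end > target.start
            for p in again
        )

    def test_broad_mode_preserves_a_broad_domain(self):
        from tagpeaks import broad_domain_scenario, truth_overlap_metrics

        config = broad_domain_scenario(seed=21)
        out = simulate(config)
        peaks = call_peaks(
            out.sample, None, config.chrom_sizes,
            CallParams(broad=True, mdist=3000),
        )
        assert len(peaks) == 1
        recall, _ = truth_overlap_metrics(peaks, out.truth, min_frac=0.95)
        assert recall == 1.0

    def test_broad_flag_rewrites_step_and_slide_only(self):
        params = CallParams(broad=True, mdist=3000).resolve()
        assert (params.step, params.slide) == (5000, 1000)
        assert params.mdist == 3000

    def test_default_parameters_match_published_values(self):
        params = CallParams()
        assert (
            params.step, params.slide, params.minreads, params.pthresh,
            params.mdist, params.minwidth,
        ) == (100, 50, 15, 0.05, 150, 150)
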