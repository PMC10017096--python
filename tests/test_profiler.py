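"""Windowed profiling, thresholding, counting and binning semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnascan import (
    EntropyTrack,
    SecondaryStructure,
    ThresholdSpec,
    bin_structure_content,
    compute_bpc,
    half_structured_spec,
    make_entropy,
    make_structure,
    resolve_thresholds,
    run_scan,
    smooth_entropy,
    structure_counts,
)
from rnascan.profiler import StructureCountMask, rank_bins
from rnascan.fixtures import random_structure

from .oracles import naive_bin_counts, naive_bpc, naive_median_smooth


def structure_from(pairing):
    return SecondaryStructure(sequence="N" * len(pairing), pairing=np.array(pairing))


class TestComputeBPC:
    def test_fully_paired_duplex_is_100_everywhere(self):
        s = structure_from([4, 3, 2, 1])
        for w in (1, 3, 7):
            assert compute_bpc(s, w).tolist() == [100.0] * 4

    def test_hairpin_window3_truncation(self, hairpin):
        bpc = compute_bpc(hairpin, 3)
        assert bpc[0] == 100.0            # truncated window {1,2}, both paired
        assert bpc[1] == 100.0
        assert bpc[4] == pytest.approx(100 / 3)  # window {4,5,6}, one paired

    def test_window1_is_binary(self, hairpin):
        bpc = compute_bpc(hairpin, 1)
        assert set(bpc.tolist()) <= {0.0, 100.0}
        assert np.array_equal(bpc > 0, hairpin.paired)

    @pytest.mark.parametrize("window", [0, 2, 4, -1])
    def test_even_or_nonpositive_window_rejected(self, hairpin, window):
        with pytest.raises(ValueError, match="odd positive"):
            compute_bpc(hairpin, window)

    def test_oversized_window_rejected(self, hairpin):
        with pytest.raises(ValueError, match="2N-1"):
            compute_bpc(hairpin, 25)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 500),
           window=st.sampled_from([1, 3, 11, 51]))
    def test_matches_naive_oracle_exactly(self, seed, n, window):
        if window > 2 * n - 1:
            window = 1
        rng = np.random.default_rng(seed)
        s = random_structure(n, rng)
        assert np.array_equal(compute_bpc(s, window), naive_bpc(s.pairing, window))


class TestSmoothEntropy:
    def test_middle_of_three(self):
        t = EntropyTrack(values=np.array([0.1, 0.5, 0.9]))
        assert smooth_entropy(t, 3)[1] == 0.5

    def test_window1_is_identity(self):
        values = np.array([0.3, np.nan, 1.2, 0.0])
        out = smooth_entropy(EntropyTrack(values=values), 1)
        assert np.array_equal(out, values, equal_nan=True)

    def test_missing_excluded_from_median(self):
        t = EntropyTrack(values=np.array([0.1, np.nan, 0.9]))
        assert smooth_entropy(t, 3)[1] == pytest.approx(0.5)

    def test_all_missing_window_stays_missing(self):
        t = EntropyTrack(values=np.array([np.nan, np.nan, 0.7]))
        out = smooth_entropy(t, 1)
        assert np.isnan(out[0]) and out[2] == 0.7

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 300),
           window=st.sampled_from([1, 3, 11, 51]))
    def test_matches_naive_oracle(self, seed, n, window):
        if window > 2 * n - 1:
            window = 1
        rng = np.random.default_rng(seed)
        values = rng.random(n) * 2
        values[rng.random(n) < 0.2] = np.nan
        out = smooth_entropy(EntropyTrack(values=values), window)
        expected = naive_median_smooth(values, window)
        assert np.array_equal(out, expected, equal_nan=True)


class TestResolveThresholds:
    def test_odd_count_median(self):
        spec = resolve_thresholds(np.array([1., 2, 3, 4, 5]),
                                  np.array([1., 2, 3, 4, 5]), 50, 50)
        assert spec.bpc_cutoff == 3.0

    def test_boundary_percentiles(self):
        v = np.array([1., 2, 3, 4, 5])
        assert resolve_thresholds(v, v, 0, 0).bpc_cutoff == 1.0
        assert resolve_thresholds(v, v, 100, 100).se_cutoff == 5.0

    def test_even_count_linear_interpolation(self):
        v = np.array([1., 2, 3, 4])
        assert resolve_thresholds(v, v, 50, 50).bpc_cutoff == 2.5

    def test_missing_se_excluded_from_pool(self):
        se = np.array([0.2, np.nan, 0.8])
        spec = resolve_thresholds(np.array([1., 2, 3]), se, 50, 50)
        assert spec.se_cutoff == pytest.approx(0.5)

    def test_all_missing_se_errors(self):
        with pytest.raises(ValueError, match="missing"):
            resolve_thresholds(np.array([1.0]), np.array([np.nan]), 50, 50)

    @pytest.mark.parametrize("p", [-1, 101])
    def test_percentile_out_of_range(self, p):
        v = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            resolve_thresholds(v, v, p, 50)


class TestStructureCounts:
    def test_strict_dual_predicate(self):
        spec = ThresholdSpec(50, 50, 50.0, 0.5)
        mask = structure_counts(np.array([100., 100, 0]),
                                np.array([0.1, 0.9, 0.5]), spec)
        assert mask.mask.tolist() == [True, False, False]

    def test_cutoff_at_max_bpc_yields_nothing(self):
        bpc = np.array([10., 40, 40])
        spec = ThresholdSpec(100, 50, 40.0, 1.0)
        mask = structure_counts(bpc, np.array([0., 0, 0]), spec)
        assert mask.total == 0

    def test_missing_se_never_counts(self):
        spec = ThresholdSpec(50, 50, 0.0, 1.0)
        mask = structure_counts(np.array([100.0]), np.array([np.nan]), spec)
        assert mask.total == 0

    def test_length_mismatch(self):
        spec = ThresholdSpec(50, 50, 0.0, 1.0)
        with pytest.raises(ValueError, match="length"):
            structure_counts(np.array([1.0, 2.0]), np.array([0.1]), spec)


class TestBinStructureContent:
    def test_hand_counted_example(self):
        mask = np.zeros(10, dtype=bool)
        mask[[0, 1, 2, 5]] = True
        table = bin_structure_content(StructureCountMask(mask=mask), 5)
        assert table["n_counts"].tolist() == [3, 1]
        assert table["pct_structure_content"].tolist() == [60.0, 20.0]

    def test_all_true_every_bin_100(self):
        mask = np.ones(20, dtype=bool)
        table = bin_structure_content(StructureCountMask(mask=mask), 7)
        assert (table["pct_structure_content"] == 100.0).all()

    def test_truncated_final_bin_denominator(self):
        mask = np.zeros(12, dtype=bool)
        mask[10] = True  # position 11 in the 2-nt final bin
        table = bin_structure_content(StructureCountMask(mask=mask), 5)
        assert table["bin_start"].tolist() == [1, 6, 11]
        assert table["bin_end"].tolist() == [5, 10, 12]
        assert table["pct_structure_content"].iloc[-1] == 50.0

    def test_bins_tile_without_gaps(self):
        mask = StructureCountMask(mask=np.zeros(103, dtype=bool))
        table = bin_structure_content(mask, 10)
        assert (table["bin_start"].iloc[1:].to_numpy()
                == table["bin_end"].iloc[:-1].to_numpy() + 1).all()
        assert table["bin_start"].iloc[0] == 1
        assert table["bin_end"].iloc[-1] == 103

    @pytest.mark.parametrize("bin_size", [1, 7, 30, 100])
    def test_conservation_and_oracle(self, bin_size):
        rng = np.random.default_rng(11)
        mask = rng.random(257) < 0.3
        table = bin_structure_content(StructureCountMask(mask=mask), bin_size)
        assert table["n_counts"].sum() == mask.sum()
        expected = naive_bin_counts(mask, bin_size)
        assert list(map(tuple, table.itertuples(index=False))) == expected

    def test_bad_bin_size(self):
        mask = StructureCountMask(mask=np.zeros(5, dtype=bool))
        with pytest.raises(ValueError, match="bin_size"):
            bin_structure_content(mask, 0)

    def test_ranked_descending_with_start_tiebreak(self):
        table = pd.DataFrame({
            "bin_start": [1, 6, 11], "bin_end": [5, 10, 15],
            "n_counts": [1, 3, 1],
            "pct_structure_content": [20.0, 60.0, 20.0],
        })
        ranked = rank_bins(table)
        assert ranked["bin_start"].tolist() == [6, 1, 11]


class TestRunScan:
    def test_constant_entropy_yields_zero_counts(self):
        s = structure_from([4, 3, 2, 1])
        e = EntropyTrack(values=np.full(4, 0.3))
        res = run_scan(s, e, window=3, bin_size=2)
        # nothing is strictly below a constant's median
        assert res.counts.total == 0
        assert (res.bins["pct_structure_content"] == 0).all()

    def test_half_structured_fixture_recovery(self, half_structured):
        structure, entropy, _ = half_structured
        res = run_scan(structure, entropy, window=11, bin_size=30)
        pct = res.bins["pct_structure_content"].to_numpy()
        assert pct[2] == 0.0 and pct[3] == 0.0
        assert min(pct[0], pct[1]) > max(pct[2], pct[3])
        # step-by-step independent recomputation
        bpc = naive_bpc(structure.pairing, 11)
        se = naive_median_smooth(entropy.values, 11)
        cut_b, cut_s = np.percentile(bpc, 50), np.percentile(se, 50)
        mask = (bpc > cut_b) & (se < cut_s)
        assert np.array_equal(res.counts.mask, mask)

    def test_bpc_percentile_monotonicity(self, half_structured):
        structure, entropy, _ = half_structured
        totals = [
            run_scan(structure, entropy, window=11, bin_size=30,
                     bpc_percentile=p).counts.total
            for p in (25, 50, 75)
        ]
        assert totals == sorted(totals, reverse=True)

    def test_deterministic_bitwise(self, half_structured):
        structure, entropy, _ = half_structured
        a = run_scan(structure, entropy, window=11, bin_size=30)
        b = run_scan(structure, entropy, window=11, bin_size=30)
        assert np.array_equal(a.profile.bpc, b.profile.bpc)
        assert np.array_equal(a.profile.se_smooth, b.profile.se_smooth,
                              equal_nan=True)
        pd.testing.assert_frame_equal(a.bins, b.bins)

    def test_length_mismatch_rejected(self, hairpin):
        e = EntropyTrack(values=np.zeros(5))
        with pytest.raises(ValueError, match="length"):
            run_scan(hairpin, e)

    def test_stage_labels_in_errors(self, hairpin):
        e = EntropyTrack(values=np.full(12, np.nan))
        with pytest.raises(ValueError, match="threshold stage"):
            run_scan(hairpin, e, window=3, bin_size=4)

    def test_summary_reports_cutoffs(self, half_structured):
        structure, entropy, _ = half_structured
        res = run_scan(structure, entropy, window=11, bin_size=30)
        text = res.summary()
        assert f"{res.thresholds.bpc_cutoff:.4f}" in text
        assert str(res.counts.total) in text
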