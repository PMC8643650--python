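"""Circular binary segmentation: statistic, maximization, recursion, rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porecn import (
    CBSParams,
    CBSSegmenter,
    best_split,
    cbs_statistic,
    exhaustive_best_split,
    segment,
)


class TestCbsStatistic:
    def test_constant_profile_scores_zero(self):
        x = np.ones(20)
        for i, j in [(0, 5), (3, 12), (0, 19)]:
            assert cbs_statistic(x, i, j) == 0.0

    def test_hand_computed_pooled_t(self):
        # arc [1,1] vs complement [2,2,2,4]: diff=1.5, ss=0+3, s_p^2=3/4,
        # denom = sqrt(0.75*(1/2+1/4)) = 0.75 -> t = 2.0
        x = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 4.0])
        assert cbs_statistic(x, 0, 2) == pytest.approx(2.0)

    def test_zero_within_variance_step_is_infinite(self):
        x = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        assert np.isinf(cbs_statistic(x, 0, 3))

    def test_symmetric_under_arc_complement_swap(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        # arc (5, 20] vs its complement == arc (0,5]+(20,30] seen from the
        # other side: same statistic by construction
        a = cbs_statistic(x, 5, 20)
        swapped = np.concatenate([x[5:20], x[20:], x[:5]])
        b = cbs_statistic(swapped, 0, 15)
        assert a == pytest.approx(b)

    def test_invalid_indices_rejected(self):
        x = np.ones(10)
        with pytest.raises(ValueError):
            cbs_statistic(x, 5, 5)
        with pytest.raises(ValueError):
            cbs_statistic(x, 0, 11)

    def test_both_sides_singleton_rejected(self):
        with pytest.raises(ValueError):
            cbs_statistic(np.array([1.0, 2.0]), 0, 1)


class TestBestSplitOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_fast_scan_matches_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        cut = int(rng.integers(8, n - 8))
        x = rng.normal(1.0, 0.1, n)
        x[cut:] += rng.uniform(0.3, 1.0)
        fast = best_split(x, min_width=5)
        ex = exhaustive_best_split(x, min_width=5)
        assert (fast.i, fast.j) == (ex.i, ex.j)
        assert fast.statistic == pytest.approx(ex.statistic)

    def test_fast_scan_matches_exhaustive_without_min_width(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=40)
        fast, ex = best_split(x, 1), exhaustive_best_split(x, 1)
        assert (fast.i, fast.j) == (ex.i, ex.j)
        assert fast.statistic == pytest.approx(ex.statistic)

    def test_clean_step_maximizer_is_true_boundary(self):
        x = np.concatenate([np.ones(10), np.full(10, 2.0)])
        bs = best_split(x, min_width=1)
        assert {bs.i, bs.j} <= {0, 10, 20}
        assert (bs.j - bs.i) % 10 == 0

    def test_constant_input_flagged_as_tie(self):
        bs = best_split(np.ones(30), min_width=5)
        assert bs.statistic == 0.0 and bs.tie
        ex = exhaustive_best_split(np.ones(30), min_width=5)
        assert ex.statistic == 0.0 and ex.tie

    def test_alternating_pattern_matches_enumeration(self):
        x = np.tile([0.0, 1.0], 10)
        fast, ex = best_split(x, 1), exhaustive_best_split(x, 1)
        assert (fast.i, fast.j, round(fast.statistic, 10)) == (
            ex.i, ex.j, round(ex.statistic, 10))


class TestSegment:
    def test_flat_noise_usually_one_segment(self):
        """Type-I control: flat truth, sd 0.05, n=500, alpha=0.01."""
        single = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            x = 1.0 + rng.normal(0, 0.05, 500)
            segs = segment(x, CBSParams(seed=seed))
            single += len(segs) == 1
        assert single >= 0.95 * reps

    def test_step_recovered_at_true_boundary(self, noisy_step):
        segs = segment(noisy_step, CBSParams(seed=0))
        assert len(segs) == 2
        assert abs(segs.iloc[1]["start_bin"] - 50) <= 1
        assert segs.iloc[0]["mean_ratio"] == pytest.approx(1.0, abs=0.05)
        assert segs.iloc[1]["mean_ratio"] == pytest.approx(2.0, abs=0.05)

    def test_three_bin_spike_not_called_with_five_bin_rule(self):
        rng = np.random.default_rng(11)
        x = 1.0 + rng.normal(0, 0.02, 100)
        x[40:43] += 1.0
        segs = segment(x, CBSParams(min_width=5, seed=1))
        assert len(segs) == 1

    def test_partition_and_min_width_invariants(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([
            rng.normal(1.0, 0.05, 60), rng.normal(1.5, 0.05, 40),
            rng.normal(0.5, 0.05, 55), rng.normal(1.0, 0.05, 45),
        ])
        segs = segment(x, CBSParams(seed=3))
        assert segs.iloc[0]["start_bin"] == 0
        assert segs.iloc[-1]["end_bin"] == len(x)
        assert (segs["end_bin"].to_numpy()[:-1] == segs["start_bin"].to_numpy()[1:]).all()
        assert (segs["n_bins"] >= 5).all()
        for _, row in segs.iterrows():
            assert row["mean_ratio"] == pytest.approx(
                x[int(row["start_bin"]) : int(row["end_bin"])].mean()
            )

    def test_deterministic_under_seed(self, noisy_step):
        a = segment(noisy_step, CBSParams(seed=5))
        b = segment(noisy_step, CBSParams(seed=5))
        assert a.equals(b)

    def test_shift_invariance_of_boundaries(self, noisy_step):
        a = segment(noisy_step, CBSParams(seed=7))
        b = segment(noisy_step + 100.0, CBSParams(seed=7))
        assert list(a["start_bin"]) == list(b["start_bin"])

    def test_scale_equivariance_of_boundaries(self, noisy_step):
        a = segment(noisy_step, CBSParams(seed=7))
        b = segment(noisy_step * 3.0, CBSParams(seed=7))
        assert list(a["start_bin"]) == list(b["start_bin"])

    def test_segment_means_are_sufficient(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([
            rng.normal(1.0, 0.05, 50), rng.normal(2.0, 0.05, 50),
            rng.normal(0.5, 0.05, 50),
        ])
        est = CBSSegmenter(random_state=0).fit(x)
        refit = segment(est.means_, CBSParams(seed=0))
        assert list(refit["start_bin"]) == list(est.segments_["start_bin"])

    def test_chromosome_labels_are_hard_breaks(self):
        rng = np.random.default_rng(6)
        x = 1.0 + rng.normal(0, 0.05, 100)
        chrom = np.repeat(["chr1", "chr2"], 50)
        segs = segment(x, CBSParams(seed=0), chrom=chrom)
        assert list(segs["start_bin"]) == [0, 50]
        assert list(segs["chrom"]) == ["chr1", "chr2"]

    def test_too_short_profile_single_segment_with_warning(self):
        with pytest.warns(UserWarning):
            segs = segment(np.ones(6), CBSParams(min_width=5))
        assert len(segs) == 1

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_partition_property_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 90))
        x = rng.normal(1.0, rng.uniform(0.01, 0.5), n)
        if rng.random() < 0.5:
            cut = int(rng.integers(5, n - 5))
            x[cut:] += rng.uniform(0.0, 2.0)
        segs = segment(x, CBSParams(n_perm=100, seed=seed))
        assert segs.iloc[0]["start_bin"] == 0
        assert segs.iloc[-1]["end_bin"] == n
        assert (segs["n_bins"] >= 5).all()
        assert (segs["end_bin"].to_numpy()[:-1] == segs["start_bin"].to_numpy()[1:]).all()


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        est = CBSSegmenter(alpha=0.05, min_width=7)
        params = est.get_params()
        assert params["alpha"] == 0.05 and params["min_width"] == 7
        est.set_params(alpha=0.01)
        assert est.alpha == 0.01

    def test_transform_returns_piecewise_means(self, noisy_step):
        est = CBSSegmenter(random_state=1).fit(noisy_step)
        means = est.transform()
        assert len(means) == len(noisy_step)
        assert len(np.unique(means)) == est.n_segments_

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CBSSegmenter(alpha=0.0).fit(np.ones(20))
        with pytest.raises(ValueError):
            CBSSegmenter(n_perm=10).fit(np.ones(20))
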