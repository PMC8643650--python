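"""Run-kinetics statistics: yield curves, lifetimes, vacancy, MAPQ analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from porecn import (
    channel_activity,
    channel_lifetimes,
    cumulative_reads,
    length_stratified_mapq_fractions,
    mapq_from_error_prob,
    relative_reads_per_channel,
    residence_time,
    vacancy_times,
)
from porecn.kinetics import read_sequencing_summary
from porecn.sim import write_sequencing_summary


def _summary(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "channel", "mux", "start_time", "duration"]
    )


class TestCumulativeReads:
    def test_empty_summary_all_zero(self):
        out = cumulative_reads(_summary([]), np.array([0.0, 10.0, 100.0]))
        assert (out == 0).all()

    def test_counts_reads_by_end_time(self):
        s = _summary([("a", 1, 1, 5.0, 5.0), ("b", 1, 1, 15.0, 5.0),
                      ("c", 2, 1, 25.0, 5.0)])
        assert list(cumulative_reads(s, np.array([15.0, 25.0, 35.0]))) == [1, 2, 3]

    def test_matches_bruteforce_scan(self, small_run):
        grid = np.linspace(0, 1800, 37)
        fast = cumulative_reads(small_run, grid)
        ends = (small_run["start_time"] + small_run["duration"]).to_numpy()
        brute = np.array([(ends <= t).sum() for t in grid])
        assert np.array_equal(fast, brute)
        assert (np.diff(fast) >= 0).all()
        assert fast[-1] == len(small_run)

    def test_unsorted_grid_rejected(self, small_run):
        with pytest.raises(ValueError):
            cumulative_reads(small_run, np.array([10.0, 5.0]))


class TestChannelLifetimes:
    def test_single_read(self):
        s = _summary([("a", 1, 1, 5.0, 2.0)])
        assert channel_lifetimes(s) == {1: 7.0}

    def test_max_rule_over_reads(self):
        s = _summary([("a", 3, 1, 90.0, 10.0), ("b", 3, 1, 30.0, 10.0)])
        assert channel_lifetimes(s) == {3: 100.0}

    def test_matches_bruteforce_max(self, small_run):
        fast = channel_lifetimes(small_run)
        for ch in small_run["channel"].unique():
            grp = small_run[small_run["channel"] == ch]
            assert fast[ch] == pytest.approx(
                (grp["start_time"] + grp["duration"]).max()
            )

    def test_readless_channels_absent(self):
        assert channel_lifetimes(_summary([])) == {}


class TestVacancyTimes:
    def test_one_read_per_pore_no_gaps(self):
        s = _summary([("a", 1, 1, 0.0, 1.0), ("b", 2, 1, 0.0, 1.0)])
        assert len(vacancy_times(s)) == 0

    def test_gap_is_start_minus_previous_end(self):
        s = _summary([("a", 1, 1, 0.0, 1.0), ("b", 1, 1, 4.0, 1.0)])
        assert list(vacancy_times(s)) == [3.0]

    def test_different_pore_same_channel_excluded(self):
        s = _summary([("a", 1, 1, 0.0, 1.0), ("b", 1, 2, 4.0, 1.0)])
        assert len(vacancy_times(s)) == 0

    def test_overlap_within_pore_rejected(self):
        s = _summary([("a", 1, 1, 0.0, 5.0), ("b", 1, 1, 2.0, 1.0)])
        with pytest.raises(ValueError, match="overlap"):
            vacancy_times(s)

    def test_deterministic_run_gaps_and_residence_exact(self, deterministic_run):
        params, run = deterministic_run
        gaps = vacancy_times(run)
        assert np.allclose(gaps, params.mean_vacancy)
        assert np.allclose(run["duration"], params.median_bp / params.speed)

    def test_gaps_nonnegative_on_simulated_run(self, small_run):
        assert (vacancy_times(small_run) >= 0).all()


class TestResidenceTime:
    def test_long_molecule_rounds_to_22s(self):
        assert round(residence_time(10000, 450)) == 22

    def test_short_molecule_rounds_to_1s(self):
        assert residence_time(400, 450) == pytest.approx(0.889, abs=1e-3)
        assert round(residence_time(400, 450)) == 1

    def test_zero_length(self):
        assert residence_time(0, 450) == 0.0

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            residence_time(100, 0)


class TestChannelActivity:
    def test_read_spanning_boundary_marks_both_windows(self):
        s = _summary([("a", 1, 1, 250.0, 100.0)])
        act = channel_activity(s, window=300.0)
        assert act.loc[1, 0.0] and act.loc[1, 300.0]

    def test_readless_channel_row_all_false(self):
        s = _summary([("a", 2, 1, 10.0, 5.0)])
        act = channel_activity(s, window=300.0, n_channels=3)
        assert not act.loc[1].any() and not act.loc[3].any()

    def test_every_producing_channel_has_activity(self, small_run):
        act = channel_activity(small_run)
        assert (act.sum(axis=1) >= 1).all()


class TestRelativeReadsPerChannel:
    @pytest.mark.parametrize(
        "reads,channels,expected",
        [(0, 512, 0.0), (1024, 512, 2.0), (6332668, 512, 6332668 / 512)],
    )
    def test_values(self, reads, channels, expected):
        assert relative_reads_per_channel(reads, channels) == expected

    def test_minion_scale_run(self):
        # a ~6.3M-read short-library run on a 512-channel device
        assert round(relative_reads_per_channel(6332668, 512), 1) == 12368.5

    def test_zero_channels_rejected(self):
        with pytest.raises(ValueError):
            relative_reads_per_channel(100, 0)


class TestMapq:
    @pytest.mark.parametrize("p,expected", [(1e-6, 60), (0.1, 10), (1.0, 0)])
    def test_values(self, p, expected):
        assert mapq_from_error_prob(p) == expected

    def test_caps_at_60(self):
        assert mapq_from_error_prob(1e-12) == 60

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(ValueError):
            mapq_from_error_prob(p)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False))
    def test_monotone_nonincreasing_and_saturating(self, p):
        q = mapq_from_error_prob(p)
        assert 0 <= q <= 60
        assert mapq_from_error_prob(min(1.0, p * 10)) <= q


class TestLengthStratifiedFractions:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["read_length", "mapq", "is_unmapped"])

    def test_all_perfect_mapq(self):
        rec = self._records([(150, 60, False)] * 5 + [(450, 60, False)] * 3)
        out = length_stratified_mapq_fractions(rec)
        assert (out["perfect"] == 1.0).all()

    def test_mixed_stratum_fractions(self):
        rec = self._records(
            [(150, 0, True)] * 10 + [(150, 60, False)] * 30 + [(150, 30, False)] * 10
        )
        out = length_stratified_mapq_fractions(rec)
        row = out.iloc[0]
        assert (row["unaligned"], row["perfect"], row["suboptimal"]) == pytest.approx(
            (0.2, 0.6, 0.2)
        )

    def test_fractions_sum_to_one_per_stratum(self):
        rng = np.random.default_rng(0)
        rec = self._records(
            list(zip(rng.integers(100, 1000, 200),
                     rng.integers(0, 61, 200),
                     rng.random(200) < 0.2))
        )
        out = length_stratified_mapq_fractions(rec)
        assert np.allclose(out[["unaligned", "perfect", "suboptimal"]].sum(axis=1), 1.0)


class TestSummaryRoundTrip:
    def test_ont_dialect_roundtrip(self, tmp_path, small_run):
        path = tmp_path / "sequencing_summary.txt"
        write_sequencing_summary(small_run, path)
        back = read_sequencing_summary(path)
        assert len(back) == len(small_run)
        assert np.allclose(back["start_time"], small_run["start_time"])
        assert np.allclose(back["length"], small_run["length"])
        assert (back["passed"] == small_run["passed"]).all()

    def test_tolerates_extra_and_case_varied_columns(self, tmp_path):
        path = tmp_path / "summary.tsv"
        pd.DataFrame({
            "Read_ID": ["a"], "Channel": [1], "Mux": [1],
            "Start_Time": [0.0], "Duration": [1.0],
            "Sequence_Length_Template": [450], "extra_col": ["x"],
        }).to_csv(path, sep="\t", index=False)
        back = read_sequencing_summary(path)
        assert back.loc[0, "length"] == 450
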