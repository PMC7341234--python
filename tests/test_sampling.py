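import math

import numpy as np
import pandas as pd
import pytest

from flockai import (
    ActivitySample,
    CumulativeWindow,
    FrameSequence,
    SegmentationModel,
    ai_series,
    cumulative_windows,
    ratio_to_baseline,
    subsample,
    summarize_groups,
)
from flockai.sampling import IntervalSpec, windows_to_frame


def make_samples(times, ais, interval=0.04, roi_label="open"):
    return [
        ActivitySample(
            ai=a,
            t=t,
            interval=interval,
            changed_pixels=0 if np.isnan(a) else int(round(a * 100)),
            bird_pixels=0 if np.isnan(a) else 100,
            roi_label=roi_label,
        )
        for t, a in zip(times, ais)
    ]


class TestSubsample:
    def test_one_in_five_frames_at_0_2s(self, rng):
        seq = FrameSequence(frames=rng.integers(0, 256, (100, 4, 4), dtype=np.uint8), frame_rate=25.0)
        sub = subsample(seq, 0.2)
        assert len(sub) == 20  # 80% of frames dropped
        np.testing.assert_array_equal(sub.frames, seq.frames[::5])
        np.testing.assert_array_equal(sub.timestamps, seq.timestamps[::5])

    def test_full_frame_interval_is_identity(self, rng):
        seq = FrameSequence(frames=rng.integers(0, 256, (10, 4, 4), dtype=np.uint8), frame_rate=25.0)
        sub = subsample(seq, 0.04)
        np.testing.assert_array_equal(sub.frames, seq.frames)

    def test_non_integer_stride_errors(self, rng):
        seq = FrameSequence(frames=rng.integers(0, 256, (10, 4, 4), dtype=np.uint8), frame_rate=25.0)
        with pytest.raises(ValueError, match="0.3.*25"):
            subsample(seq, 0.3)

    def test_subsampling_composes(self, rng):
        seq = FrameSequence(frames=rng.integers(0, 256, (200, 4, 4), dtype=np.uint8), frame_rate=25.0)
        via_two = subsample(subsample(seq, 0.2), 1.0)
        direct = subsample(seq, 1.0)
        np.testing.assert_array_equal(via_two.frames, direct.frames)
        np.testing.assert_array_equal(via_two.timestamps, direct.timestamps)

    def test_ai_on_subsample_equals_ai_at_retained_pairs(self, rng):
        frames = rng.integers(0, 256, (21, 8, 8), dtype=np.uint8)
        seq = FrameSequence(frames=frames, frame_rate=25.0)
        model = SegmentationModel(background=rng.integers(0, 256, (8, 8)), seg_threshold=30)
        sub_samples = ai_series(subsample(seq, 0.2), model, tau=30)
        manual = FrameSequence(frames=frames[::5], frame_rate=5.0, timestamps=seq.timestamps[::5])
        manual_samples = ai_series(manual, model, tau=30)
        assert [s.ai for s in sub_samples] == [s.ai for s in manual_samples]

    def test_study_intervals_are_integer_strides_at_25fps(self):
        for interval, stride in zip((0.04, 0.2, 1, 10, 60, 300), (1, 5, 25, 250, 1500, 7500)):
            assert IntervalSpec(interval).stride(25.0) == stride


class TestCumulativeWindows:
    def test_56_minute_clip_yields_11_windows(self):
        times = np.arange(1, 3360) * 1.0  # 1-s interval samples
        windows = cumulative_windows(make_samples(times, np.ones(len(times)), 1.0), 300.0, 3360.0)
        assert len(windows) == 11

    def test_one_hour_clip_yields_12_windows(self):
        times = np.arange(1, 3601) * 1.0
        windows = cumulative_windows(make_samples(times, np.ones(3600), 1.0), 300.0, 3600.0)
        assert len(windows) == 12

    def test_constant_ai_sums_directly(self):
        # 300 s of full-frame pairs: current-frame times (0, 300], one per 0.04 s
        times = np.arange(1, 7501) * 0.04
        windows = cumulative_windows(make_samples(times, np.full(7500, 0.01)), 300.0, 300.0)
        assert len(windows) == 1
        assert windows[0].n_samples == 7500
        assert windows[0].cumulative_ai == pytest.approx(0.01 * 7500)

    def test_each_window_holds_window_over_interval_pairs(self):
        for interval in (0.2, 1.0, 10.0, 60.0, 300.0):
            times = np.arange(1, int(600 / interval) + 1) * interval
            wins = cumulative_windows(
                make_samples(times, np.ones(len(times)), interval), 300.0, 600.0
            )
            assert [w.n_samples for w in wins] == [int(300 / interval)] * 2

    def test_missing_samples_skipped_and_counted(self):
        times = np.arange(1, 301) * 1.0
        ais = np.ones(300)
        ais[10:20] = np.nan
        wins = cumulative_windows(make_samples(times, ais, 1.0), 300.0, 300.0)
        assert wins[0].n_samples == 290
        assert wins[0].n_missing == 10
        assert wins[0].cumulative_ai == pytest.approx(290.0)

    def test_sample_partition_across_windows(self, rng):
        times = np.arange(1, 901) * 1.0
        ais = rng.random(900)
        wins = cumulative_windows(make_samples(times, ais, 1.0), 300.0, 900.0)
        assert sum(w.n_samples for w in wins) == 900
        assert sum(w.cumulative_ai for w in wins) == pytest.approx(ais.sum())

    def test_trailing_partial_window_dropped(self):
        times = np.arange(1, 451) * 1.0  # 450 s of samples
        wins = cumulative_windows(make_samples(times, np.ones(450), 1.0), 300.0, 450.0)
        assert len(wins) == 1

    def test_nonpositive_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            cumulative_windows([], window=0.0, clip_duration=100.0)

    def test_unsorted_samples_error(self):
        samples = make_samples([2.0, 1.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="sorted"):
            cumulative_windows(samples, 300.0, 300.0)


def make_windows(values, interval, starts=None):
    starts = starts if starts is not None else np.arange(len(values)) * 300.0
    return [
        CumulativeWindow(
            window_start=s,
            window_end=s + 300.0,
            cumulative_ai=v,
            n_samples=10,
            n_missing=0,
            interval=interval,
        )
        for s, v in zip(starts, values)
    ]


class TestRatioToBaseline:
    def test_identical_series_gives_100(self):
        vals = [3.0, 5.0, 2.0]
        table = ratio_to_baseline({0.04: make_windows(vals, 0.04), 0.2: make_windows(vals, 0.2)})
        by_interval = {c.interval: c for c in table}
        assert by_interval[0.04].ratio_pct == pytest.approx(100.0)
        assert by_interval[0.2].ratio_pct == pytest.approx(100.0)

    def test_halved_series_gives_50(self):
        vals = np.array([3.0, 5.0, 2.0])
        table = ratio_to_baseline(
            {0.04: make_windows(vals, 0.04), 1.0: make_windows(vals / 2, 1.0)}
        )
        assert {c.interval: c for c in table}[1.0].ratio_pct == pytest.approx(50.0)

    def test_mean_ratio_matches_per_window_loop(self, rng):
        base = rng.uniform(1, 10, 8)
        other = rng.uniform(0.1, 10, 8)
        table = ratio_to_baseline(
            {0.04: make_windows(base, 0.04), 10.0: make_windows(other, 10.0)}
        )
        expected = np.mean([100 * o / b for o, b in zip(other, base)])
        comp = {c.interval: c for c in table}[10.0]
        assert comp.ratio_pct == pytest.approx(expected)
        assert comp.ratio_of_means_pct == pytest.approx(100 * other.mean() / base.mean())

    def test_missing_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            ratio_to_baseline({1.0: make_windows([1.0], 1.0)}, baseline=0.04)

    def test_zero_baseline_windows_excluded(self):
        base = [2.0, 0.0, 4.0]
        other = [1.0, 5.0, 1.0]
        table = ratio_to_baseline({0.04: make_windows(base, 0.04), 1.0: make_windows(other, 1.0)})
        comp = {c.interval: c for c in table}[1.0]
        assert comp.ratio_pct == pytest.approx(np.mean([50.0, 25.0]))

    def test_mismatched_boundaries_error(self):
        a = make_windows([1.0, 2.0], 0.04)
        b = make_windows([1.0, 2.0], 1.0, starts=[100.0, 400.0])
        with pytest.raises(ValueError, match="boundaries"):
            ratio_to_baseline({0.04: a, 1.0: b})

    def test_sem_is_sd_over_sqrt_n(self):
        vals = [10.0, 20.0]
        table = ratio_to_baseline({0.04: make_windows(vals, 0.04)})
        assert table[0].mean_cumulative_ai == pytest.approx(15.0)
        assert table[0].sem == pytest.approx(5.0)


class TestSummarizeGroups:
    def test_two_window_group_mean_and_sem(self):
        wins = make_windows([10.0, 20.0], 0.04)
        for w in wins:
            w.meta["age_week"] = 3
        out = summarize_groups(wins, ["age_week"])
        row = out.iloc[0]
        assert row["n"] == 2
        assert row["mean_cumulative_ai"] == pytest.approx(15.0)
        assert row["sem"] == pytest.approx(5.0)

    def test_singleton_group_sem_is_missing(self):
        wins = make_windows([10.0], 0.04)
        wins[0].meta["age_week"] = 1
        out = summarize_groups(wins, ["age_week"])
        assert math.isnan(out.iloc[0]["sem"])

    def test_group_counts_partition_total(self, rng):
        wins = make_windows(rng.uniform(0, 5, 12), 0.04)
        for i, w in enumerate(wins):
            w.meta["age_week"] = 1 + i % 3
            w.roi_label = ("feeder", "drinker", "open")[i % 2]
        out = summarize_groups(wins, ["age_week", "roi_label"])
        assert out["n"].sum() == 12

    def test_empty_keys_error(self):
        with pytest.raises(ValueError, match="grouping key"):
            summarize_groups(make_windows([1.0], 0.04), [])

    def test_unknown_key_errors(self):
        with pytest.raises(KeyError, match="time_of_day"):
            summarize_groups(make_windows([1.0], 0.04), ["time_of_day"])

    def test_accepts_dataframe_input(self):
        df = windows_to_frame(make_windows([1.0, 3.0], 0.04))
        out = summarize_groups(df, ["interval"])
        assert out.iloc[0]["mean_cumulative_ai"] == pytest.approx(2.0)
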