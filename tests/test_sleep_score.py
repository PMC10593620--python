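"""Immobility detection, bout segmentation and sleep summaries.

The segmentation oracle here is an independent brute-force run-length
scanner (plain Python loop); it is reused at scale by the acceptance
suite.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cagerhythm as cr
from cagerhythm.sleep_score import (
    bout_duration_histogram,
    count_bouts_by_phase,
    detect_immobility,
    segment_sleep_bouts,
    sleep_epoch_mask,
    sleep_fraction_by_hour,
    sleep_latency,
    sleep_phase_summary,
)

from conftest import make_annotated


def brute_force_bouts(immobile, missing, min_epochs):
    """Independent oracle: scan for maximal immobile runs >= min_epochs.

    Missing epochs break runs.  Returns (start, length-in-epochs) pairs.
    """
    out = []
    run_start = None
    for i, (im, mi) in enumerate(zip(immobile, missing)):
        ok = im and not mi
        if ok and run_start is None:
            run_start = i
        if not ok and run_start is not None:
            if i - run_start >= min_epochs:
                out.append((run_start, i - run_start))
            run_start = None
    if run_start is not None and len(immobile) - run_start >= min_epochs:
        out.append((run_start, len(immobile) - run_start))
    return out


def imm_series(flags, missing=None):
    """ImmobilitySeries from a boolean pattern (True = immobile)."""
    flags = np.asarray(flags, dtype=bool)
    activity = np.where(flags, 0.0, 50.0)
    if missing is not None:
        activity = activity.astype(float)
        activity[np.asarray(missing, dtype=bool)] = np.nan
    ann = make_annotated(activity)
    return detect_immobility(ann), ann


class TestImmobility:
    @pytest.mark.parametrize(
        "activity,threshold,expected",
        [
            ([0, 0, 5, 0], 0, [True, True, False, True]),
            ([0, 0, 0], 0, [True, True, True]),
            ([0, 5, 6], 5, [True, True, False]),  # boundary inclusive
        ],
    )
    def test_threshold_predicate(self, activity, threshold, expected):
        ann = make_annotated(activity)
        imm = detect_immobility(ann, threshold)
        np.testing.assert_array_equal(imm.immobile, expected)

    def test_missing_propagates(self):
        ann = make_annotated([0.0, np.nan, 0.0])
        imm = detect_immobility(ann)
        assert not imm.immobile[1] and imm.missing[1]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_immobility(make_annotated([0.0]), -1)


class TestSegmentation:
    def test_forty_seconds_is_a_bout(self):
        imm, _ = imm_series([False, True, True, True, True, False])
        bouts = segment_sleep_bouts(imm, 40)
        assert len(bouts) == 1 and bouts[0].duration_s == 40

    def test_thirty_seconds_is_not(self):
        imm, _ = imm_series([False, True, True, True, False])
        assert segment_sleep_bouts(imm, 40) == []

    def test_two_bout_pattern(self):
        # M,I,I,I,I,I,M,I,I,I,I,M -> 50 s and 40 s  (oracle-checked pattern)
        pattern = [0, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0]
        imm, _ = imm_series(pattern)
        bouts = segment_sleep_bouts(imm, 40)
        assert [b.duration_s for b in bouts] == [50, 40]
        oracle = brute_force_bouts(np.array(pattern, bool), np.zeros(12, bool), 4)
        assert [(b.onset_index, b.duration_s // 10) for b in bouts] == oracle

    def test_missing_splits_runs(self):
        flags = [True] * 9
        missing = [False] * 4 + [True] + [False] * 4
        imm, _ = imm_series(flags, missing)
        bouts = segment_sleep_bouts(imm, 40)
        assert [b.duration_s for b in bouts] == [40, 40]

    def test_non_multiple_duration_rejected(self):
        imm, _ = imm_series([True] * 5)
        with pytest.raises(ValueError, match="multiple"):
            segment_sleep_bouts(imm, 45)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(1, 400))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        flags = rng.random(n) < 0.6
        missing = rng.random(n) < 0.1
        imm, _ = imm_series(flags, missing)
        bouts = segment_sleep_bouts(imm, 40)
        oracle = brute_force_bouts(flags & ~missing, np.zeros(n, bool), 4)
        assert [(b.onset_index, b.duration_s // 10) for b in bouts] == oracle

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_raising_threshold_is_monotone(self, seed):
        """A higher minimum duration never yields more bouts or more sleep."""
        rng = np.random.default_rng(seed)
        flags = rng.random(500) < 0.7
        imm, _ = imm_series(flags)
        prev_n, prev_t = np.inf, np.inf
        for min_s in (40, 80, 120, 200):
            bouts = segment_sleep_bouts(imm, min_s)
            n, t = len(bouts), sum(b.duration_s for b in bouts)
            assert n <= prev_n and t <= prev_t
            prev_n, prev_t = n, t

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_time_conservation(self, seed):
        """Sleep + wake + missing epochs account for every epoch."""
        rng = np.random.default_rng(seed)
        n = 2000
        activity = np.where(rng.random(n) < 0.5, 0.0, 40.0)
        activity[rng.random(n) < 0.05] = np.nan
        ann = make_annotated(activity)
        imm = detect_immobility(ann)
        bouts = segment_sleep_bouts(imm, 40)
        asleep = sleep_epoch_mask(bouts, ann)
        n_sleep = int(asleep.sum())
        n_missing = int(ann.missing.sum())
        n_wake = int((~asleep & ~ann.missing).sum())
        assert n_sleep + n_wake + n_missing == n
        assert not np.any(asleep & ann.missing)


class TestHourlySleep:
    def test_half_hour_bout_gives_fifty_percent(self):
        activity = np.full(8640, 50.0)
        activity[360 : 360 + 180] = 0.0  # 30 min immobile inside hour 1
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        hourly = sleep_fraction_by_hour(bouts, ann)
        assert hourly.loc[hourly["ZT_hour"] == 1, "pct_asleep"].item() == pytest.approx(50.0)

    def test_bout_spanning_hour_boundary_splits_overlap(self):
        activity = np.full(8640, 50.0)
        activity[360 - 60 : 360 + 60] = 0.0  # last 10 min of hr 0 + first 10 of hr 1
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        hourly = sleep_fraction_by_hour(bouts, ann).set_index("ZT_hour")
        assert hourly.loc[0, "pct_asleep"] == pytest.approx(100 * 60 / 360, abs=1e-9)
        assert hourly.loc[1, "pct_asleep"] == pytest.approx(100 * 60 / 360, abs=1e-9)

    def test_no_bouts_gives_zero_everywhere(self):
        ann = make_annotated(np.full(8640, 50.0))
        hourly = sleep_fraction_by_hour([], ann)
        assert (hourly["pct_asleep"] == 0).all()

    def test_all_missing_hour_is_nan(self):
        activity = np.full(8640, 50.0)
        activity[:360] = np.nan
        ann = make_annotated(activity)
        hourly = sleep_fraction_by_hour([], ann).set_index("ZT_hour")
        assert np.isnan(hourly.loc[0, "pct_asleep"])
        assert hourly.loc[0, "coverage"] == 0.0


class TestPhaseSummary:
    def hourly_frame(self, values):
        return pd.DataFrame(
            {
                "animal_id": "a",
                "day": 0,
                "ZT_hour": range(24),
                "pct_asleep": values,
                "coverage": 1.0,
            }
        )

    def test_light_asleep_dark_awake(self, schedule, tiny_design):
        hourly = self.hourly_frame([100.0] * 12 + [0.0] * 12)
        out = sleep_phase_summary(hourly, schedule, tiny_design).set_index("window")
        assert out.loc["whole", "pct_asleep"] == pytest.approx(50.0)
        assert out.loc["light", "pct_asleep"] == pytest.approx(100.0)
        assert out.loc["dark", "pct_asleep"] == pytest.approx(0.0)

    def test_uniform_quarter(self, schedule, tiny_design):
        out = sleep_phase_summary(self.hourly_frame([25.0] * 24), schedule, tiny_design)
        assert (out["pct_asleep"] == 25.0).all()

    def test_missing_hour_uses_available_and_flags_coverage(self, schedule, tiny_design):
        values = [0.0] * 12 + [30.0] * 12
        hourly = self.hourly_frame(values)
        hourly.loc[hourly["ZT_hour"] == 13, "pct_asleep"] = np.nan
        out = sleep_phase_summary(hourly, schedule, tiny_design).set_index("window")
        assert out.loc["dark", "pct_asleep"] == pytest.approx(30.0)
        assert out.loc["dark", "coverage"] == pytest.approx(11 / 12)


class TestLatency:
    def test_already_asleep_at_lights_on_is_zero(self):
        activity = np.full(2 * 8640, 50.0)
        activity[8640 - 180 : 8640 + 180] = 0.0  # bout spans day-2 lights-on
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        day2 = int(ann.treatment_day[8640])
        assert sleep_latency(bouts, ann, day2) == 0.0

    def test_first_bout_600_seconds_in(self):
        activity = np.full(8640, 50.0)
        activity[60:100] = 0.0
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        assert sleep_latency(bouts, ann, int(ann.treatment_day[0])) == 600.0

    def test_no_light_phase_sleep_is_missing(self):
        activity = np.full(8640, 50.0)
        activity[5000:5200] = 0.0  # dark-phase bout only
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        assert np.isnan(sleep_latency(bouts, ann, int(ann.treatment_day[0])))

    def test_day_outside_trace_errors(self):
        ann = make_annotated(np.full(8640, 50.0))
        with pytest.raises(ValueError):
            sleep_latency([], ann, 99)


class TestBoutAttribution:
    def test_counts_by_onset_phase(self, study_design):
        activity = np.full(8640, 50.0)
        activity[100:150] = 0.0  # light bout
        activity[4500:4550] = 0.0  # dark bout 1
        activity[5000:5050] = 0.0  # dark bout 2
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        counts = count_bouts_by_phase(bouts, study_design).set_index("phase")
        assert counts.loc["light", "n_bouts"] == 1
        assert counts.loc["dark", "n_bouts"] == 2

    def test_boundary_spanning_bout_counted_at_onset(self, study_design):
        activity = np.full(8640, 50.0)
        # onset at ZT 11.9 (light), runs 120 s into the dark phase
        onset = int(11.9 * 360)
        activity[onset : onset + 48] = 0.0
        ann = make_annotated(activity)
        bouts = segment_sleep_bouts(detect_immobility(ann), 40)
        assert len(bouts) == 1 and bouts[0].onset_phase == "light"
        counts = count_bouts_by_phase(bouts, study_design)
        assert counts["phase"].tolist() == ["light"]
        # epoch-level sleep attribution still credits the dark phase
        mask = sleep_epoch_mask(bouts, ann)
        assert mask[~ann.is_light].sum() > 0

    def test_zero_bouts_is_zero_not_missing(self, study_design):
        counts = count_bouts_by_phase([], study_design)
        assert counts.empty  # caller reindexes to 0 per calendar slot


class TestHistogram:
    def make_bouts(self, durations):
        return [
            cr.SleepBout("a", i, pd.Timestamp("2021-06-01"), d, "dark", 1, 13.0)
            for i, d in enumerate(durations)
        ]

    def test_one_bout_per_bin(self):
        hist = bout_duration_histogram(self.make_bouts([50, 300, 1800, 5400]))
        assert (hist["pct"] == 25.0).all()

    def test_bin_boundaries_inclusive_left(self):
        hist = bout_duration_histogram(self.make_bouts([60])).set_index("bin")
        assert hist.loc["le1min", "pct"] == 100.0
        hist = bout_duration_histogram(self.make_bouts([600])).set_index("bin")
        assert hist.loc["1to10min", "pct"] == 100.0
        hist = bout_duration_histogram(self.make_bouts([3600])).set_index("bin")
        assert hist.loc["10to60min", "pct"] == 100.0

    def test_empty_selection_has_nan_percentages(self):
        hist = bout_duration_histogram([])
        assert (hist["count"] == 0).all()
        assert hist["pct"].isna().all()

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        hist = bout_duration_histogram(
            self.make_bouts((rng.integers(4, 500, size=200) * 10).tolist())
        )
        assert hist["pct"].sum() == pytest.approx(100.0, abs=1e-9)
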