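import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifemon.pattern_stats import (
    ActivityProfile,
    ActivityTimeline,
    DafRecord,
    Episode,
    build_dap,
    compute_daf,
    compute_raf,
    fit_profile,
    format_daf_delta,
    grade_gaf,
    movement_daf,
    windows_to_timeline,
)
from lifemon.sensor_io import (
    IDLE_LABEL,
    LabeledWindow,
    SensorEvent,
    SensorSpec,
    SensorStream,
)

DAY = date(2024, 5, 6)


def label_run(labels, size=60):
    """Contiguous windows (all-zero features) carrying the given labels."""
    base = datetime(2024, 5, 6)
    return [
        LabeledWindow(base + timedelta(seconds=i * size), size, {}, lab)
        for i, lab in enumerate(labels)
    ]


def episode(activity, start_min, end_min):
    base = datetime(2024, 5, 6)
    return Episode(activity, base + timedelta(minutes=start_min), base + timedelta(minutes=end_min))


# ---------------------------------------------------------------------------
# Episode merging
# ---------------------------------------------------------------------------

class TestTimeline:
    def test_two_sleep_runs_with_wide_gap_are_two_episodes(self):
        labels = ["sleeping"] * 5 + [IDLE_LABEL] * 2 + ["sleeping"] * 2
        timeline = windows_to_timeline(label_run(labels))
        assert [e.activity for e in timeline.episodes] == ["sleeping", "sleeping"]

    def test_single_idle_window_does_not_split_an_episode(self):
        labels = ["sleeping"] * 5 + [IDLE_LABEL] + ["sleeping"] * 2
        timeline = windows_to_timeline(label_run(labels))
        assert len(timeline.episodes) == 1
        assert timeline.episodes[0].end - timeline.episodes[0].start == timedelta(minutes=8)

    def test_different_activity_always_splits(self):
        labels = ["eating"] * 3 + ["toileting"] + ["eating"] * 2
        timeline = windows_to_timeline(label_run(labels))
        assert [e.activity for e in timeline.episodes] == ["eating", "toileting", "eating"]

    def test_episodes_sorted_and_non_overlapping(self):
        labels = ["eating"] * 2 + [IDLE_LABEL] * 3 + ["toileting"] * 2 + ["eating"]
        timeline = windows_to_timeline(label_run(labels))
        for prev, nxt in zip(timeline.episodes, timeline.episodes[1:]):
            assert prev.end <= nxt.start

    def test_unlabeled_windows_rejected(self):
        with pytest.raises(ValueError, match="labeled"):
            windows_to_timeline(label_run([None, "eating"]))


# ---------------------------------------------------------------------------
# DAF
# ---------------------------------------------------------------------------

class TestDaf:
    def test_three_eating_episodes_count_three(self):
        timeline = ActivityTimeline(
            DAY, [episode("eating", 540, 570), episode("eating", 780, 810), episode("eating", 1140, 1170)]
        )
        assert compute_daf(timeline, "eating").value == 3

    def test_absent_activity_counts_zero(self):
        timeline = ActivityTimeline(DAY, [episode("eating", 540, 570)])
        assert compute_daf(timeline, "showering").value == 0

    def test_unknown_dia_against_vocabulary_rejected(self):
        timeline = ActivityTimeline(DAY, [])
        with pytest.raises(KeyError, match="unknown DIA"):
            compute_daf(timeline, "flying", vocabulary=["eating", "sleeping"])

    def test_episode_merge_rule_governs_the_count(self):
        labels = ["sleeping"] * 5 + [IDLE_LABEL] * 2 + ["sleeping"] * 2
        timeline = windows_to_timeline(label_run(labels))
        assert compute_daf(timeline, "sleeping").value == 2

    def test_movement_counts_location_transitions(self):
        sensors = [
            SensorSpec("bed", "Bed", "bedroom"),
            SensorSpec("fridge", "Fridge", "kitchen"),
            SensorSpec("stove", "Stove", "kitchen"),
            SensorSpec("flush", "Toilet flush", "bathroom"),
        ]
        base = datetime(2024, 5, 6)

        def ev(sid, minute):
            return SensorEvent(sid, base + timedelta(minutes=minute), base + timedelta(minutes=minute + 1))

        # bedroom -> kitchen -> kitchen -> bathroom -> bedroom: 3 transitions
        stream = SensorStream(
            sensors, [ev("bed", 0), ev("fridge", 60), ev("stove", 65), ev("flush", 120), ev("bed", 200)]
        )
        assert movement_daf(stream, DAY).value == 3


# ---------------------------------------------------------------------------
# RAF and profiles
# ---------------------------------------------------------------------------

class TestRaf:
    def test_twenty_occurrences_over_twenty_five_days(self):
        series = [DafRecord(DAY + timedelta(days=d), "cooking", 1.0 if d < 20 else 0.0) for d in range(25)]
        assert compute_raf(series) == pytest.approx(0.8)

    def test_constant_series_returns_the_constant(self):
        assert compute_raf([4.0] * 7) == 4.0

    def test_simple_mean(self):
        assert compute_raf([1, 2, 3]) == 2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_raf([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_raf_equals_brute_force_mean(self, values):
        brute = sum(values) / len(values)
        assert compute_raf(values) == pytest.approx(brute, abs=1e-9)


class TestProfile:
    def test_zero_two_series_closed_form(self):
        profile = fit_profile([0.0, 2.0], "eating")
        assert profile.raf == 1.0
        assert profile.sd == pytest.approx(math.sqrt(2))

    def test_constant_series_has_zero_dispersion(self):
        profile = fit_profile([3.0, 3.0, 3.0], "eating")
        assert profile.sd == 0.0

    def test_single_day_warns_and_sets_zero_dispersion(self):
        with pytest.warns(UserWarning, match="single training day"):
            profile = fit_profile([5.0], "eating")
        assert profile.sd == 0.0

    def test_dia_taken_from_records(self):
        series = [DafRecord(DAY, "toileting", 4.0), DafRecord(DAY + timedelta(days=1), "toileting", 6.0)]
        profile = fit_profile(series)
        assert profile.dia == "toileting"
        assert profile.raf == 5.0


# ---------------------------------------------------------------------------
# GAF grading
# ---------------------------------------------------------------------------

def banding_oracle(z):
    """Brute-force band lookup: interval table, boundaries to the inner band."""
    table = [
        (-math.inf, -2, -2, False, False),  # z strictly below -2
        (-2, -1, -1, True, False),
        (-1, 1, 0, True, True),
        (1, 2, 1, False, True),
        (2, math.inf, 2, False, False),
    ]
    for lo, hi, grade, lo_closed, hi_closed in table:
        above = z > lo or (lo_closed and z == lo)
        below = z < hi or (hi_closed and z == hi)
        if above and below:
            return grade
    raise AssertionError


class TestGrading:
    PROFILE = ActivityProfile("eating", raf=3.0, sd=0.8, days=25)

    def test_value_at_raf_is_regular(self):
        assert grade_gaf(3.0, self.PROFILE) == 0

    @pytest.mark.parametrize("z,expected", [(1.5, 1), (-2.5, -2), (0.0, 0), (2.5, 2), (-1.5, -1)])
    def test_band_interior(self, z, expected):
        assert grade_gaf(self.PROFILE.raf + z * self.PROFILE.sd, self.PROFILE) == expected

    @pytest.mark.parametrize("z,expected", [(-2.0, -1), (-1.0, 0), (1.0, 0), (2.0, 1)])
    def test_boundaries_fall_in_the_more_regular_band(self, z, expected):
        assert grade_gaf(self.PROFILE.raf + z * self.PROFILE.sd, self.PROFILE) == expected

    def test_grid_matches_banding_oracle(self):
        for z in np.linspace(-4, 4, 1601):
            value = self.PROFILE.raf + z * self.PROFILE.sd
            expected = banding_oracle((value - self.PROFILE.raf) / self.PROFILE.sd)
            assert grade_gaf(value, self.PROFILE) == expected

    def test_symmetry_about_the_raf(self):
        for delta in np.linspace(0, 4 * self.PROFILE.sd, 101):
            up = grade_gaf(self.PROFILE.raf + delta, self.PROFILE)
            down = grade_gaf(self.PROFILE.raf - delta, self.PROFILE)
            assert up == -down

    def test_monotone_in_the_daf_value(self):
        grades = [grade_gaf(v, self.PROFILE) for v in np.linspace(-2, 8, 401)]
        assert grades == sorted(grades)

    def test_degenerate_profile_exact_match_rule(self):
        flat = ActivityProfile("eating", raf=2.0, sd=0.0, days=10)
        assert grade_gaf(2.0, flat) == 0
        assert grade_gaf(2.5, flat) == 2
        assert grade_gaf(1.0, flat) == -2

    def test_training_days_grade_mostly_regular_under_normal_dafs(self):
        rng = np.random.default_rng(12)
        training = rng.normal(5.0, 1.3, size=500)
        profile = fit_profile(list(training), "eating")
        fresh = rng.normal(5.0, 1.3, size=2000)
        share_regular = np.mean([grade_gaf(v, profile) == 0 for v in fresh])
        expected = 0.6827  # mass of the inner band of a standard normal
        sigma = math.sqrt(expected * (1 - expected) / 2000)
        assert abs(share_regular - expected) <= 3 * sigma


# ---------------------------------------------------------------------------
# DAP assembly and display strings
# ---------------------------------------------------------------------------

DIABETES_ORDER = ("eating", "sleeping", "movement", "toileting", "weight")


class TestDap:
    def test_all_regular_vector(self):
        dap = build_dap(DAY, dict.fromkeys(DIABETES_ORDER, 0), DIABETES_ORDER)
        assert dap.gafs == (0, 0, 0, 0, 0)

    def test_toileting_spike_lands_in_fourth_position(self):
        gafs = dict.fromkeys(DIABETES_ORDER, 0)
        gafs["toileting"] = 2
        dap = build_dap(DAY, gafs, DIABETES_ORDER)
        assert dap.gafs == (0, 0, 0, 2, 0)

    def test_duplicate_dia_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_dap(DAY, {"eating": 0}, ("eating", "eating"))

    def test_missing_dia_rejected(self):
        with pytest.raises(KeyError, match="sleeping"):
            build_dap(DAY, {"eating": 0}, ("eating", "sleeping"))

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError, match="GAF"):
            build_dap(DAY, {"eating": 3}, ("eating",))


class TestDisplay:
    @pytest.mark.parametrize(
        "value,raf,expected",
        [(2, 1, "2(▲ 1)"), (1, 1, "1"), (0, 2, "0(▼ 2)"), (3.5, 1.2, "3.5(▲ 2.5)")],
    )
    def test_delta_strings(self, value, raf, expected):
        assert format_daf_delta(value, raf) == expected
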