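import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfsleep import (
    AnalysisWindow,
    ComputationError,
    ScoringParams,
    ValidationError,
    classify_seconds,
    compute_sleep_metrics,
    detect_sleep_bouts,
)
from zfsleep.sleep_scoring import (
    IMMOBILE,
    MISSING,
    MOVING,
    SLEEP,
    WAKE,
    count_awakenings,
)

from conftest import labels_from_string, trajectory_with_speeds


def brute_force_bouts(labels, thr=6):
    """Independent run-length oracle: scan seconds one by one.

    Returns (state, start_index, length) triples; missing seconds belong to
    no bout and terminate runs.  Immobile runs shorter than `thr` are wake.
    """
    bouts = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] == MISSING:
            i += 1
            continue
        # one observed segment
        j = i
        while j < n and labels[j] != MISSING:
            j += 1
        k = i
        pending_wake = None
        while k < j:
            r = k
            while r < j and labels[r] == labels[k]:
                r += 1
            if labels[k] == IMMOBILE and (r - k) >= thr:
                if pending_wake is not None:
                    bouts.append((WAKE, pending_wake, k - pending_wake))
                    pending_wake = None
                bouts.append((SLEEP, k, r - k))
            else:
                if pending_wake is None:
                    pending_wake = k
            k = r
        if pending_wake is not None:
            bouts.append((WAKE, pending_wake, j - pending_wake))
        i = j
    return bouts


class TestClassifySeconds:
    @pytest.mark.parametrize(
        "speeds,expected",
        [([0.5, 1.2, 0.3], MOVING),   # any sample above threshold
         ([0.2, 0.9], IMMOBILE),      # all samples at or below
         ([1.0], IMMOBILE)],          # exactly at threshold: strict rule
    )
    def test_threshold_rule(self, speeds, expected, scoring):
        from zfsleep import Trajectory

        t = np.linspace(0, 0.99, len(speeds)) if len(speeds) > 1 else np.array([0.5])
        traj = Trajectory("f", t=t, x=np.zeros_like(t), y=np.zeros_like(t),
                          v=np.array(speeds, float))
        cls = classify_seconds(traj, scoring, AnalysisWindow(0, 1))
        assert cls.labels[0] == expected

    def test_empty_second_is_missing(self, scoring):
        from zfsleep import Trajectory

        traj = Trajectory("f", t=np.array([0.5, 2.5]), x=np.zeros(2),
                          y=np.zeros(2), v=np.array([0.1, 0.1]))
        cls = classify_seconds(traj, scoring, AnalysisWindow(0, 3))
        assert list(cls.labels) == [IMMOBILE, MISSING, IMMOBILE]

    def test_undefined_first_velocity_not_an_observation(self, scoring):
        from zfsleep import Trajectory

        traj = Trajectory("f", t=np.array([0.2, 1.2, 2.2]), x=np.zeros(3),
                          y=np.zeros(3), v=np.array([np.nan, 0.5, 0.5]))
        cls = classify_seconds(traj, scoring, AnalysisWindow(0, 3))
        assert cls.labels[0] == MISSING

    def test_requires_velocities(self, scoring):
        from zfsleep import Trajectory

        traj = Trajectory("f", t=np.arange(3.0), x=np.zeros(3), y=np.zeros(3))
        with pytest.raises(ValidationError):
            classify_seconds(traj, scoring, AnalysisWindow(0, 2))

    def test_monotone_in_movement_threshold(self):
        rng = np.random.default_rng(5)
        speeds = rng.exponential(1.0, 300)
        traj = trajectory_with_speeds(speeds, rate=3)
        w = AnalysisWindow(0, 300)
        lo = classify_seconds(traj, ScoringParams(movement_threshold=0.5), w)
        hi = classify_seconds(traj, ScoringParams(movement_threshold=2.0), w)
        # raising the threshold can only turn MOVING into IMMOBILE
        assert np.all((hi.labels == MOVING) <= (lo.labels == MOVING))


class TestDetectSleepBouts:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("IIIIII", [(SLEEP, 0, 6)]),  # shortest possible sleep bout
            ("MIIIIIM", [(WAKE, 0, 7)]),  # 5 s immobility stays wake
            ("MIIIIIIIM", [(WAKE, 0, 1), (SLEEP, 1, 7), (WAKE, 8, 1)]),
            ("MMMM", [(WAKE, 0, 4)]),
        ],
    )
    def test_worked_examples(self, s, expected, make_classification, scoring):
        seg = detect_sleep_bouts(make_classification(s), scoring)
        got = [(b.state, b.start_s, b.duration_s) for b in seg.bouts]
        assert got == expected

    def test_missing_breaks_immobility_runs(self, make_classification, scoring):
        # 8 immobile seconds split 4+4 by a gap: no sleep is scored
        seg = detect_sleep_bouts(make_classification("IIII.IIII"), scoring)
        assert all(b.state == WAKE for b in seg.bouts)
        assert seg.missing_s == 1

    def test_truncation_flags_at_edges_and_gaps(self, make_classification, scoring):
        seg = detect_sleep_bouts(make_classification("IIIIIIM.MIIIIII"), scoring)
        states = [(b.state, b.truncated_start, b.truncated_end) for b in seg.bouts]
        assert states == [
            (SLEEP, True, False),   # starts at the window edge
            (WAKE, False, True),    # ends at the gap
            (WAKE, True, False),    # starts after the gap
            (SLEEP, False, True),   # runs into the window edge
        ]

    def test_conservation_of_seconds(self, make_classification, scoring):
        rng = np.random.default_rng(9)
        for _ in range(50):
            s = "".join(rng.choice(list("MI."), 120))
            seg = detect_sleep_bouts(make_classification(s), scoring)
            assert sum(b.duration_s for b in seg.bouts) + seg.missing_s == 120

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="MI.", min_size=1, max_size=80))
    def test_matches_brute_force_oracle(self, s):
        labels = labels_from_string(s)
        from zfsleep.sleep_scoring import SecondClassification

        seg = detect_sleep_bouts(SecondClassification("h", labels, 0.0))
        got = [(b.state, int(b.start_s), b.duration_s) for b in seg.bouts]
        assert got == brute_force_bouts(labels)

    def test_monotone_in_sleep_period_threshold(self, make_classification):
        rng = np.random.default_rng(21)
        s = "".join(rng.choice(list("MI"), 500, p=[0.4, 0.6]))
        ratios = []
        for thr in (3, 6, 10):
            seg = detect_sleep_bouts(
                make_classification(s), ScoringParams(sleep_period_threshold=thr)
            )
            ratios.append(sum(b.duration_s for b in seg.bouts if b.state == SLEEP))
        assert ratios[0] >= ratios[1] >= ratios[2]


class TestSleepMetrics:
    def test_alternating_six_six(self, make_classification, scoring):
        s = ("I" * 6 + "M" * 6) * 300  # 3600 s of 6-s sleep / 6-s wake cycles
        seg = detect_sleep_bouts(make_classification(s), scoring)
        m = compute_sleep_metrics(seg)
        assert m.sleep_ratio == pytest.approx(0.5)
        assert m.mean_sleep_bout_s == pytest.approx(6.0)
        assert m.mean_wake_bout_s == pytest.approx(6.0)
        assert m.fragmentation == pytest.approx(300.0)

    def test_single_sleep_bout_whole_window(self, make_classification, scoring):
        seg = detect_sleep_bouts(make_classification("I" * 600), scoring)
        m = compute_sleep_metrics(seg)
        assert m.sleep_ratio == 1.0
        assert m.fragmentation == 0.0

    def test_no_sleep_gives_undefined_mean_not_zero(self, make_classification,
                                                    scoring):
        seg = detect_sleep_bouts(make_classification("M" * 60), scoring)
        m = compute_sleep_metrics(seg)
        assert m.sleep_ratio == 0.0
        assert math.isnan(m.mean_sleep_bout_s)

    def test_ratios_sum_to_one_without_missing(self, make_classification, scoring):
        rng = np.random.default_rng(3)
        s = "".join(rng.choice(list("MI"), 400))
        m = compute_sleep_metrics(detect_sleep_bouts(make_classification(s), scoring))
        assert m.sleep_ratio + m.wake_ratio == pytest.approx(1.0)

    def test_missing_excluded_from_denominators(self, make_classification, scoring):
        s = "I" * 6 + "." * 4 + "M" * 10
        m = compute_sleep_metrics(detect_sleep_bouts(make_classification(s), scoring))
        assert m.analyzed_s == 16
        assert m.sleep_ratio == pytest.approx(6 / 16)

    def test_awakenings_require_adjacency(self, make_classification, scoring):
        # sleep bout ending at a gap is not an observed awakening
        seg = detect_sleep_bouts(make_classification("IIIIII.MMM"), scoring)
        assert count_awakenings(seg) == 0
        seg2 = detect_sleep_bouts(make_classification("IIIIIIMMM"), scoring)
        assert count_awakenings(seg2) == 1

    def test_zero_analyzed_seconds_raises(self, make_classification, scoring):
        seg = detect_sleep_bouts(make_classification("...."), scoring)
        with pytest.raises(ComputationError):
            compute_sleep_metrics(seg)

    def test_velocity_and_distance_from_trajectory(self, scoring):
        traj = trajectory_with_speeds([2.0] * 100, rate=5)
        from zfsleep import score_sleep

        m, _ = score_sleep(traj, AnalysisWindow(0, 100), scoring)
        assert m.total_distance == pytest.approx(2.0 * 100, rel=1e-2)
        assert m.velocity == pytest.approx(2.0, rel=1e-2)
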