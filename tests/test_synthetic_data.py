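import numpy as np
import pytest

from zfsleep import (
    AnalysisWindow,
    ConfigError,
    LightSchedule,
    ScoringParams,
    ValidationError,
    analytic_sleep_fraction,
    calibrate_state_params,
    default_presets,
    score_sleep,
    simulate_cohort,
    simulate_trajectory,
    simulate_zone_walk,
    social_arena_layout,
)
from zfsleep.synthetic_data import (
    CohortSpec,
    GroupPreset,
    StateParams,
    expected_scored_sleep_bout_s,
    expected_scored_sleep_ratio,
    expected_scored_wake_bout_s,
    simulate_latent_states,
)
from zfsleep.zone_assays import ArenaLayout, Band, occupancy


@pytest.fixture
def night_schedule():
    """Recording started at lights-off: the whole span is NIGHT."""
    return LightSchedule(recording_start="22:00")


class TestClosedForms:
    @pytest.mark.parametrize(
        "p_fs,p_wu,expected",
        [(0.2, 0.2, 0.5), (0.1, 0.05, 2 / 3)],
    )
    def test_stationary_sleep_fraction(self, p_fs, p_wu, expected):
        sp = StateParams(p_fall_asleep=p_fs, p_wake_up=p_wu)
        assert analytic_sleep_fraction(sp) == pytest.approx(expected)

    def test_absorbing_sleep_limit(self):
        sp = StateParams(p_fall_asleep=0.2, p_wake_up=1e-9)
        assert analytic_sleep_fraction(sp) == pytest.approx(1.0, abs=1e-6)

    def test_calibration_round_trip(self):
        sp = calibrate_state_params(11.513, 0.445, 0.18)
        assert expected_scored_sleep_bout_s(sp) == pytest.approx(11.513)
        assert expected_scored_sleep_ratio(sp) == pytest.approx(0.445)

    def test_closed_forms_match_latent_chain_monte_carlo(self):
        # score a long latent-state sequence with the production scorer and
        # compare against the geometric-bout closed forms
        from zfsleep.sleep_scoring import (
            IMMOBILE,
            MOVING,
            SecondClassification,
            compute_sleep_metrics,
            detect_sleep_bouts,
        )

        sp = StateParams(p_fall_asleep=1 / 14.0, p_wake_up=1 / 12.0)
        rng = np.random.default_rng(99)
        states = simulate_latent_states(rng, sp, 400_000)
        labels = np.where(states == 1, MOVING, IMMOBILE).astype(np.int8)
        seg = detect_sleep_bouts(SecondClassification("mc", labels, 0.0))
        m = compute_sleep_metrics(seg)
        assert m.sleep_ratio == pytest.approx(
            expected_scored_sleep_ratio(sp), abs=0.01
        )
        assert m.mean_sleep_bout_s == pytest.approx(
            expected_scored_sleep_bout_s(sp), rel=0.02
        )
        assert m.mean_wake_bout_s == pytest.approx(
            expected_scored_wake_bout_s(sp), rel=0.02
        )


class TestStateParams:
    def test_probabilities_validated(self):
        with pytest.raises(ValidationError):
            StateParams(p_fall_asleep=-0.1, p_wake_up=0.5)
        with pytest.raises(ValidationError):
            StateParams(p_fall_asleep=0.0, p_wake_up=0.0)

    def test_boundary_probabilities_allowed(self):
        StateParams(p_fall_asleep=0.0, p_wake_up=1.0)

    def test_emission_threshold_ordering_enforced(self, night_schedule):
        bad = StateParams(p_fall_asleep=0.2, p_wake_up=0.1,
                          sleep_speed_mean=1.5)  # above the 1.0 mm/s threshold
        preset = GroupPreset("bad", day=bad, night=bad)
        with pytest.raises(ConfigError):
            simulate_trajectory(preset, CohortSpec(duration_s=60), night_schedule, 0)


class TestTrajectorySimulation:
    def test_same_seed_is_bit_identical(self, night_schedule):
        preset = default_presets()["group1"]
        spec = CohortSpec(duration_s=600, sample_rate=10.0)
        a = simulate_trajectory(preset, spec, night_schedule, 42)
        b = simulate_trajectory(preset, spec, night_schedule, 42)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.v, b.v)

    def test_never_sleeping_preset_scores_zero_sleep(self, night_schedule):
        sp = StateParams(p_fall_asleep=0.0, p_wake_up=1.0)
        preset = GroupPreset("awake", day=sp, night=sp)
        traj = simulate_trajectory(
            preset, CohortSpec(duration_s=600, sample_rate=5.0), night_schedule, 3
        )
        m, _ = score_sleep(traj, AnalysisWindow(0, 600))
        assert m.sleep_ratio == 0.0

    def test_positions_confined_to_well(self, night_schedule):
        preset = default_presets()["group4"]
        spec = CohortSpec(duration_s=1200, sample_rate=10.0, well_mm=6.4)
        traj = simulate_trajectory(preset, spec, night_schedule, 7)
        assert traj.x.min() >= 0 and traj.x.max() <= 6.4
        assert traj.y.min() >= 0 and traj.y.max() <= 6.4

    def test_wake_seconds_always_moving_sleep_never(self, night_schedule):
        # scored mobility must reflect the latent state exactly
        preset = default_presets()["group1"]
        spec = CohortSpec(duration_s=2000, sample_rate=10.0)
        traj = simulate_trajectory(preset, spec, night_schedule, 11)
        m, _ = score_sleep(traj, AnalysisWindow(0, 2000))
        exp = expected_scored_sleep_ratio(preset.night)
        assert m.sleep_ratio == pytest.approx(exp, abs=0.06)
        assert m.missing_s == 0

    def test_cohort_determinism_and_labels(self, night_schedule):
        presets = {g: default_presets()[g] for g in ("group1", "group4")}
        spec = CohortSpec(n_per_group=2, duration_s=120, sample_rate=5.0, seed=5)
        c1 = simulate_cohort(presets, spec, night_schedule)
        c2 = simulate_cohort(presets, spec, night_schedule)
        assert [t.subject_id for t in c1] == [t.subject_id for t in c2]
        assert {t.group_label for t in c1} == {"group1", "group4"}
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.x, b.x)


class TestZoneWalk:
    def test_single_zone_layout_holds_all_time(self):
        layout = ArenaLayout(100.0, 50.0, [Band("only", 0.0, 100.0)])
        traj = simulate_zone_walk(layout, {"only": 1.0}, 300.0, seed=1)
        occ = occupancy(traj, layout, AnalysisWindow(0, 300))
        assert occ.seconds_per_zone["only"] == pytest.approx(300.0)

    def test_probabilities_must_sum_to_one(self):
        layout = social_arena_layout()
        with pytest.raises(ConfigError):
            simulate_zone_walk(layout, {"group": 0.5, "individual": 0.4}, 60, 1)
        with pytest.raises(ConfigError):
            simulate_zone_walk(layout, {"group": 0.5, "nowhere": 0.5}, 60, 1)

    def test_uniform_target_recovers_equal_occupancy(self):
        layout = social_arena_layout()
        target = {"group": 1 / 3, "individual": 1 / 3, "empty": 1 / 3}
        times = []
        for seed in range(25):
            traj = simulate_zone_walk(layout, target, 1200.0, seed=seed)
            occ = occupancy(traj, layout, AnalysisWindow(0, 1200))
            times.append([occ.seconds_per_zone[z] for z in
                          ("group", "individual", "empty")])
        means = np.mean(times, axis=0)
        sem = np.std(times, axis=0, ddof=1) / np.sqrt(len(times))
        for m, s in zip(means, sem):
            assert abs(m - 400.0) < 4 * s + 10.0

    def test_determinism(self):
        layout = social_arena_layout()
        t1 = simulate_zone_walk(layout, {"group": 0.4, "individual": 0.3,
                                          "empty": 0.3}, 120, seed=9)
        t2 = simulate_zone_walk(layout, {"group": 0.4, "individual": 0.3,
                                          "empty": 0.3}, 120, seed=9)
        np.testing.assert_array_equal(t1.x, t2.x)
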