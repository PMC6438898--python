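import numpy as np
import pytest

from reachsketch.geometry import generate_pattern_for_level
from reachsketch.io import session_to_json
from reachsketch.strategy import (
    SessionConfig,
    StrategyState,
    TerminalStateError,
    Trajectory,
    evaluate_sketch,
    next_state,
    run_session,
)
from tests_helpers import empty_trajectory, ideal_trajectory


class TestTrajectory:
    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros(3), np.zeros(3))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            Trajectory(np.array([0.0, 1.0]), np.array([0.0, np.nan]),
                       np.zeros(2))


class TestEvaluateSketch:
    def test_ideal_sweep_credits_all_dots_with_exact_length(self, layout):
        pat = generate_pattern_for_level(1, layout)
        dot_no, length, touches = evaluate_sketch(ideal_trajectory(pat), pat)
        assert dot_no == 7
        assert len(touches) == 7
        # entry-point offsets at the first and last dot cancel, so the
        # measured window is exactly the 6 x 107 px polyline
        assert length == pytest.approx(pat.ideal_length_px, abs=1e-6)

    @pytest.mark.parametrize("level", [2, 3, 5, 6])
    def test_ideal_sweep_on_bent_patterns(self, layout, level):
        pat = generate_pattern_for_level(level, layout)
        dot_no, length, _ = evaluate_sketch(ideal_trajectory(pat), pat)
        assert dot_no == 7
        assert length == pytest.approx(pat.ideal_length_px, abs=1e-6)

    def test_empty_trajectory(self, layout):
        pat = generate_pattern_for_level(1, layout)
        assert evaluate_sketch(empty_trajectory(), pat) == (0, 0.0, [])

    def test_out_of_order_touch_not_credited(self, layout):
        pat = generate_pattern_for_level(1, layout)
        dots = np.asarray(pat.dots)
        # sweep that dodges dot 2 by more than the radius, then hits dot 3
        detour = dots[1] + np.array([0.0, 2.5 * pat.dot_radius_px])
        waypoints = np.vstack([dots[0] + [-60, 0], dots[0], detour, dots[2]])
        pts = []
        for a, b in zip(waypoints[:-1], waypoints[1:]):
            for f in np.linspace(0, 1, 20, endpoint=False):
                pts.append(a + f * (b - a))
        pts.append(waypoints[-1])
        pts = np.asarray(pts)
        traj = Trajectory(np.arange(len(pts)) * 33.0, pts[:, 0], pts[:, 1])
        dot_no, length, touches = evaluate_sketch(traj, pat)
        assert dot_no == 1
        assert length == 0.0
        assert len(touches) == 1

    def test_interpolation_prevents_tunnelling(self, layout):
        pat = generate_pattern_for_level(1, layout)
        dots = np.asarray(pat.dots)
        # two samples only, far apart, whose connecting segment passes
        # through every dot center
        start = dots[0] + np.array([-60.0, 0.0])
        traj = Trajectory(np.array([0.0, 1000.0]),
                          np.array([start[0], dots[-1][0]]),
                          np.array([start[1], dots[-1][1]]))
        dot_no, _, touches = evaluate_sketch(traj, pat)
        assert dot_no == 7
        assert touches == sorted(touches)

    def test_touch_times_increasing_and_match_count(self, layout, rng):
        pat = generate_pattern_for_level(2, layout)
        traj = ideal_trajectory(pat)
        dot_no, _, touches = evaluate_sketch(traj, pat)
        assert dot_no == len(touches)
        assert all(a < b for a, b in zip(touches, touches[1:]))


class TestStateMachine:
    def test_adequate_promotes(self):
        s = next_state(StrategyState(current_level=1), "adequate")
        assert s.current_level == 2 and s.mode == "increase_difficulty"

    def test_inadequate_repeats(self):
        s = next_state(StrategyState(current_level=3), "inadequate")
        assert s.current_level == 3 and s.mode == "same_difficulty"

    def test_adequate_at_top_level_terminates(self):
        s = next_state(StrategyState(current_level=6), "adequate")
        assert s.terminal

    def test_terminal_is_absorbing(self):
        s = next_state(StrategyState(current_level=6), "adequate")
        with pytest.raises(TerminalStateError):
            next_state(s, "adequate")

    def test_level_monotone_over_random_adequacy_sequences(self, rng):
        for _ in range(1000):
            state = StrategyState(current_level=1)
            levels = [1]
            for adequacy in rng.choice(["adequate", "inadequate"], size=12):
                state = next_state(state, str(adequacy))
                if state.terminal:
                    break
                levels.append(state.current_level)
            assert all(a <= b for a, b in zip(levels, levels[1:]))

    def test_always_adequate_reaches_terminal_in_six_steps(self):
        state = StrategyState(current_level=1)
        for _ in range(6):
            assert not state.terminal
            state = next_state(state, "adequate")
        assert state.terminal

    def test_never_adequate_never_leaves_level_one(self):
        state = StrategyState(current_level=1)
        for _ in range(50):
            state = next_state(state, "inadequate")
            assert state.current_level == 1 and not state.terminal


class TestRunSession:
    def test_perfect_source_completes_all_levels(self, canonical_bounds, layout):
        def source(pattern, task_index, rng):
            return ideal_trajectory(pattern)

        rec = run_session(source, canonical_bounds, seed=1)
        assert len(rec.tasks) == 6
        assert [lvl for _, lvl in rec.progression] == [1, 2, 3, 4, 5, 6]
        assert rec.termination_reason == "dlvi_adequate"
        assert rec.perf_norm == pytest.approx(100.0)

    def test_empty_source_exhausts_budget_at_level_one(self, canonical_bounds):
        cfg = SessionConfig(session_budget_ms=5 * 60_000.0)

        def source(pattern, task_index, rng):
            return empty_trajectory()

        rec = run_session(source, canonical_bounds, cfg, seed=1)
        assert rec.termination_reason == "duration_elapsed"
        assert {lvl for _, lvl in rec.progression} == {1}
        assert rec.perf_norm == pytest.approx(0.0)
        # 5 min budget / 60 s per failed task
        assert len(rec.tasks) == 5

    def test_alternating_source_staircase_progression(self, canonical_bounds):
        def source(pattern, task_index, rng):
            if task_index % 2 == 0:
                return empty_trajectory()
            return ideal_trajectory(pattern)

        rec = run_session(source, canonical_bounds, seed=1)
        assert [lvl for _, lvl in rec.progression] == [
            1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6]
        assert rec.termination_reason == "dlvi_adequate"

    def test_missing_bounds_rejected(self, canonical_bounds):
        partial = {k: v for k, v in canonical_bounds.items() if k != 4}
        with pytest.raises(ValueError, match="4"):
            run_session(lambda p, i, r: empty_trajectory(), partial)

    def test_source_failure_flags_aborted_partial_record(self, canonical_bounds):
        def source(pattern, task_index, rng):
            if task_index == 2:
                raise RuntimeError("camera went away")
            return ideal_trajectory(pattern)

        rec = run_session(source, canonical_bounds, seed=1)
        assert rec.aborted
        assert len(rec.tasks) == 2

    def test_determinism_byte_identical_session_json(self, cohort_bounds):
        from reachsketch.virtual_user import PRESETS, make_trajectory_source
        src = make_trajectory_source(PRESETS["impaired_mild"])
        a = run_session(src, cohort_bounds, seed=77)
        b = run_session(src, cohort_bounds, seed=77)
        assert session_to_json(a) == session_to_json(b)

    def test_task_durations_respect_cap(self, cohort_bounds):
        from reachsketch.virtual_user import PRESETS, make_trajectory_source
        cfg = SessionConfig()
        rec = run_session(make_trajectory_source(PRESETS["impaired_severe"]),
                          cohort_bounds, cfg, seed=5)
        assert all(t.duration_ms <= cfg.max_task_duration_ms for t in rec.tasks)
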