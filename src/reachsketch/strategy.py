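"""Sketch evaluation and the adaptive-difficulty session engine.

A sketch is evaluated against its pattern by crediting dots strictly in
pattern order: the next expected dot is credited when the sampled hand path
(with linear interpolation between samples, so a fast sweep cannot tunnel
through a dot) comes within the dot radius of its center. The sketched
trajectory length is measured along the path between the first and the last
credited touch.

The session engine is a three-mode state machine. Adequate performance at a
level promotes to the next level ("increase difficulty"); inadequate
performance repeats the same level ("same difficulty") — the level never
decreases, the design intent being skill training rather than regression.
Adequate performance at the top level (VI) is absorbing, ending the session;
otherwise the session runs until a wall-clock budget is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .geometry import (
    DEFAULT_DOT_DIAMETER_PX,
    DEFAULT_SPACING_PX,
    DotPattern,
    MonitorLayout,
    N_DOTS,
    generate_pattern_for_level,
    layout_monitor,
)
from .scoring import LevelBounds, ScoringConfig, TaskScore, perf_norm, score_task

__all__ = [
    "Trajectory",
    "TaskRecord",
    "StrategyState",
    "SessionRecord",
    "SessionConfig",
    "TerminalStateError",
    "evaluate_sketch",
    "next_state",
    "run_session",
    "DEFAULT_TASK_DURATION_MS",
    "DEFAULT_SESSION_BUDGET_MS",
]

Mode = Literal["increase_difficulty", "same_difficulty", "terminal"]
TerminationReason = Literal["duration_elapsed", "dlvi_adequate"]

DEFAULT_TASK_DURATION_MS = 60_000.0
DEFAULT_SESSION_BUDGET_MS = 20 * 60_000.0


class TerminalStateError(RuntimeError):
    """Raised when a transition is requested on a terminal state."""


@dataclass(frozen=True)
class Trajectory:
    """Timestamped screen-space hand path.

    ``t_ms`` must be strictly increasing and all coordinates finite.
    """

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    source: Literal["simulated", "replayed"] = "simulated"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        x = np.asarray(self.x_px, dtype=float)
        y = np.asarray(self.y_px, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t_ms, x_px, y_px must be 1-D arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))
                and np.all(np.isfinite(y))):
            raise ValueError("trajectory samples must be finite")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "x_px", x)
        object.__setattr__(self, "y_px", y)

    def __len__(self) -> int:
        return int(self.t_ms.size)

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[tuple[float, float, float]],
        source: Literal["simulated", "replayed"] = "simulated",
    ) -> "Trajectory":
        arr = np.asarray(samples, dtype=float).reshape(-1, 3)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], source=source)

    def truncated(self, max_t_ms: float) -> "Trajectory":
        """Samples with t <= max_t_ms (used to enforce the per-task cap)."""
        keep = self.t_ms <= max_t_ms
        return Trajectory(self.t_ms[keep], self.x_px[keep], self.y_px[keep],
                          source=self.source)

    def path_length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x_px), np.diff(self.y_px)).sum())


@dataclass(frozen=True)
class TaskRecord:
    difficulty_level: int
    pattern: DotPattern
    score: TaskScore
    duration_ms: float
    completed: bool
    touch_times_ms: tuple[float, ...] = ()


@dataclass
class StrategyState:
    current_level: int = 1
    mode: Mode = "same_difficulty"
    elapsed_ms: float = 0.0
    history: list[TaskRecord] = field(default_factory=list)

    @property
    def terminal(self) -> bool:
        return self.mode == "terminal"


@dataclass(frozen=True)
class SessionRecord:
    tasks: tuple[TaskRecord, ...]
    progression: tuple[tuple[int, int], ...]  # (task index, level)
    perf_norm: float
    termination_reason: TerminationReason
    seed: int | None = None
    aborted: bool = False


@dataclass(frozen=True)
class SessionConfig:
    """Engine parameters for one exercise session."""

    layout: MonitorLayout = field(default_factory=lambda: layout_monitor(1600, 900))
    handedness: Literal["left", "right"] = "right"
    spacing_px: float = DEFAULT_SPACING_PX
    dot_diameter_px: float = DEFAULT_DOT_DIAMETER_PX
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    max_task_duration_ms: float = DEFAULT_TASK_DURATION_MS
    session_budget_ms: float = DEFAULT_SESSION_BUDGET_MS
    start_level: int = 1


def _first_hit_on_segment(
    ax: float, ay: float, bx: float, by: float,
    cx: float, cy: float, radius: float, s_start: float,
) -> float | None:
    """Earliest parameter s in [s_start, 1] where segment A->B enters the
    disc of radius ``radius`` around C; None if it never does."""
    abx, aby = bx - ax, by - ay
    acx, acy = cx - ax, cy - ay
    seg2 = abx * abx + aby * aby
    if seg2 == 0.0:
        d2 = (acx) ** 2 + (acy) ** 2
        return s_start if d2 <= radius * radius else None
    proj = abx * acx + aby * acy
    # quadratic seg2*s^2 - 2*proj*s + |AC|^2 - r^2 = 0
    disc = proj * proj - seg2 * (acx * acx + acy * acy - radius * radius)
    if disc < 0:
        return None
    sqrt_disc = math.sqrt(disc)
    s_lo = (proj - sqrt_disc) / seg2
    s_hi = (proj + sqrt_disc) / seg2
    entry = max(s_lo, s_start)
    if entry > 1.0 or entry > s_hi:
        return None
    return entry


def evaluate_sketch(
    trajectory: Trajectory, pattern: DotPattern
) -> tuple[int, float, list[float]]:
    """Score a hand path against a dot pattern.

    Returns ``(dot_no, traj_length_px, touch_times_ms)``. Dots are credited
    strictly in pattern order; a dot is touched when the interpolated path
    enters its radius. The trajectory length is the path length between the
    first and last credited touch points (0 if fewer than two dots are
    credited). An empty trajectory yields ``(0, 0.0, [])``.
    """
    n = len(trajectory)
    if n == 0:
        return (0, 0.0, [])
    radius = pattern.dot_radius_px
    t = trajectory.t_ms
    x = trajectory.x_px
    y = trajectory.y_px

    # cumulative arc length at each sample, for the length window
    if n > 1:
        seg_len = np.hypot(np.diff(x), np.diff(y))
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    else:
        seg_len = np.array([])
        cum = np.array([0.0])

    expected = 0
    touch_times: list[float] = []
    touch_arcs: list[float] = []

    if n == 1:
        cx, cy = pattern.dots[0]
        if math.hypot(x[0] - cx, y[0] - cy) <= radius:
            touch_times.append(float(t[0]))
            touch_arcs.append(0.0)
            expected = 1
    else:
        for i in range(n - 1):
            s_cursor = 0.0
            while expected < N_DOTS:
                cx, cy = pattern.dots[expected]
                s = _first_hit_on_segment(
                    x[i], y[i], x[i + 1], y[i + 1], cx, cy, radius, s_cursor)
                if s is None:
                    break
                touch_times.append(float(t[i] + s * (t[i + 1] - t[i])))
                touch_arcs.append(float(cum[i] + s * seg_len[i]))
                expected += 1
                s_cursor = s
            if expected >= N_DOTS:
                break

    dot_no = len(touch_times)
    length = touch_arcs[-1] - touch_arcs[0] if dot_no >= 2 else 0.0
    return (dot_no, float(length), touch_times)


def next_state(state: StrategyState, adequacy: str) -> StrategyState:
    """Advance the difficulty state machine after one scored task.

    Adequate below level 6 promotes; inadequate repeats the level; adequate
    at level 6 terminates the session. The level never decreases and the
    terminal mode is absorbing.
    """
    if state.terminal:
        raise TerminalStateError("cannot transition from a terminal state")
    if adequacy not in ("adequate", "inadequate"):
        raise ValueError(f"adequacy must be adequate/inadequate, got {adequacy!r}")
    new = StrategyState(
        current_level=state.current_level,
        mode=state.mode,
        elapsed_ms=state.elapsed_ms,
        history=list(state.history),
    )
    if adequacy == "inadequate":
        new.mode = "same_difficulty"
    elif state.current_level >= 6:
        new.mode = "terminal"
    else:
        new.current_level = state.current_level + 1
        new.mode = "increase_difficulty"
    return new


TrajectorySource = Callable[[DotPattern, int, np.random.Generator], Trajectory]


def run_session(
    trajectory_source: TrajectorySource,
    bounds: Mapping[int, LevelBounds],
    config: SessionConfig | None = None,
    seed: int | None = None,
) -> SessionRecord:
    """Run one adaptive exercise session.

    Loops: generate the current level's pattern, obtain a trajectory from
    ``trajectory_source(pattern, task_index, rng)``, truncate it to the
    per-task duration cap, evaluate and score it, then advance the state
    machine. A completed task (all 7 dots) ends when its last dot is
    credited; an incomplete task consumes the full per-task allowance. The
    session stops when the time budget is spent or adequate performance is
    reached at the top level. Identical seed and source give identical
    records. If the source raises, the partial session is returned with
    ``aborted=True``.
    """
    cfg = config or SessionConfig()
    missing = [lvl for lvl in range(1, 7) if lvl not in bounds]
    if missing:
        raise ValueError(f"bounds missing for levels {missing}")
    rng = np.random.default_rng(seed)
    state = StrategyState(current_level=cfg.start_level)
    aborted = False

    task_index = 0
    while not state.terminal and state.elapsed_ms < cfg.session_budget_ms:
        pattern = generate_pattern_for_level(
            state.current_level, cfg.layout, cfg.handedness,
            cfg.spacing_px, cfg.dot_diameter_px)
        try:
            traj = trajectory_source(pattern, task_index, rng)
        except Exception:
            aborted = True
            break
        traj = traj.truncated(cfg.max_task_duration_ms)
        dot_no, length, touch_times = evaluate_sketch(traj, pattern)
        completed = dot_no == N_DOTS
        duration = (touch_times[-1] if completed
                    else cfg.max_task_duration_ms)
        ts = score_task(dot_no, N_DOTS, length, bounds[state.current_level],
                        cfg.scoring)
        record = TaskRecord(
            difficulty_level=state.current_level,
            pattern=pattern,
            score=ts,
            duration_ms=float(duration),
            completed=completed,
            touch_times_ms=tuple(touch_times),
        )
        state.history.append(record)
        state.elapsed_ms += duration
        state = next_state(state, ts.adequacy)
        task_index += 1

    tasks = tuple(state.history)
    level_scores: dict[int, list[float]] = {}
    for rec in tasks:
        level_scores.setdefault(rec.difficulty_level, []).append(rec.score.perf_score)
    pn = perf_norm(level_scores, cfg.scoring) if level_scores else 0.0
    reason: TerminationReason = ("dlvi_adequate" if state.terminal
                                 else "duration_elapsed")
    return SessionRecord(
        tasks=tasks,
        progression=tuple((i, rec.difficulty_level) for i, rec in enumerate(tasks)),
        perf_norm=pn,
        termination_reason=reason,
        seed=seed,
        aborted=aborted,
    )
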