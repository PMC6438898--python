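"""Virtual-patient trajectory source: goal-directed reaching with noise.

Emulates the hand paths of healthy and motor-impaired users well enough to
exercise every engine path without hardware. Motion is piecewise
goal-directed, dot to dot, at a constant speed sampled at 30 Hz (a typical
skeletal-camera frame rate). Impairment and state enter as:

* perpendicular Gaussian jitter around the intended path (``jitter_sd_px``),
* a constant-fraction overshoot past each dot followed by a correction
  (``overshoot_frac``), the classic signature of poorly damped reaching,
* occasional wide misses that bypass a dot entirely (``miss_prob``),
* aim corruption: with probability ``1 - skill`` the landing point at a dot
  inherits the current path jitter instead of hitting the center,
* within-session fatigue (jitter grows per task) and across-session
  learning (jitter decays per session),
* a reach ceiling (``max_reach_level``): patterns above it — the elevated
  zone a contracted arm cannot reach — produce truncated low paths.

The simulator makes no biomechanical claim; it reproduces qualitative
orderings (more jitter => lower scores, learning => rising session scores)
used to validate the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DotPattern, N_DOTS
from .scoring import LevelBounds
from .strategy import (
    SessionConfig,
    SessionRecord,
    Trajectory,
    run_session,
)

__all__ = [
    "VirtualUserParams",
    "PRESETS",
    "simulate_trajectory",
    "make_trajectory_source",
    "simulate_course",
    "reference_bounds",
]

SAMPLE_RATE_HZ = 30.0
MIN_JITTER_SD_PX = 0.1


@dataclass(frozen=True)
class VirtualUserParams:
    skill: float = 0.9
    jitter_sd_px: float = 4.0
    speed_px_s: float = 400.0
    overshoot_frac: float = 0.05
    miss_prob: float = 0.0
    fatigue_rate: float = 0.0
    learning_rate: float = 0.0
    max_reach_level: int = 6
    sample_rate_hz: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        for name in ("skill", "miss_prob", "overshoot_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("jitter_sd_px", "fatigue_rate", "learning_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.speed_px_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("speed and sample rate must be positive")
        if not (1 <= self.max_reach_level <= 6):
            raise ValueError("max_reach_level must be 1-6")


#: named parameter sets spanning the conditions the engine is tested under
PRESETS: dict[str, VirtualUserParams] = {
    "healthy": VirtualUserParams(
        skill=0.95, jitter_sd_px=3.0, speed_px_s=500.0, overshoot_frac=0.03,
        miss_prob=0.0, fatigue_rate=0.0, learning_rate=0.0, max_reach_level=6),
    "impaired_mild": VirtualUserParams(
        skill=0.6, jitter_sd_px=12.0, speed_px_s=250.0, overshoot_frac=0.15,
        miss_prob=0.08, fatigue_rate=0.02, learning_rate=0.3, max_reach_level=4),
    "impaired_severe": VirtualUserParams(
        skill=0.3, jitter_sd_px=25.0, speed_px_s=150.0, overshoot_frac=0.3,
        miss_prob=0.25, fatigue_rate=0.05, learning_rate=0.3, max_reach_level=2),
}


def _segment_samples(
    start: np.ndarray,
    end: np.ndarray,
    speed_px_s: float,
    dt_ms: float,
    jitter_sd: float,
    rng: np.random.Generator,
    include_start: bool,
) -> np.ndarray:
    """Points along start->end at constant speed, landing exactly on ``end``,
    with perpendicular Gaussian jitter on the interior points."""
    vec = end - start
    dist = float(np.hypot(*vec))
    if dist == 0.0:
        return start[None, :] if include_start else np.empty((0, 2))
    step = speed_px_s * dt_ms / 1000.0
    n_steps = max(1, int(np.ceil(dist / step)))
    fracs = np.linspace(0.0, 1.0, n_steps + 1)
    if not include_start:
        fracs = fracs[1:]
    pts = start[None, :] + fracs[:, None] * vec[None, :]
    if jitter_sd > 0 and len(pts) > 0:
        perp = np.array([-vec[1], vec[0]]) / dist
        offs = rng.normal(0.0, jitter_sd, size=len(pts))
        # endpoints stay put only when they are the goal landing (last point)
        interior = np.ones(len(pts), dtype=bool)
        interior[-1] = fracs[-1] < 1.0
        pts = pts + np.where(interior, offs, 0.0)[:, None] * perp[None, :]
    return pts


def simulate_trajectory(
    params: VirtualUserParams,
    pattern: DotPattern,
    task_index: int = 0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """One simulated sketch of ``pattern``.

    Noise-free limits hold exactly: with zero jitter, overshoot and miss
    probability the path passes through all seven dot centers and its length
    matches the ideal polyline. Jitter s.d. grows by ``(1+fatigue_rate)`` per
    completed task within a session. Patterns above the reach ceiling yield a
    short, low-amplitude path near the bottom of the working zone that
    touches nothing.
    """
    if rng is None:
        rng = np.random.default_rng()
    dt_ms = 1000.0 / params.sample_rate_hz
    jitter = params.jitter_sd_px * (1.0 + params.fatigue_rate) ** task_index
    radius = pattern.dot_radius_px

    if pattern.difficulty_level > params.max_reach_level:
        # arm cannot be raised to the pattern's zone: drift below it
        x0, y0 = pattern.dots[0]
        zone_drop = 250.0
        start = np.array([x0, y0 + zone_drop])
        end = np.array([x0 + 0.3 * pattern.ideal_length_px, y0 + zone_drop])
        pts = _segment_samples(start, end, params.speed_px_s, dt_ms,
                               jitter, rng, include_start=True)
        t = np.arange(len(pts)) * dt_ms
        return Trajectory(t, pts[:, 0], pts[:, 1], source="simulated")

    # approach from slightly outside the first dot so the first touch is a
    # genuine arrival, then visit dots in order
    first = np.array(pattern.dots[0], dtype=float)
    approach = first + np.array([-3.0 * radius, 2.0 * radius])
    chunks: list[np.ndarray] = [approach[None, :]]
    pos = approach
    for k, dot in enumerate(pattern.dots):
        target = np.array(dot, dtype=float)
        missed = False
        if params.miss_prob > 0 and rng.random() < params.miss_prob:
            # wide miss: bypass the dot well outside its radius
            seg = target - pos
            seg_len = float(np.hypot(*seg)) or 1.0
            perp = np.array([-seg[1], seg[0]]) / seg_len
            target = target + perp * (radius * 2.5 + jitter)
            missed = True
        elif params.skill < 1.0 and jitter > 0 and rng.random() > params.skill:
            # aim corruption: the landing point inherits the path jitter,
            # so unsteady hands also land off-center, not just wander
            target = target + rng.normal(0.0, jitter, size=2)
        travel_from = pos
        chunks.append(_segment_samples(pos, target, params.speed_px_s, dt_ms,
                                       jitter, rng, include_start=False))
        pos = target
        if params.overshoot_frac > 0 and not missed and k < N_DOTS - 1:
            # continue past the dot along the incoming heading, then correct
            inc = target - travel_from
            inc_len = float(np.hypot(*inc))
            if inc_len > 0:
                over = target + (inc / inc_len) * (
                    params.overshoot_frac * pattern.spacing_px)
                chunks.append(_segment_samples(
                    target, over, params.speed_px_s, dt_ms, jitter, rng,
                    include_start=False))
                chunks.append(_segment_samples(
                    over, target, params.speed_px_s, dt_ms, jitter, rng,
                    include_start=False))
                pos = target

    pts = np.concatenate([c for c in chunks if len(c)], axis=0)
    t = np.arange(len(pts)) * dt_ms
    return Trajectory(t, pts[:, 0], pts[:, 1], source="simulated")


def make_trajectory_source(params: VirtualUserParams):
    """Adapt a parameter set to the engine's trajectory-source callback."""

    def source(pattern: DotPattern, task_index: int,
               rng: np.random.Generator) -> Trajectory:
        return simulate_trajectory(params, pattern, task_index, rng)

    return source


def reference_bounds(
    config: SessionConfig | None = None,
    n_reference: int = 12,
    seed: int = 2024,
) -> dict[int, LevelBounds]:
    """Per-level trajectory bands from a simulated unimpaired cohort.

    Stands in for the pilot-cohort measurement that anchors the trajectory
    penalty. The synthetic cohort is heterogeneous — each of the
    ``n_reference`` members draws their own steadiness (jitter 2-10 px) and
    overshoot (2-15%), as age-matched human cohorts do — and each sketches
    every level once. The median sketched length is the reference length and
    the min/max ratios bound the unpenalized band.
    """
    from .geometry import generate_pattern_for_level
    from .scoring import estimate_bounds
    from .strategy import evaluate_sketch

    cfg = config or SessionConfig()
    rng = np.random.default_rng(seed)
    members = [
        VirtualUserParams(
            skill=1.0,
            jitter_sd_px=float(rng.uniform(2.0, 10.0)),
            speed_px_s=float(rng.uniform(350.0, 550.0)),
            overshoot_frac=float(rng.uniform(0.02, 0.15)),
            miss_prob=0.0,
        )
        for _ in range(n_reference)
    ]
    lengths: dict[int, list[float]] = {}
    for level in range(1, 7):
        pattern = generate_pattern_for_level(
            level, cfg.layout, cfg.handedness, cfg.spacing_px,
            cfg.dot_diameter_px)
        for member in members:
            traj = simulate_trajectory(member, pattern, 0, rng)
            _, length, _ = evaluate_sketch(traj, pattern)
            if length > 0:
                lengths.setdefault(level, []).append(length)
    return estimate_bounds(lengths)


def simulate_course(
    params: VirtualUserParams,
    n_sessions: int,
    config: SessionConfig | None = None,
    bounds: dict[int, LevelBounds] | None = None,
    seed: int | None = None,
) -> list[SessionRecord]:
    """Simulate a multi-session exercise course for one virtual patient.

    Session ``s`` (0-based) scales the error components of the movement —
    jitter s.d. (floored at a small minimum), wide-miss probability, and
    overshoot fraction — by ``(1 - learning_rate)**s``, emulating
    inter-session motor learning as a broad gain in movement accuracy rather
    than steadiness alone. Deterministic under ``seed``.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    cfg = config or SessionConfig()
    if bounds is None:
        bounds = reference_bounds(cfg)
    ss = np.random.SeedSequence(seed)
    session_seeds = ss.generate_state(n_sessions) % (2**31 - 1)
    records: list[SessionRecord] = []
    for s in range(n_sessions):
        decay = (1.0 - params.learning_rate) ** s
        p_s = replace(
            params,
            jitter_sd_px=max(params.jitter_sd_px * decay, MIN_JITTER_SD_PX),
            miss_prob=params.miss_prob * decay,
            overshoot_frac=params.overshoot_frac * decay,
        )
        rec = run_session(make_trajectory_source(p_s), bounds, cfg,
                          seed=int(session_seeds[s]))
        records.append(rec)
    return records
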