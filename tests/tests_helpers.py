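"""Deterministic trajectory builders shared across test modules."""

import numpy as np

from reachsketch.strategy import Trajectory


def ideal_trajectory(pattern, approach_px=80.0, step_px=10.0):
    """Straight sweep through all dot centers, preceded by an approach run-in
    longer than the dot radius so the first touch is a genuine arrival."""
    dots = np.asarray(pattern.dots)
    first_dir = dots[1] - dots[0]
    first_dir = first_dir / np.hypot(*first_dir)
    start = dots[0] - first_dir * approach_px
    waypoints = np.vstack([start, dots])
    pts = [waypoints[0]]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.hypot(*seg) / step_px)))
        for f in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + f * seg)
    pts = np.asarray(pts)
    t = np.arange(len(pts)) * 33.0
    return Trajectory(t, pts[:, 0], pts[:, 1])


def empty_trajectory():
    return Trajectory(np.array([]), np.array([]), np.array([]))


def ideal_source(pattern, task_index, rng):
    """Trajectory source producing a perfect sketch for every task."""
    return ideal_trajectory(pattern)
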