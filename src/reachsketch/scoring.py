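"""Per-task and per-session performance scoring.

A task score blends two metrics with equal weight:

* ``DOT_R`` — fraction of pattern dots the sketch touched, in order;
* a banded trajectory-length penalty — the sketched length is divided by a
  reference "optimal" length for that difficulty level (itself measured from
  an unimpaired reference cohort, and typically longer than the pattern's
  geometric length), and the resulting ratio is mapped to 1.0 inside the
  reference band, 0.5 inside a slack-widened band, and 0.0 outside it.

The per-task score is ``100 * (0.5*DOT_R + 0.5*case_value)``, classified
"adequate" at or above a configurable threshold (default 70%). The session
summary ``Perf_NORM`` is a weighted mean of per-level mean scores with
weights 1..6 by difficulty level, normalized over the levels attempted.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "LevelBounds",
    "TaskScore",
    "ScoringConfig",
    "InsufficientDataError",
    "dot_ratio",
    "trajectory_ratio",
    "penalty",
    "perf_score",
    "classify",
    "perf_norm",
    "estimate_bounds",
    "score_task",
    "DEFAULT_THRESHOLD_PCT",
    "DEFAULT_BAND_SLACK",
    "DEFAULT_WEIGHTS",
]

CaseLabel = Literal["case1", "case2", "case3"]
Adequacy = Literal["adequate", "inadequate"]

DEFAULT_THRESHOLD_PCT = 70.0
DEFAULT_BAND_SLACK = 0.2
DEFAULT_WEIGHTS: dict[int, float] = {i: float(i) for i in range(1, 7)}


class InsufficientDataError(ValueError):
    """Raised when too few observations exist to compute a statistic."""


@dataclass(frozen=True)
class LevelBounds:
    """Reference trajectory-length band for one difficulty level.

    ``traj_length_opt_px`` is the reference (cohort-derived) trajectory
    length; ``r_min``/``r_max`` bound the unpenalized ratio band.
    """

    difficulty_level: int
    traj_length_opt_px: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.traj_length_opt_px <= 0:
            raise ValueError("traj_length_opt_px must be positive")
        if not (0 < self.r_min <= self.r_max):
            raise ValueError(
                f"need 0 < r_min <= r_max, got ({self.r_min}, {self.r_max})")


@dataclass(frozen=True)
class TaskScore:
    dot_no: int
    dot_total: int
    dot_r: float
    traj_length_px: float
    traj_r: float
    case_label: CaseLabel
    case_specific_r: float
    perf_score: float
    adequacy: Adequacy


@dataclass(frozen=True)
class ScoringConfig:
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    band_slack: float = DEFAULT_BAND_SLACK
    weights: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        if not (0 < self.threshold_pct <= 100):
            raise ValueError("threshold_pct must be in (0, 100]")
        if self.band_slack < 0:
            raise ValueError("band_slack must be non-negative")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be strictly positive")


def dot_ratio(dot_no: int, dot_total: int) -> float:
    """Fraction of pattern dots touched: dot_no / dot_total."""
    if dot_total <= 0:
        raise ValueError("dot_total must be positive")
    if not (0 <= dot_no <= dot_total):
        raise ValueError(f"dot_no must be in [0, {dot_total}], got {dot_no}")
    return dot_no / dot_total


def trajectory_ratio(traj_length_px: float, bounds: LevelBounds) -> float:
    """Sketched trajectory length over the level's reference length."""
    if traj_length_px < 0:
        raise ValueError("trajectory length cannot be negative")
    return traj_length_px / bounds.traj_length_opt_px


def penalty(
    traj_r: float,
    bounds: LevelBounds,
    band_slack: float = DEFAULT_BAND_SLACK,
) -> tuple[CaseLabel, float]:
    """Three-case banded penalty on the trajectory ratio.

    Case 1 (no penalty): r_min < traj_r < r_max -> 1.0.
    Case 2 (limited penalty): (1-slack)*r_min < traj_r < (1+slack)*r_max -> 0.5.
    Case 3: anything else -> 0.0.

    Case 2's interval contains Case 1's, so Case 1 is tested first; all
    interval boundaries are strict.
    """
    if traj_r < 0:
        raise ValueError("traj_r cannot be negative")
    if bounds.r_min < traj_r < bounds.r_max:
        return ("case1", 1.0)
    if (1.0 - band_slack) * bounds.r_min < traj_r < (1.0 + band_slack) * bounds.r_max:
        return ("case2", 0.5)
    return ("case3", 0.0)


def perf_score(dot_r: float, case_specific_r: float) -> float:
    """Per-task performance score in percent: 100*(0.5*dot_r + 0.5*case_r)."""
    if not (0 <= dot_r <= 1):
        raise ValueError("dot_r must be in [0, 1]")
    return 100.0 * (0.5 * dot_r + 0.5 * case_specific_r)


def classify(score_pct: float, config: ScoringConfig | None = None) -> Adequacy:
    """Label a task adequate iff its score meets the threshold (inclusive)."""
    cfg = config or ScoringConfig()
    return "adequate" if score_pct >= cfg.threshold_pct else "inadequate"


def score_task(
    dot_no: int,
    dot_total: int,
    traj_length_px: float,
    bounds: LevelBounds,
    config: ScoringConfig | None = None,
) -> TaskScore:
    """Full per-task evaluation: ratios, penalty case, score, adequacy."""
    cfg = config or ScoringConfig()
    d_r = dot_ratio(dot_no, dot_total)
    t_r = trajectory_ratio(traj_length_px, bounds)
    label, case_r = penalty(t_r, bounds, cfg.band_slack)
    score = perf_score(d_r, case_r)
    return TaskScore(
        dot_no=dot_no,
        dot_total=dot_total,
        dot_r=d_r,
        traj_length_px=traj_length_px,
        traj_r=t_r,
        case_label=label,
        case_specific_r=case_r,
        perf_score=score,
        adequacy=classify(score, cfg),
    )


def perf_norm(
    level_scores: Mapping[int, Sequence[float]],
    config: ScoringConfig | None = None,
) -> float:
    """Weighted normalized session score over attempted difficulty levels.

    Each attempted level contributes the arithmetic mean of its per-task
    scores, weighted by the level's weight (default w_i = i); the sum is
    normalized by the total weight of the attempted levels only, so a
    session that never reaches the hardest level is not mechanically
    penalized for the levels it never saw.
    """
    cfg = config or ScoringConfig()
    attempted = {lvl: scores for lvl, scores in level_scores.items() if len(scores) > 0}
    if not attempted:
        raise ValueError("perf_norm requires at least one scored task")
    unknown = set(attempted) - set(cfg.weights)
    if unknown:
        raise ValueError(f"no weight configured for levels {sorted(unknown)}")
    num = sum(cfg.weights[lvl] * statistics.fmean(scores)
              for lvl, scores in attempted.items())
    den = sum(cfg.weights[lvl] for lvl in attempted)
    return num / den


def estimate_bounds(
    reference_lengths: Mapping[int, Iterable[float]],
    ideal_length_px: float | Mapping[int, float] | None = None,
) -> dict[int, LevelBounds]:
    """Estimate per-level reference bands from a cohort of sketched lengths.

    For each level: the reference length is the cohort median and the band is
    [min, max] of the cohort lengths expressed as ratios to that median.
    Reference lengths typically exceed the pattern's geometric length
    (``ideal_length_px``, if given) because even steady hands wander; this is
    expected but not enforced. Requires at least 3 observations per level.
    """
    out: dict[int, LevelBounds] = {}
    for level, lengths in reference_lengths.items():
        vals = sorted(float(v) for v in lengths)
        if len(vals) < 3:
            raise InsufficientDataError(
                f"level {level}: need >= 3 reference lengths, got {len(vals)}")
        if vals[0] <= 0:
            raise ValueError(f"level {level}: reference lengths must be positive")
        opt = statistics.median(vals)
        out[level] = LevelBounds(
            difficulty_level=level,
            traj_length_opt_px=opt,
            r_min=vals[0] / opt,
            r_max=vals[-1] / opt,
        )
    return out
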