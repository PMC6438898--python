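"""File formats, configuration, group comparisons, and session reports.

All text formats use one CSV dialect: comma separator, dot decimal, UTF-8,
mandatory header. Every writer's output is accepted bit-identically by its
reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    DEFAULT_DOT_DIAMETER_PX,
    DEFAULT_SPACING_PX,
    layout_monitor,
    pattern_to_json,
)
from .physio import EDATrace, TonicSummary
from .scoring import (
    DEFAULT_BAND_SLACK,
    DEFAULT_THRESHOLD_PCT,
    InsufficientDataError,
    LevelBounds,
    ScoringConfig,
)
from .strategy import (
    DEFAULT_SESSION_BUDGET_MS,
    DEFAULT_TASK_DURATION_MS,
    SessionConfig,
    SessionRecord,
    Trajectory,
)

__all__ = [
    "TrajectoryParseError",
    "ComparisonReport",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_eda_csv",
    "write_eda_csv",
    "read_bounds_csv",
    "write_bounds_csv",
    "session_to_json",
    "write_session_json",
    "read_session_perf",
    "write_tonic_summary_csv",
    "load_config",
    "session_config_from_mapping",
    "compare_exposures",
    "report_session",
]

TRAJECTORY_HEADER = "t_ms,x_px,y_px"
EDA_HEADER = "t_ms,eda_uS,marker"
BOUNDS_HEADER = "level,traj_length_opt_px,r_min,r_max"


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class ComparisonReport:
    test: Literal["friedman", "rank_sum", "signed_rank"]
    statistic: float
    p_value: float
    n: int
    paired: bool
    inputs: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


# ---------------------------------------------------------------- trajectories

def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    lines = [TRAJECTORY_HEADER]
    for t, x, y in zip(trajectory.t_ms, trajectory.x_px, trajectory.y_px):
        lines.append(f"{float(t)!r},{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read a ``t_ms,x_px,y_px`` file; strict header, monotone timestamps."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0].strip() != TRAJECTORY_HEADER:
        raise TrajectoryParseError(
            f"expected header {TRAJECTORY_HEADER!r}", line=1)
    rows: list[tuple[float, float, float]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 3:
            raise TrajectoryParseError(
                f"expected 3 fields, got {len(parts)}", line=lineno)
        try:
            t, x, y = (float(p) for p in parts)
        except ValueError as exc:
            raise TrajectoryParseError(str(exc), line=lineno) from None
        if rows and t <= rows[-1][0]:
            raise TrajectoryParseError(
                f"timestamp {t} not after previous {rows[-1][0]}", line=lineno)
        rows.append((t, x, y))
    if not rows:
        return Trajectory(np.array([]), np.array([]), np.array([]),
                          source="replayed")
    arr = np.asarray(rows)
    return Trajectory(arr[:, 0], arr[:, 1], arr[:, 2], source="replayed")


# ------------------------------------------------------------------------ EDA

def write_eda_csv(trace: EDATrace, path: str | Path) -> None:
    """Write ``t_ms,eda_uS,marker`` (marker column empty except at events)."""
    t = trace.t_ms
    marker_at: dict[int, str] = {}
    for m_ms, label in trace.markers:
        marker_at[trace._index(m_ms)] = label
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(EDA_HEADER + "\n")
        for i, (ti, vi) in enumerate(zip(t, trace.values)):
            fh.write(f"{float(ti)!r},{float(vi)!r},{marker_at.get(i, '')}\n")


def read_eda_csv(path: str | Path) -> EDATrace:
    df = pd.read_csv(path, dtype={"marker": "string"},
                     float_precision="round_trip")
    if list(df.columns) != EDA_HEADER.split(","):
        raise ValueError(f"expected header {EDA_HEADER!r}, got {list(df.columns)}")
    t = df["t_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("EDA trace needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("EDA trace must be uniformly sampled")
    fs = 1000.0 / dt[0]
    markers = [(float(t[i]), str(m)) for i, m in enumerate(df["marker"])
               if pd.notna(m) and str(m) != ""]
    return EDATrace(sample_rate_hz=fs,
                    values=df["eda_uS"].to_numpy(dtype=float),
                    markers=tuple(markers))


def write_tonic_summary_csv(summary: TonicSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------- bounds

def write_bounds_csv(bounds: Mapping[int, LevelBounds], path: str | Path) -> None:
    lines = [BOUNDS_HEADER]
    for level in sorted(bounds):
        b = bounds[level]
        lines.append(f"{level},{b.traj_length_opt_px!r},{b.r_min!r},{b.r_max!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_bounds_csv(path: str | Path) -> dict[int, LevelBounds]:
    df = pd.read_csv(path)
    if list(df.columns) != BOUNDS_HEADER.split(","):
        raise ValueError(f"expected header {BOUNDS_HEADER!r}")
    return {
        int(r.level): LevelBounds(int(r.level), float(r.traj_length_opt_px),
                                  float(r.r_min), float(r.r_max))
        for r in df.itertuples()
    }


# ------------------------------------------------------------------- sessions

def session_to_json(session: SessionRecord,
                    config: SessionConfig | None = None) -> str:
    """Serialize a session log, embedding the resolved config snapshot."""
    cfg = config or SessionConfig()
    snapshot = {
        "monitor.width": cfg.layout.width_px,
        "monitor.height": cfg.layout.height_px,
        "pattern.spacing_px": cfg.spacing_px,
        "pattern.dot_diameter_px": cfg.dot_diameter_px,
        "scoring.threshold_pct": cfg.scoring.threshold_pct,
        "scoring.band_slack": cfg.scoring.band_slack,
        "scoring.weights": [cfg.scoring.weights[i] for i in range(1, 7)],
        "strategy.max_task_duration_ms": cfg.max_task_duration_ms,
        "strategy.session_budget_ms": cfg.session_budget_ms,
        "handedness": cfg.handedness,
    }
    tasks = []
    for rec in session.tasks:
        tasks.append({
            "level": rec.difficulty_level,
            "pattern": json.loads(pattern_to_json(rec.pattern)),
            "dot_no": rec.score.dot_no,
            "traj_length_px": rec.score.traj_length_px,
            "traj_r": rec.score.traj_r,
            "case": rec.score.case_label,
            "perf_score": rec.score.perf_score,
            "adequacy": rec.score.adequacy,
            "duration_ms": rec.duration_ms,
            "completed": rec.completed,
            "touch_times_ms": list(rec.touch_times_ms),
        })
    doc = {
        "seed": session.seed,
        "config": snapshot,
        "tasks": tasks,
        "progression": [list(p) for p in session.progression],
        "perf_norm": session.perf_norm,
        "termination_reason": session.termination_reason,
        "aborted": session.aborted,
    }
    return json.dumps(doc, indent=2)


def write_session_json(session: SessionRecord, path: str | Path,
                       config: SessionConfig | None = None) -> None:
    Path(path).write_text(session_to_json(session, config), encoding="utf-8")


def read_session_perf(path: str | Path) -> dict:
    """Load the summary fields of a session log."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


# --------------------------------------------------------------------- config

KNOWN_CONFIG_KEYS = {
    "monitor.width", "monitor.height",
    "pattern.spacing_px", "pattern.dot_diameter_px",
    "calibration.span_px",
    "scoring.threshold_pct", "scoring.band_slack", "scoring.weights",
    "strategy.max_task_duration_ms", "strategy.session_budget_ms",
    "strategy.handedness",
    "seed",
}


def load_config(path: str | Path) -> dict[str, object]:
    """Parse a flat ``key = value`` config file; unknown keys are rejected.

    Values are numbers where they parse as such; ``scoring.weights`` is a
    comma-separated list of 6 floats.
    """
    out: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8")
                                 .splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in KNOWN_CONFIG_KEYS:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        if key == "scoring.weights":
            weights = [float(v) for v in value.split(",")]
            if len(weights) != 6:
                raise ValueError(f"line {lineno}: scoring.weights needs 6 values")
            out[key] = weights
        elif key == "strategy.handedness":
            out[key] = value
        else:
            try:
                num = float(value)
                out[key] = int(num) if num.is_integer() and "." not in value else num
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric value {value!r} "
                                 f"for {key!r}") from None
    return out


def session_config_from_mapping(cfg: Mapping[str, object]) -> SessionConfig:
    """Materialize a SessionConfig from parsed flat config keys."""
    width = int(cfg.get("monitor.width", 1600))
    height = int(cfg.get("monitor.height", 900))
    weights_list = cfg.get("scoring.weights")
    weights = ({i + 1: float(w) for i, w in enumerate(weights_list)}
               if weights_list else {i: float(i) for i in range(1, 7)})
    scoring = ScoringConfig(
        threshold_pct=float(cfg.get("scoring.threshold_pct",
                                    DEFAULT_THRESHOLD_PCT)),
        band_slack=float(cfg.get("scoring.band_slack", DEFAULT_BAND_SLACK)),
        weights=weights,
    )
    return SessionConfig(
        layout=layout_monitor(width, height),
        handedness=str(cfg.get("strategy.handedness", "right")),
        spacing_px=float(cfg.get("pattern.spacing_px", DEFAULT_SPACING_PX)),
        dot_diameter_px=float(cfg.get("pattern.dot_diameter_px",
                                      DEFAULT_DOT_DIAMETER_PX)),
        scoring=scoring,
        max_task_duration_ms=float(cfg.get("strategy.max_task_duration_ms",
                                           DEFAULT_TASK_DURATION_MS)),
        session_budget_ms=float(cfg.get("strategy.session_budget_ms",
                                        DEFAULT_SESSION_BUDGET_MS)),
    )


# ---------------------------------------------------------------- comparisons

def compare_exposures(
    records_first: Sequence[float],
    records_last: Sequence[float],
    paired: bool = True,
    extra_conditions: Sequence[Sequence[float]] = (),
    alternative: str = "two-sided",
) -> ComparisonReport:
    """Nonparametric comparison of per-subject session scores across exposures.

    Two paired samples use the Wilcoxon signed-rank test (zero differences
    dropped, Wilcoxon's convention; exact small-sample p where SciPy provides
    it); two independent samples use the rank-sum test; three or more
    conditions use the Friedman test. ``alternative`` follows SciPy's
    convention and applies to the two-sample tests ("less" means the first
    exposure scores lower). Requires n >= 5 per group.
    """
    a = np.asarray(records_first, dtype=float)
    b = np.asarray(records_last, dtype=float)
    groups = [a, b] + [np.asarray(g, dtype=float) for g in extra_conditions]
    if any(len(g) < 5 for g in groups):
        raise InsufficientDataError("each group needs n >= 5")
    if len(groups) > 2:
        if len({len(g) for g in groups}) != 1:
            raise ValueError("Friedman test requires equal-length conditions")
        stat, p = stats.friedmanchisquare(*groups)
        return ComparisonReport("friedman", float(stat), float(p),
                                n=len(a), paired=True,
                                inputs=f"{len(groups)} conditions x n={len(a)}")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length samples")
        diffs = b - a
        if np.all(diffs == 0):
            # every pair tied: no evidence of a shift
            return ComparisonReport("signed_rank", 0.0, 1.0, n=len(a),
                                    paired=True, inputs="all differences zero")
        res = stats.wilcoxon(a, b, zero_method="wilcox", mode="auto",
                             alternative=alternative)
        return ComparisonReport("signed_rank", float(res.statistic),
                                float(res.pvalue), n=len(a), paired=True,
                                inputs=f"paired n={len(a)}")
    res = stats.ranksums(a, b, alternative=alternative)
    return ComparisonReport("rank_sum", float(res.statistic),
                            float(res.pvalue), n=len(a) + len(b), paired=False,
                            inputs=f"independent n={len(a)}+{len(b)}")


# -------------------------------------------------------------------- reports

def report_session(session: SessionRecord,
                   tonic: TonicSummary | None = None) -> tuple[str, dict]:
    """Human-readable and JSON report of one session.

    Shows per-level mean scores, the level progression path, the weighted
    normalized session score, and (when available) the per-level mean
    baseline-referenced tonic table.
    """
    level_scores: dict[int, list[float]] = {}
    for rec in session.tasks:
        level_scores.setdefault(rec.difficulty_level, []).append(
            rec.score.perf_score)
    per_level = {lvl: float(np.mean(v)) for lvl, v in sorted(level_scores.items())}

    doc: dict = {
        "per_level_mean_perf_score": per_level,
        "progression": [list(p) for p in session.progression],
        "perf_norm": session.perf_norm,
        "termination_reason": session.termination_reason,
        "n_tasks": len(session.tasks),
    }
    lines = ["Session report", "=" * 14]
    lines.append(f"tasks: {len(session.tasks)}  "
                 f"termination: {session.termination_reason}")
    lines.append("level  n_tasks  mean Perf_SCORE")
    for lvl, mean in per_level.items():
        lines.append(f"  {lvl:>3}  {len(level_scores[lvl]):>7}  {mean:>14.1f}")
    lines.append("progression: " +
                 " -> ".join(str(lvl) for _, lvl in session.progression))
    lines.append(f"Perf_NORM: {session.perf_norm:.1f}")

    if tonic is not None:
        per_level_delta: dict[int, list[float]] = {}
        for level, _idx, _tm, delta in tonic.per_task:
            per_level_delta.setdefault(level, []).append(delta)
        delta_table = {lvl: float(np.mean(v))
                       for lvl, v in sorted(per_level_delta.items())}
        doc["tonic_baseline_uS"] = tonic.tonic_baseline_uS
        doc["per_level_mean_delta_tonic_uS"] = delta_table
        lines.append(f"baseline tonic: {tonic.tonic_baseline_uS:.3f} uS")
        lines.append("level  mean dTonic (uS)")
        for lvl, d in delta_table.items():
            lines.append(f"  {lvl:>3}  {d:>+16.3f}")

    return ("\n".join(lines), doc)
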