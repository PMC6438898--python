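"""Event-marked electrodermal-activity (EDA) handling.

Skin conductance (microsiemens) is recorded continuously during an exercise
session, with in-band event markers delimiting a resting baseline and each
task. Per task the slow-varying (tonic) component is extracted — here with a
4 s moving-median filter, a standard robust tonic estimator that suppresses
the fast phasic skin-conductance responses — and summarized as its mean.
Day-to-day baseline drift is removed by reporting the task tonic mean minus
the same-session baseline tonic mean (delta tonic), so values are comparable
across sessions; a decline in delta tonic across exposures reads as reduced
task-related arousal.

A synthetic generator couples tonic arousal to simulated task challenge
(difficulty level) and achieved score, and inserts phasic responses at
dot-touch events, giving every analysis path a testable input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .strategy import SessionRecord

__all__ = [
    "EDATrace",
    "TonicSummary",
    "MarkerStructureError",
    "InsufficientSegmentError",
    "segment_by_markers",
    "tonic_mean",
    "delta_tonic",
    "summarize_session",
    "simulate_eda",
    "DEFAULT_SAMPLE_RATE_HZ",
    "DEFAULT_BASELINE_S",
    "TONIC_MEDIAN_WINDOW_S",
]

DEFAULT_SAMPLE_RATE_HZ = 1000.0
DEFAULT_BASELINE_S = 180.0
TONIC_MEDIAN_WINDOW_S = 4.0
MIN_SEGMENT_S = 10.0

# conventional phasic skin-conductance-response shape
SCR_RISE_S = 0.7
SCR_DECAY_S = 3.0


class MarkerStructureError(ValueError):
    """Raised on unmatched or out-of-order event markers."""


class InsufficientSegmentError(ValueError):
    """Raised when a segment is too short for a stable tonic estimate."""


@dataclass(frozen=True)
class EDATrace:
    """Uniformly sampled conductance with task-event markers.

    Markers are ``(t_ms, label)`` pairs; labels are ``baseline_start``,
    ``baseline_end`` and ``task_start:<level>:<index>`` /
    ``task_end:<level>:<index>`` tokens.
    """

    sample_rate_hz: float
    values: np.ndarray
    markers: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        times = [t for t, _ in self.markers]
        if times != sorted(times):
            raise MarkerStructureError("markers must be time-ordered")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * (1000.0 / self.sample_rate_hz)

    def _index(self, t_ms: float) -> int:
        return int(round(t_ms * self.sample_rate_hz / 1000.0))


@dataclass(frozen=True)
class TonicSummary:
    tonic_baseline_uS: float
    per_task: tuple[tuple[int, int, float, float], ...]
    """(level, task index, tonic mean in uS, delta from baseline in uS)."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.per_task),
            columns=["level", "task_index", "tonic_mean_uS", "delta_uS"])


def _parse_task_label(label: str) -> tuple[str, int, int] | None:
    parts = label.split(":")
    if parts[0] in ("task_start", "task_end") and len(parts) == 3:
        return (parts[0], int(parts[1]), int(parts[2]))
    return None


def segment_by_markers(
    trace: EDATrace,
) -> tuple[np.ndarray, list[tuple[int, int, np.ndarray]]]:
    """Split a trace into its baseline window and per-task windows.

    Returns ``(baseline_samples, [(level, index, task_samples), ...])``.
    Samples between tasks (rest gaps) are excluded. Raises
    :class:`MarkerStructureError` on unmatched or inverted marker pairs.
    """
    baseline_start = baseline_end = None
    open_task: tuple[int, int, float] | None = None
    tasks: list[tuple[int, int, np.ndarray]] = []
    for t_ms, label in trace.markers:
        if label == "baseline_start":
            if baseline_start is not None:
                raise MarkerStructureError("duplicate baseline_start")
            baseline_start = t_ms
        elif label == "baseline_end":
            if baseline_start is None or baseline_end is not None:
                raise MarkerStructureError("baseline_end without baseline_start")
            baseline_end = t_ms
        else:
            parsed = _parse_task_label(label)
            if parsed is None:
                raise MarkerStructureError(f"unknown marker label {label!r}")
            kind, level, index = parsed
            if kind == "task_start":
                if open_task is not None:
                    raise MarkerStructureError(
                        f"task_start:{level}:{index} before previous task ended")
                open_task = (level, index, t_ms)
            else:
                if open_task is None or open_task[:2] != (level, index):
                    raise MarkerStructureError(
                        f"task_end:{level}:{index} does not match an open task")
                i0 = trace._index(open_task[2])
                i1 = trace._index(t_ms)
                if i1 <= i0:
                    raise MarkerStructureError(
                        f"task {level}:{index} has non-positive span")
                tasks.append((level, index, trace.values[i0:i1]))
                open_task = None
    if open_task is not None:
        raise MarkerStructureError(
            f"task_start:{open_task[0]}:{open_task[1]} never ended")
    if baseline_start is None or baseline_end is None:
        raise MarkerStructureError("trace must contain a baseline marker pair")
    b0, b1 = trace._index(baseline_start), trace._index(baseline_end)
    if b1 <= b0:
        raise MarkerStructureError("baseline window has non-positive span")
    return trace.values[b0:b1], tasks


def tonic_mean(
    segment: Sequence[float] | np.ndarray,
    sample_rate_hz: float,
    median_window_s: float = TONIC_MEDIAN_WINDOW_S,
) -> float:
    """Mean of the tonic component of one conductance segment.

    The tonic component is a centered moving-median with a ``median_window_s``
    window (default 4 s), which flattens phasic responses of a few seconds or
    less. Segments shorter than 10 s are rejected as too unstable.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < MIN_SEGMENT_S * sample_rate_hz:
        raise InsufficientSegmentError(
            f"segment of {x.size / sample_rate_hz:.1f} s is shorter than the "
            f"{MIN_SEGMENT_S:.0f} s minimum")
    win = max(1, int(round(median_window_s * sample_rate_hz)))
    tonic = (pd.Series(x)
             .rolling(window=win, center=True, min_periods=1)
             .median()
             .to_numpy())
    return float(tonic.mean())


def delta_tonic(task_tonic_uS: float, baseline_tonic_uS: float) -> float:
    """Baseline-referenced tonic mean: task minus same-session baseline."""
    if not (np.isfinite(task_tonic_uS) and np.isfinite(baseline_tonic_uS)):
        raise ValueError("tonic means must be finite")
    return float(task_tonic_uS - baseline_tonic_uS)


def summarize_session(trace: EDATrace) -> TonicSummary:
    """Per-task baseline-referenced tonic summary of one marked trace."""
    baseline, tasks = segment_by_markers(trace)
    base = tonic_mean(baseline, trace.sample_rate_hz)
    rows = []
    for level, index, seg in tasks:
        tm = tonic_mean(seg, trace.sample_rate_hz)
        rows.append((level, index, tm, delta_tonic(tm, base)))
    return TonicSummary(tonic_baseline_uS=base, per_task=tuple(rows))


def _scr_pulse(n: int, sample_rate_hz: float, amplitude_uS: float) -> np.ndarray:
    """Phasic response: linear rise over 0.7 s, exponential decay (tau 3 s)."""
    t = np.arange(n) / sample_rate_hz
    rise = np.clip(t / SCR_RISE_S, 0.0, 1.0)
    decay = np.where(t > SCR_RISE_S,
                     np.exp(-(t - SCR_RISE_S) / SCR_DECAY_S), 1.0)
    return amplitude_uS * rise * decay


def simulate_eda(
    session: SessionRecord,
    arousal_gain_uS: float = 1.0,
    skill_link: float = 0.0,
    noise_sd_uS: float = 0.01,
    seed: int | None = None,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    baseline_s: float = DEFAULT_BASELINE_S,
    baseline_level_uS: float = 5.0,
    drift_uS_per_min: float = 0.02,
    scr_amplitude_uS: float = 0.15,
    inter_task_gap_s: float = 5.0,
    min_task_s: float = 12.0,
) -> EDATrace:
    """Synthesize a marked EDA trace for a simulated session.

    The tonic level rests at ``baseline_level_uS`` plus a slow linear drift.
    During each task it is elevated by
    ``arousal_gain_uS * (level/6) * (1 - skill_link * perf_score/100)`` —
    higher difficulty raises arousal, and (when ``skill_link > 0``) better
    performance damps it, the coupling that lets courses with rising scores
    show declining task arousal. Phasic responses fire at dot-touch times.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    segments: list[np.ndarray] = []
    markers: list[tuple[float, str]] = []
    cursor_ms = 0.0

    def emit(n: int) -> np.ndarray:
        seg = np.zeros(n)
        segments.append(seg)
        return seg

    # baseline window
    n_base = int(round(baseline_s * fs))
    markers.append((cursor_ms, "baseline_start"))
    emit(n_base)
    cursor_ms += n_base * 1000.0 / fs
    markers.append((cursor_ms, "baseline_end"))

    for idx, rec in enumerate(session.tasks):
        # rest gap before each task
        n_gap = int(round(inter_task_gap_s * fs))
        emit(n_gap)
        cursor_ms += n_gap * 1000.0 / fs

        dur_s = max(rec.duration_ms / 1000.0, min_task_s)
        n_task = int(round(dur_s * fs))
        markers.append((cursor_ms, f"task_start:{rec.difficulty_level}:{idx}"))
        elevation = (arousal_gain_uS * (rec.difficulty_level / 6.0)
                     * (1.0 - skill_link * rec.score.perf_score / 100.0))
        seg = emit(n_task)
        seg += elevation
        for touch_ms in rec.touch_times_ms:
            i0 = int(round(touch_ms / 1000.0 * fs))
            if i0 >= n_task:
                continue
            pulse = _scr_pulse(min(n_task - i0, int(8 * fs)), fs,
                               scr_amplitude_uS)
            seg[i0:i0 + pulse.size] += pulse
        cursor_ms += n_task * 1000.0 / fs
        markers.append((cursor_ms, f"task_end:{rec.difficulty_level}:{idx}"))

    # one closing sample so the final end marker lands on a real sample row
    segments.append(np.zeros(1))
    values = np.concatenate(segments)
    t_min = np.arange(values.size) / fs / 60.0
    values = values + baseline_level_uS + drift_uS_per_min * t_min
    if noise_sd_uS > 0:
        values = values + rng.normal(0.0, noise_sd_uS, size=values.size)
    return EDATrace(sample_rate_hz=fs, values=values, markers=tuple(markers))
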