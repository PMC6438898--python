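# Methods

This note documents the models implemented in `reachsketch`, the defaults
and why they were chosen, the construction of the synthetic data sources,
and the numerical conventions used throughout.

## Coordinate and layout conventions

All geometry lives in screen pixels with the origin at the top-left corner
and y increasing downward; dot centers are floating-point. The working zone
is the top two thirds of the monitor (TOP:BOTTOM = 2:1) tiled into four
equal sub-zones; the bottom third never hosts patterns. Patterns are
centered in the bounding rectangle of their sub-zone. Left-hand patterns are
generated by building the right-hand pattern in the east-side zone and
reflecting it about the vertical midline; because the tiling is symmetric,
the reflected pattern is exactly centered in the west-side zone, and the
mirroring invariant (per-dot equality after reflection) holds to machine
precision rather than within a tolerance.

Dot centers are kept as floats rather than rounded to integer pixels: the
triangular pattern's horizontal step is 107·cos 60° = 53.5 px, and rounding
each coordinate independently can perturb consecutive-dot spacing beyond
the ±0.5 px contract. A renderer is free to round for display.

### Pattern shapes

* *straight* — seven collinear horizontal dots.
* *triangular* — segments alternate at +60°/−60° to the horizontal (apex-up
  first), i.e. a six-segment zig-zag whose vertices are the dots.
* *square wave* — segments alternate vertical/horizontal (up, right, down,
  right, up, right), so every consecutive segment pair is perpendicular.

"Angular separation" θ is the absolute angle of a segment to the horizontal
(0°, 60°, 90° for the three shapes). Spacing (107 px), dot diameter (40 px)
and the calibration span (700 px) are configuration defaults, overridable
per run; they are typical values, not constraints of the method.

### Calibration

The angle-to-pixel map is affine and individualized: whatever a user's
personal adduction range (center-hold azimuth to periphery-hold azimuth),
it maps onto the full `span_px` horizontal pixels. Ranges of 5° or less are
rejected as degenerate — below that, sensor noise in a phone-based
orientation reading dominates the map's slope. Elevation is abstracted to a
normalized 0–1 input mapped linearly onto the working zone's vertical
extent; which zone a user can actually reach is a property of the
(virtual) user, not of the geometry.

## Sketch evaluation

Dots are credited strictly in pattern order. The next expected dot is
credited at the earliest moment the *interpolated* path — the segment
between consecutive samples, not just the samples — enters the dot's radius
(20 px default). Interpolation closes the tunnelling hole: at 30 Hz a
500 px/s sweep moves ~17 px between samples and could otherwise jump over
a dot. The entry parameter is found by solving the segment–circle
intersection quadratic; a single segment may credit several dots in order.
Out-of-order touches are ignored entirely: touching dot 3 while dot 2 is
still pending credits nothing, which mirrors a display that only connects
consecutive dots.

The sketched trajectory length is the arc length along the sampled path
between the first and the last credited touch point; it is 0 when fewer
than two dots are credited. Measuring from first touch (rather than from
the first sample) scores the sketch, not the approach to the pattern. A
useful exactness property falls out: the entry point is always one dot
radius of arc before the aimed center, so for a straight sweep the offsets
at the first and last dot cancel and an ideal sketch measures exactly
6 × spacing.

## Scoring

Per-task score: `100·(0.5·DOT_R + 0.5·case_value)`, never rounded
internally. The trajectory ratio `Traj_R = length / reference length` is
mapped through three cases — 1.0 inside the reference band
(r_min, r_max), 0.5 inside the slack-widened band
((1−slack)·r_min, (1+slack)·r_max) with slack defaulting to 0.2, 0.0
otherwise. Two conventions worth making explicit:

* **Case precedence.** The slack band strictly contains the nominal band,
  so the nominal band is tested first; otherwise the full-credit case would
  be unreachable.
* **Strict boundaries.** All four interval endpoints are open. Landing
  exactly on a boundary is a measure-zero event for continuous lengths; it
  resolves to the wider (lower-credit) case.

Adequacy uses an inclusive threshold: a score of exactly 70.0% is Adequate.
The comparison is made on the unrounded score.

The session score `Perf_NORM` weights each attempted level's mean task
score by w_i = i and normalizes by the total weight *of the attempted
levels only*. Restricting the denominator matters: normalizing by Σ(1…6)
would mechanically push any session that never reaches the top level far
below its own per-task scores. Weights are configurable; the score is
invariant to uniform weight scaling.

### Reference bands

The reference ("optimal") trajectory length and the (r_min, r_max) band
per level come from an unimpaired reference cohort: reference length =
cohort median, band = cohort min/max expressed as ratios to the median.
`reference_bounds()` simulates that cohort with the package's own virtual
user: 12 members, each with their own steadiness (jitter s.d. drawn from
2–10 px) and overshoot habit (2–15%), each sketching every level once.
The heterogeneity is deliberate — a cohort built from a single parameter
set produces a band a few percent wide, which no human cohort would, and
which would penalize nearly every non-member sketch. Cohort medians come
out near 800 px per level, comfortably above the 642 px geometric length,
as expected when even steady hands wander. Reference length ≥ geometric
length is expected but not enforced by the estimator.

## Adaptive strategy

The difficulty state machine has three modes: *increase difficulty*
(after an Adequate task below level 6), *same difficulty* (after an
Inadequate task — the level never decreases; the design trains skill
rather than regressing), and *terminal* (Adequate at level 6, absorbing).
A session ends at terminal or when the time budget (default 20 min) is
exhausted.

Timing conventions: a task that credits all seven dots ends at the moment
of the last credited touch; an incomplete task consumes the full per-task
allowance T (default 60 s — the platform would wait out the clock before
offering the next task). The incomplete-task rule is also what guarantees
termination: a source of empty trajectories consumes T per attempt and
exhausts the budget. Trajectories are truncated at T before evaluation.

## The virtual patient

`simulate_trajectory` produces piecewise goal-directed motion, dot to dot,
at constant speed sampled at 30 Hz (a typical skeletal-camera frame rate;
configurable). Error enters as:

* **jitter** — per-sample Gaussian displacement perpendicular to the
  intended direction, s.d. `jitter_sd_px`;
* **overshoot** — at each dot except the last, the path continues past the
  dot along its incoming heading by `overshoot_frac × spacing` and then
  corrects, the classic signature of poorly damped reaching;
* **wide misses** — with probability `miss_prob` per dot, the path bypasses
  the dot at 2.5 radii plus the current jitter; combined with ordered
  crediting, one wide miss caps the dot count for the task;
* **aim corruption** — with probability `1 − skill`, the landing point
  inherits the current jitter s.d. instead of hitting the center exactly.
  Tying the corruption scale to the jitter (not to the dot radius) keeps
  the noise-free limit exact: with zero jitter, overshoot and miss
  probability, the path passes through all seven centers and measures the
  ideal polyline length regardless of `skill`;
* **fatigue** — jitter s.d. grows by (1 + `fatigue_rate`) per task within a
  session;
* **reach ceiling** — patterns above `max_reach_level` (the elevated zones
  a contracted arm cannot reach) yield a short low-amplitude drift below
  the pattern that touches nothing.

`simulate_course` emulates multi-session exercise: session *s* scales
jitter s.d. (floored at 0.1 px), miss probability and overshoot fraction
by (1 − `learning_rate`)^s. Learning is modeled as a broad gain in
movement accuracy rather than steadiness alone; with jitter-only decay the
session score barely responds, because scores of impaired users are
dominated by misses (which truncate the ordered dot count) and overshoot
(which inflates the trajectory ratio), and a learning effect that real
courses display would be undetectable in the simulator's own output.

Presets: `healthy` (jitter 3 px, no misses, full reach), `impaired_mild`
(jitter 12 px, 8% miss, reach ceiling DLIV, learning 0.3), and
`impaired_severe` (jitter 25 px, 25% miss, reach ceiling DLII). These are
qualitative archetypes chosen to span the engine's behavior — first-task
adequacy at every level for the healthy preset; budget-limited sessions
concentrated at low levels for the impaired ones.

**What the simulator does and does not show.** It reproduces the
qualitative orderings the engine is validated against: more jitter never
raises the mean score; positive learning rates produce rising session
scores whose sign a trend fit recovers; the healthy archetype passes every
level immediately. It is a screen-space noise model with no biomechanics —
no joint kinematics, no speed–accuracy tradeoff, no tremor spectrum — so
passing tests say the *engine* handles impaired-like input correctly, not
that any preset is clinically representative.

## EDA analysis

Traces are uniformly sampled conductance (µS; 1 kHz default) with in-band
event markers (`baseline_start/end`, `task_start/end:<level>:<index>`)
replacing a hardware trigger channel. Segmentation returns the baseline
window and per-task windows; inter-task gaps are excluded; unmatched or
inverted markers are structural errors.

The tonic component is a centered 4 s moving-median — a standard robust
tonic estimator that flattens phasic skin-conductance responses, which
rise in under a second and decay in a few seconds. The per-segment summary
is the mean of the tonic component; segments under 10 s are rejected as
unstable. ΔTonic = task tonic mean − same-session baseline tonic mean
(default baseline window 3 min), which removes common offsets exactly and
thereby day-to-day baseline drift. The decomposition method is a
deliberate, swappable choice; any tonic estimator that passes the
filter-invariance checks (constant in → constant out; 1 s bump suppressed)
can replace it.

The synthetic EDA generator writes: a constant baseline level (5 µS) with
slow linear drift (0.02 µS/min); a per-task tonic elevation
`arousal_gain · (level/6) · (1 − skill_link · score/100)` — difficulty
raises arousal, and good performance damps it when `skill_link > 0`, the
coupling that makes improving courses show declining task arousal; phasic
pulses (0.7 s linear rise, 3 s exponential decay, 0.15 µS default) at each
dot-touch time; and white Gaussian noise. Quick tasks are padded to a 12 s
marker span (display, sketch and score-presentation time all sit inside
the real marker pair). All generation is deterministic under a seed.

## Statistics

Exposure comparisons use the field's standard nonparametric tests via
SciPy: Wilcoxon signed-rank for paired samples (zero differences dropped,
Wilcoxon's convention; exact small-sample null where available), rank-sum
for independent samples, Friedman for three or more related conditions.
Identical paired lists short-circuit to statistic 0, p = 1 (no evidence of
a shift) rather than erroring on all-zero differences. Groups below n = 5
are rejected. Under a simulated null the paired test's type-I error at
α = 0.05 sits within [0.03, 0.07] (discreteness of the exact null keeps it
slightly conservative).

## Numerical and interface choices

* One CSV dialect everywhere: comma, dot decimal, UTF-8, mandatory header.
  Floats are written with `repr` and read back with pandas'
  round-trip parser, so writer→reader is bit-exact.
* Config is flat `key = value` text; unknown keys are rejected to catch
  typos; every session log embeds the resolved config snapshot.
* All randomness flows through `numpy.random.Generator`; course seeds are
  spawned from a `SeedSequence`, and identical seeds give byte-identical
  session logs.
* CLI exit codes: 0 success, 2 usage error, 3 data error.

## Problem sizes used in validation

The validation suites run at desk scale: penalty-oracle agreement over
10⁴ random triples; state-machine properties over 10³ random adequacy
sequences; stochastic ordering over a 3-point jitter grid × 100 seeds;
learning-sign recovery over 100 five-session courses per rate (five
sessions because 2–3-session courses leave the trend fit noise-dominated);
tonic recovery and arousal-direction checks on 100 Hz and 50 Hz synthetic
traces (the analysis is sample-rate-agnostic; 1 kHz is the acquisition
default, not an analysis requirement); signed-rank calibration over 10³
null draws at n = 10.

## Known limitations

* The virtual patient is a screen-space noise model; see above.
* The reference band estimator (median/min/max) is sensitive to cohort
  extremes by construction; a quantile-based band would be less fragile
  but is not what the scoring scheme specifies.
* The strict-open penalty boundaries make boundary hits resolve to the
  lower-credit case; with measured lengths this is immaterial.
* ΔTonic as implemented assumes one baseline per session; split-baseline
  protocols would need additional marker vocabulary.
* No rendering, audio, or live capture: the engine consumes and produces
  data only.
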