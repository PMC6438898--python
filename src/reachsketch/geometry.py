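"""Screen layout, dot-pattern generation, and physical-to-screen calibration.

Coordinate convention (used everywhere in this package): pixel origin at the
top-left corner of the monitor, x increases rightward, y increases downward.
Dot centers are floating-point pixel coordinates.

The exercise screen is split into a working zone (top two thirds of the
monitor, zone ratio TOP:BOTTOM = 2:1) that is further tiled into four
sub-zones: NE and NW in its upper half, E and W in its lower half, with
E/NE on the right. Reaching a pattern in E/W requires roughly horizontal arm
flexion; NE/NW requires an elevated arm, which is what makes levels IV-VI
harder than I-III.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

__all__ = [
    "Rect",
    "MonitorLayout",
    "DotPattern",
    "CalibrationProfile",
    "PatternOverflowError",
    "CalibrationError",
    "DEFAULT_SPACING_PX",
    "DEFAULT_DOT_DIAMETER_PX",
    "DEFAULT_SPAN_PX",
    "N_DOTS",
    "LEVEL_PATTERN_TYPE",
    "LEVEL_ZONE_BAND",
    "layout_monitor",
    "generate_pattern",
    "calibrate_mapping",
    "map_hand_point",
    "pattern_to_json",
    "pattern_from_json",
]

PatternType = Literal["straight", "triangular", "square_wave"]
Handedness = Literal["left", "right"]
ZoneId = Literal["NE", "E", "NW", "W", "BOTTOM"]

N_DOTS = 7
DEFAULT_SPACING_PX = 107.0
DEFAULT_DOT_DIAMETER_PX = 40.0
DEFAULT_SPAN_PX = 700.0

#: pattern shape per difficulty level (I/IV straight, II/V triangular,
#: III/VI square wave)
LEVEL_PATTERN_TYPE: dict[int, PatternType] = {
    1: "straight", 2: "triangular", 3: "square_wave",
    4: "straight", 5: "triangular", 6: "square_wave",
}

#: which vertical band of the working zone a level occupies: levels 1-3 sit
#: in the middle band (E/W), levels 4-6 in the top band (NE/NW)
LEVEL_ZONE_BAND: dict[int, tuple[str, str]] = {
    1: ("E", "W"), 2: ("E", "W"), 3: ("E", "W"),
    4: ("NE", "NW"), 5: ("NE", "NW"), 6: ("NE", "NW"),
}

#: segment angle from horizontal for the zig-zag (triangular) pattern
TRIANGULAR_THETA_DEG = 60.0


class PatternOverflowError(ValueError):
    """Raised when a pattern does not fit in its zone at the requested spacing."""


class CalibrationError(ValueError):
    """Raised when the calibration angle range is degenerate."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains_point(self, x: float, y: float, margin: float = 0.0) -> bool:
        return (self.x0 + margin <= x <= self.x1 - margin
                and self.y0 + margin <= y <= self.y1 - margin)


@dataclass(frozen=True)
class MonitorLayout:
    width_px: int
    height_px: int
    zone_rects: dict[str, Rect] = field(repr=False)

    @property
    def zone_top_height(self) -> float:
        """Height of the working zone (top 2/3 of the monitor)."""
        return self.height_px * 2.0 / 3.0


@dataclass(frozen=True)
class DotPattern:
    pattern_type: PatternType
    zone: str
    dots: tuple[tuple[float, float], ...]
    dot_diameter_px: float
    spacing_px: float
    theta_deg: float
    difficulty_level: int
    handedness: Handedness

    @property
    def dot_radius_px(self) -> float:
        return self.dot_diameter_px / 2.0

    @property
    def ideal_length_px(self) -> float:
        """Polyline length of the pattern itself: 6 segments x spacing."""
        return (N_DOTS - 1) * self.spacing_px


@dataclass(frozen=True)
class CalibrationProfile:
    """Affine map from shoulder azimuth (degrees) to screen x (pixels).

    The full personal adduction range (center to periphery posture) always
    maps onto ``span_px`` horizontal pixels, whatever the individual's angular
    range, which is what makes the calibration individualized.
    """

    center_angle_deg: float
    periphery_angle_deg: float
    span_px: float
    center_x_px: float
    direction: Handedness

    def map_angle(self, azimuth_deg: float) -> float:
        """Screen x for a given azimuth; unclamped."""
        frac = ((azimuth_deg - self.center_angle_deg)
                / (self.periphery_angle_deg - self.center_angle_deg))
        sign = 1.0 if self.direction == "right" else -1.0
        return self.center_x_px + sign * self.span_px * frac

    def inverse_map(self, x_px: float) -> float:
        """Azimuth whose image is ``x_px`` (inverse of :meth:`map_angle`)."""
        sign = 1.0 if self.direction == "right" else -1.0
        frac = (x_px - self.center_x_px) / (sign * self.span_px)
        return self.center_angle_deg + frac * (
            self.periphery_angle_deg - self.center_angle_deg)


def layout_monitor(width_px: int, height_px: int) -> MonitorLayout:
    """Partition a monitor into the five exercise zones.

    The top 2/3 of the screen is the working zone, tiled into four
    equal-size sub-zones (NE/NW above, E/W below; E/NE on the right); the
    bottom third is unused by patterns.

    Raises ``ValueError`` for non-positive or too-small dimensions
    (minimum 800 x 450).
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("monitor dimensions must be positive")
    if width_px < 800 or height_px < 450:
        raise ValueError(
            f"monitor too small: {width_px}x{height_px}, need at least 800x450")

    top_h = height_px * 2.0 / 3.0
    half_h = top_h / 2.0
    mid_x = width_px / 2.0
    zones = {
        "NW": Rect(0.0, 0.0, mid_x, half_h),
        "NE": Rect(mid_x, 0.0, float(width_px), half_h),
        "W": Rect(0.0, half_h, mid_x, top_h),
        "E": Rect(mid_x, half_h, float(width_px), top_h),
        "BOTTOM": Rect(0.0, top_h, float(width_px), float(height_px)),
    }
    return MonitorLayout(width_px=width_px, height_px=height_px, zone_rects=zones)


def _raw_polyline(pattern_type: PatternType, spacing: float) -> list[tuple[float, float]]:
    """Seven dot centers for a right-handed pattern anchored at (0, 0).

    Built left-to-right in screen coordinates (y down). The triangular
    pattern alternates segments at -60 and +60 degrees from horizontal
    (apex up first); the square wave alternates horizontal and vertical
    segments (up first), so consecutive segments are perpendicular.
    """
    pts = [(0.0, 0.0)]
    if pattern_type == "straight":
        for k in range(1, N_DOTS):
            pts.append((k * spacing, 0.0))
    elif pattern_type == "triangular":
        theta = math.radians(TRIANGULAR_THETA_DEG)
        dx = spacing * math.cos(theta)
        dy = spacing * math.sin(theta)
        for k in range(1, N_DOTS):
            x, y = pts[-1]
            # odd segments go up (negative y), even come back down
            pts.append((x + dx, y - dy if k % 2 == 1 else y + dy))
    elif pattern_type == "square_wave":
        # segment sequence: up, right, down, right, up, right
        for k in range(1, N_DOTS):
            x, y = pts[-1]
            if k % 2 == 1:
                pts.append((x, y - spacing if k % 4 == 1 else y + spacing))
            else:
                pts.append((x + spacing, y))
    else:
        raise ValueError(f"unknown pattern type: {pattern_type!r}")
    return pts


def generate_pattern(
    pattern_type: PatternType,
    difficulty_level: int,
    layout: MonitorLayout,
    handedness: Handedness = "right",
    spacing_px: float = DEFAULT_SPACING_PX,
    dot_diameter_px: float = DEFAULT_DOT_DIAMETER_PX,
) -> DotPattern:
    """Generate the seven-dot target pattern for one task.

    The level fixes both the shape and the zone band (I/IV straight,
    II/V triangular, III/VI square wave; I-III in the middle band, IV-VI in
    the top band); the zone side follows the sketching hand (right hand uses
    E/NE). The pattern is centered in its zone rectangle; a left-hand pattern
    is the exact mirror image of the right-hand one about the monitor's
    vertical midline.
    """
    if difficulty_level not in LEVEL_PATTERN_TYPE:
        raise ValueError(f"difficulty level must be 1-6, got {difficulty_level}")
    expected_type = LEVEL_PATTERN_TYPE[difficulty_level]
    if pattern_type != expected_type:
        raise ValueError(
            f"difficulty level {difficulty_level} requires pattern type "
            f"{expected_type!r}, got {pattern_type!r}")
    if handedness not in ("left", "right"):
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    if spacing_px <= 0 or dot_diameter_px <= 0:
        raise ValueError("spacing and dot diameter must be positive")

    east_zone, west_zone = LEVEL_ZONE_BAND[difficulty_level]
    zone_id = east_zone if handedness == "right" else west_zone
    zone = layout.zone_rects[zone_id]
    # build in the east-side zone, then mirror for a left hand: the tiling is
    # symmetric about the vertical midline, so the mirrored pattern is
    # centered in the west-side zone by construction
    build_zone = layout.zone_rects[east_zone]

    raw = _raw_polyline(pattern_type, spacing_px)
    xs = [p[0] for p in raw]
    ys = [p[1] for p in raw]
    bbox_w = max(xs) - min(xs)
    bbox_h = max(ys) - min(ys)

    radius = dot_diameter_px / 2.0
    if bbox_w + dot_diameter_px > zone.width or bbox_h + dot_diameter_px > zone.height:
        raise PatternOverflowError(
            f"{pattern_type} pattern (bbox {bbox_w:.0f}x{bbox_h:.0f} px plus "
            f"{dot_diameter_px:.0f} px dots) does not fit zone {zone_id} "
            f"({zone.width:.0f}x{zone.height:.0f} px) at spacing {spacing_px} px")

    # center the bounding box in the east-side zone
    cx, cy = build_zone.center
    off_x = cx - (min(xs) + max(xs)) / 2.0
    off_y = cy - (min(ys) + max(ys)) / 2.0
    dots = [(x + off_x, y + off_y) for x, y in raw]

    if handedness == "left":
        dots = [(layout.width_px - x, y) for x, y in dots]

    for x, y in dots:
        if not zone.contains_point(x, y, margin=radius - 1e-9):
            raise PatternOverflowError(
                f"dot ({x:.1f}, {y:.1f}) inflated by radius {radius} px "
                f"escapes zone {zone_id}")

    theta = {"straight": 0.0, "triangular": TRIANGULAR_THETA_DEG,
             "square_wave": 90.0}[pattern_type]
    return DotPattern(
        pattern_type=pattern_type,
        zone=zone_id,
        dots=tuple(dots),
        dot_diameter_px=float(dot_diameter_px),
        spacing_px=float(spacing_px),
        theta_deg=theta,
        difficulty_level=difficulty_level,
        handedness=handedness,
    )


def generate_pattern_for_level(
    difficulty_level: int,
    layout: MonitorLayout,
    handedness: Handedness = "right",
    spacing_px: float = DEFAULT_SPACING_PX,
    dot_diameter_px: float = DEFAULT_DOT_DIAMETER_PX,
) -> DotPattern:
    """Convenience wrapper: infer the pattern type from the level."""
    return generate_pattern(
        LEVEL_PATTERN_TYPE[difficulty_level], difficulty_level, layout,
        handedness, spacing_px, dot_diameter_px)


def calibrate_mapping(
    center_angle_deg: float,
    periphery_angle_deg: float,
    span_px: float = DEFAULT_SPAN_PX,
    center_x_px: float = 800.0,
    direction: Handedness = "right",
) -> CalibrationProfile:
    """Build the individualized affine angle-to-pixel map.

    The angle recorded at the central hold posture maps to ``center_x_px``
    and the angle at maximal horizontal adduction (periphery hold) maps
    ``span_px`` pixels away, toward ``direction``. The personal angular
    range must exceed 5 degrees.
    """
    angle_range = abs(periphery_angle_deg - center_angle_deg)
    if angle_range <= 5.0:
        raise CalibrationError(
            f"degenerate calibration range: |{periphery_angle_deg} - "
            f"{center_angle_deg}| = {angle_range:.2f} deg (need > 5 deg)")
    if span_px <= 0:
        raise CalibrationError("span_px must be positive")
    return CalibrationProfile(
        center_angle_deg=float(center_angle_deg),
        periphery_angle_deg=float(periphery_angle_deg),
        span_px=float(span_px),
        center_x_px=float(center_x_px),
        direction=direction,
    )


def map_hand_point(
    azimuth_deg: float,
    elevation_norm: float,
    profile: CalibrationProfile,
    layout: MonitorLayout,
) -> tuple[float, float]:
    """Map a (azimuth, normalized elevation) hand posture to a screen point.

    x comes from the calibration map, clamped to the monitor; elevation 0
    maps to the bottom edge of the working zone and elevation 1 to the top
    of the screen (y decreases as the arm is raised), clamped likewise.
    """
    x = profile.map_angle(azimuth_deg)
    x = min(max(x, 0.0), float(layout.width_px))
    e = min(max(elevation_norm, 0.0), 1.0)
    top_h = layout.zone_top_height
    y = top_h * (1.0 - e)
    return (x, y)


def pattern_to_json(pattern: DotPattern) -> str:
    """Serialize a pattern to its JSON interchange record."""
    rec = {
        "pattern_type": pattern.pattern_type,
        "difficulty_level": pattern.difficulty_level,
        "zone": pattern.zone,
        "handedness": pattern.handedness,
        "spacing_px": pattern.spacing_px,
        "dot_diameter_px": pattern.dot_diameter_px,
        "dots": [[x, y] for x, y in pattern.dots],
    }
    return json.dumps(rec, indent=2)


def pattern_from_json(text: str) -> DotPattern:
    rec = json.loads(text)
    dots = tuple((float(x), float(y)) for x, y in rec["dots"])
    if len(dots) != N_DOTS:
        raise ValueError(f"pattern record must have {N_DOTS} dots, got {len(dots)}")
    theta = {"straight": 0.0, "triangular": TRIANGULAR_THETA_DEG,
             "square_wave": 90.0}[rec["pattern_type"]]
    return DotPattern(
        pattern_type=rec["pattern_type"],
        zone=rec["zone"],
        dots=dots,
        dot_diameter_px=float(rec["dot_diameter_px"]),
        spacing_px=float(rec["spacing_px"]),
        theta_deg=theta,
        difficulty_level=int(rec["difficulty_level"]),
        handedness=rec["handedness"],
    )


def save_pattern(pattern: DotPattern, path: str | Path) -> None:
    Path(path).write_text(pattern_to_json(pattern))


def load_pattern(path: str | Path) -> DotPattern:
    return pattern_from_json(Path(path).read_text())
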