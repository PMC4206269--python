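"""Arbitrary virtual-pattern injection.

A virtual pixel at image depth ``y`` on a given scan line is produced by
firing the AE element ``t = 2 y / c - d / c`` seconds after that line
starts, where ``d`` is the distance from the element to the line's aperture
center: the pulse then reaches the probe exactly when an echo from depth
``y`` would.  Two synchronization methods build a frame's
:class:`FiringPlan` from a :class:`PatternSpec`:

* **sync** — a frame/line synchronization signal is available, so ``d`` can
  be computed per target line and pixels placed at absolute image
  coordinates;
* **period-estimate** — no sync line; the A-line period is estimated from
  beacon arrivals on neighboring lines and pixels are placed relative to
  the element, timed from a reference trigger.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError, InsufficientDataError
from .scanner import LinearProbe, line_schedule

__all__ = [
    "Pixel",
    "PatternSpec",
    "PlanFiring",
    "FiringPlan",
    "BarConfig",
    "pixel_fire_time",
    "rasterize_sync",
    "estimate_line_period",
    "rasterize_relative",
    "midplane_bars",
    "pattern_from_bitmap",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pixel:
    """One virtual pixel.

    For ``absolute`` patterns ``line`` is a line index and ``depth`` an
    image depth in meters; for ``element_relative`` patterns they are a
    line offset and a depth offset from the element.
    """

    line: int
    depth: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.intensity <= 1.0):
            raise ConfigError(f"pixel intensity must be in (0, 1], got {self.intensity}")


@dataclass(frozen=True)
class PatternSpec:
    """A set of virtual pixels plus their anchoring convention."""

    pixels: tuple[Pixel, ...]
    frame_anchor: str = "absolute"  # absolute | element_relative

    def __post_init__(self) -> None:
        if self.frame_anchor not in ("absolute", "element_relative"):
            raise ConfigError(f"unknown frame_anchor {self.frame_anchor!r}")


@dataclass(frozen=True)
class PlanFiring:
    line_index: int
    fire_time: float  # seconds after the line start
    amplitude: float = 1.0


@dataclass(frozen=True)
class FiringPlan:
    """Per-line fire times realizing one pattern in one frame."""

    firings: tuple[PlanFiring, ...]
    method: str  # sync | period-estimate

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line": [f.line_index for f in self.firings],
                "time_us": [f.fire_time * 1e6 for f in self.firings],
                "amplitude": [f.amplitude for f in self.firings],
            }
        )


def pixel_fire_time(y: float, d: float, c: float) -> float:
    """Fire-time after line start for a pixel at depth ``y`` from an element
    at path distance ``d`` from the receiving aperture center.

    ``t = 2 y / c - d / c`` (round-trip delay of the virtual echo minus the
    element-to-probe travel time).  Negative ``t`` means the pixel is
    shallower than the element can reach (``2 y < d``).
    """
    if c <= 0:
        raise ConfigError("speed of sound must be > 0")
    t = (2.0 * y - d) / c
    if t < 0:
        raise GeometryError(
            f"pixel at y={y:g} m unreachable from distance d={d:g} m (2y < d)"
        )
    return t


def _merge_close(firings: list[PlanFiring], min_gap: float) -> list[PlanFiring]:
    """Merge same-line firings closer than ``min_gap`` (the element cannot
    overlap emissions); intensities add."""
    firings = sorted(firings, key=lambda f: (f.line_index, f.fire_time))
    out: list[PlanFiring] = []
    for f in firings:
        if (
            out
            and out[-1].line_index == f.line_index
            and f.fire_time - out[-1].fire_time < min_gap
        ):
            prev = out[-1]
            out[-1] = PlanFiring(
                prev.line_index, prev.fire_time, prev.amplitude + f.amplitude
            )
        else:
            out.append(f)
    return out


def _element_reference(probe: LinearProbe, element_pos) -> tuple[int, float]:
    """Nearest line to the element and the element's distance to that
    line's aperture center."""
    xs = np.array([s[1] for s in line_schedule(probe)])
    ref_line = int(np.argmin(np.abs(xs - element_pos[0])))
    d_ref = math.dist((xs[ref_line], 0.0, 0.0), tuple(element_pos))
    return ref_line, d_ref


def rasterize_sync(
    pattern: PatternSpec,
    probe: LinearProbe,
    element_pos,
    c: float,
    frame_sync: float = 0.0,
    min_gap: float = 0.0,
) -> FiringPlan:
    """Method 1: build a plan with full synchronization available.

    ``d`` is computed per target line from the element geometry; pixels land
    at their absolute image coordinates.  Unreachable pixels (fire time
    negative or outside the line window) are skipped with a logged warning.
    ``frame_sync`` is the line-0 start time of the frame the plan targets
    (kept for interface completeness; plan times are per-line).
    """
    xs = np.array([s[1] for s in line_schedule(probe)])
    pixels = list(pattern.pixels)
    if pattern.frame_anchor == "element_relative":
        ref_line, d_ref = _element_reference(probe, element_pos)
        pixels = [
            Pixel(ref_line + p.line, d_ref + p.depth, p.intensity) for p in pixels
        ]
    firings: list[PlanFiring] = []
    skipped = 0
    for p in pixels:
        if not (0 <= p.line < probe.lines_per_frame):
            skipped += 1
            log.warning("pixel on line %d outside the frame; skipped", p.line)
            continue
        if not (0.0 < p.depth <= probe.max_depth):
            skipped += 1
            log.warning("pixel depth %.4g m outside (0, max_depth]; skipped", p.depth)
            continue
        d = math.dist((xs[p.line], 0.0, 0.0), tuple(element_pos))
        try:
            t = pixel_fire_time(p.depth, d, c)
        except GeometryError as exc:
            skipped += 1
            log.warning("unreachable pixel skipped: %s", exc)
            continue
        if t >= probe.line_period:
            skipped += 1
            log.warning("pixel fire time beyond line period; skipped")
            continue
        firings.append(PlanFiring(p.line, t, p.intensity))
    if pixels and not firings:
        warnings.warn("all pattern pixels unreachable; plan is empty", stacklevel=2)
    if min_gap > 0:
        firings = _merge_close(firings, min_gap)
    firings.sort(key=lambda f: (f.line_index, f.fire_time))
    return FiringPlan(tuple(firings), method="sync")


def estimate_line_period(trigger_times, line_gaps=None) -> float:
    """Estimate the A-line period from beacon trigger times.

    With ``line_gaps`` given (number of lines between successive triggers),
    the estimate is the median of ``diff / gap``.  Otherwise the smallest
    positive difference anchors the base period and each difference is
    divided by its nearest-integer multiple — robust to skipped lines as
    long as at least one pair of adjacent-line triggers is present.
    """
    t = np.sort(np.asarray(trigger_times, dtype=float))
    if t.size < 2:
        raise InsufficientDataError("need at least two trigger times")
    diffs = np.diff(t)
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        raise InsufficientDataError("trigger times are all identical")
    if line_gaps is not None:
        gaps = np.asarray(line_gaps, dtype=float)
        if gaps.shape != diffs.shape:
            raise InsufficientDataError("line_gaps must match the differences")
        return float(np.median(diffs / gaps))
    base = diffs.min()
    gaps = np.maximum(1, np.round(diffs / base))
    return float(np.median(diffs / gaps))


def rasterize_relative(
    pattern: PatternSpec,
    period_estimate: float,
    ref_line: int,
    ref_beacon_time: float,
    probe: LinearProbe,
    c: float,
    min_gap: float = 0.0,
) -> FiringPlan:
    """Method 2: build an element-relative plan from a reference trigger.

    A pixel at ``(dlines, ddepth)`` relative to the element is realized by
    waiting ``dlines * period_estimate + 2 * ddepth / c`` after the
    reference beacon arrival; with an exact period estimate this fires at
    ``ref_beacon_time + 2 * ddepth / c`` within the target line.  A period
    error of ``dP`` displaces the firing by ``dlines * dP`` within the line.
    """
    if pattern.frame_anchor != "element_relative":
        raise ConfigError("rasterize_relative needs an element_relative pattern")
    if period_estimate <= 0:
        raise ConfigError("period_estimate must be > 0")
    firings: list[PlanFiring] = []
    for p in pattern.pixels:
        tgt = ref_line + p.line
        if not (0 <= tgt < probe.lines_per_frame):
            log.warning("relative pixel pushes to line %d outside frame; skipped", tgt)
            continue
        # delay counted by the device from the reference beacon, then
        # re-expressed within the target line using the scanner's true period
        delay = p.line * period_estimate + 2.0 * p.depth / c
        t_in_line = ref_beacon_time + delay - p.line * probe.line_period
        if not (0.0 <= t_in_line < probe.line_period):
            log.warning("relative pixel fire time outside line window; skipped")
            continue
        firings.append(PlanFiring(tgt, t_in_line, p.intensity))
    if min_gap > 0:
        firings = _merge_close(firings, min_gap)
    firings.sort(key=lambda f: (f.line_index, f.fire_time))
    return FiringPlan(tuple(firings), method="period-estimate")


@dataclass(frozen=True)
class BarConfig:
    """Geometry of the injected mid-plane indicator bars.

    Bars stack laterally beside the element, each a short vertical run of
    pixels; one bar per ``counts_per_bar`` triggers (ceiling division).
    """

    counts_per_bar: int = 5
    start_line_offset: int = 8
    spacing_lines: int = 5
    bar_depth_offset: float = -10e-3
    bar_length: float = 4e-3
    pixels_per_bar: int = 4

    def __post_init__(self) -> None:
        if self.counts_per_bar < 1 or self.pixels_per_bar < 1:
            raise ConfigError("counts_per_bar and pixels_per_bar must be >= 1")


def midplane_bars(trigger_count: int, cfg: BarConfig = BarConfig()) -> PatternSpec:
    """Trigger count -> element-relative bar pattern.

    ``ceil(count / counts_per_bar)`` bars; monotone non-decreasing in the
    count; an aligned element shows the most bars.  Zero count gives an
    empty pattern.
    """
    if trigger_count < 0:
        raise ConfigError("trigger_count must be >= 0")
    n_bars = math.ceil(trigger_count / cfg.counts_per_bar)
    pixels: list[Pixel] = []
    depths = cfg.bar_depth_offset + np.linspace(0.0, cfg.bar_length, cfg.pixels_per_bar)
    for b in range(n_bars):
        dline = cfg.start_line_offset + b * cfg.spacing_lines
        for dd in depths:
            pixels.append(Pixel(dline, float(dd), 1.0))
    return PatternSpec(tuple(pixels), frame_anchor="element_relative")


def pattern_from_bitmap(
    bitmap,
    line0: int,
    depth0: float,
    depth_step: float,
    line_step: int = 1,
    threshold: float = 0.5,
) -> PatternSpec:
    """Rasterize a monochrome bitmap into an absolute pattern.

    ``bitmap`` is a 2-D array (rows = depth, columns = lines), a path to a
    PNG/PGM image, or an ASCII-art string where any non-space character is a
    lit pixel.  Row 0 maps to ``depth0``; each row adds ``depth_step``.
    """
    if isinstance(bitmap, str) and "\n" in bitmap:
        rows = [r for r in bitmap.splitlines() if r.strip()]
        width = max(len(r) for r in rows)
        arr = np.array(
            [[1.0 if ch != " " else 0.0 for ch in r.ljust(width)] for r in rows]
        )
    elif isinstance(bitmap, (str, bytes)) or hasattr(bitmap, "read"):
        from PIL import Image

        arr = np.asarray(Image.open(bitmap).convert("L"), dtype=float) / 255.0
    else:
        arr = np.asarray(bitmap, dtype=float)
    pixels = [
        Pixel(line0 + j * line_step, depth0 + i * depth_step, 1.0)
        for i, j in zip(*np.nonzero(arr > threshold))
    ]
    return PatternSpec(tuple(pixels), frame_anchor="absolute")
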