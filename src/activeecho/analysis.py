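"""Evaluation operations: template filtering, image metrics, mid-plane
sweeps and parameter grids.

These mirror the bench evaluations of an active-echo tracking system:
extract the AE waveform by on/off frame subtraction and use it as a matched
filter; quantify spot visibility with SNR/CNR around the spot; sweep the
element through the elevational beam to localize the image mid-plane from
trigger counts or received amplitude; and map trigger counts over scanner
parameter grids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import AEDevice
from .errors import MetricError, NoSignalError
from .imaging import BModeImage
from .scanner import LinearProbe, RFFrame, acquire_frame
from .scene import Scene

__all__ = [
    "Template",
    "SweepResult",
    "MetricReport",
    "acquire_template",
    "template_filter",
    "compute_snr_cnr",
    "midplane_sweep",
    "localize_midplane",
    "detectable_range",
    "parameter_grid",
    "TRIGGER_COUNT_CEILING",
]

#: Trigger counts above this are flagged as saturated and excluded from
#: derived fits (a wide, distorted spot makes them unreliable).
TRIGGER_COUNT_CEILING = 40


@dataclass(frozen=True)
class Template:
    """AE waveform template extracted by on/off frame subtraction."""

    samples: np.ndarray
    line_index: int
    start_sample: int
    fs: float

    def __len__(self) -> int:
        return len(self.samples)


def acquire_template(frame_on: RFFrame, frame_off: RFFrame) -> Template:
    """Subtract echo-off from echo-on RF and trim to the energy support.

    With a static scene and identical seeds the difference is exactly the AE
    contribution (acquisition is linear).  The support keeps samples from the
    first to the last exceeding 1% of the difference maximum, on the line
    with the most difference energy.
    """
    if frame_on.samples.shape != frame_off.samples.shape:
        raise ValueError("frames must have identical shapes")
    diff = frame_on.samples - frame_off.samples
    peak = np.abs(diff).max()
    if peak == 0:
        raise NoSignalError("frames are identical; no AE signal to extract")
    line = int(np.argmax(np.sum(diff**2, axis=1)))
    strong = np.nonzero(np.abs(diff[line]) >= 0.01 * peak)[0]
    lo, hi = int(strong[0]), int(strong[-1]) + 1
    return Template(diff[line, lo:hi].copy(), line, lo, frame_on.fs)


def template_filter(frame: RFFrame, template: Template | np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of every line with the template.

    Output shape is (lines, n_samples - len(template) + 1); entry ``[l, k]``
    is the dot product of the template with the line segment starting at
    sample ``k``, normalized by the template norm and the local segment
    energy (true NCC, 1.0 at an exact template instance).  The map peaks at
    the AE packet start when one is present; segments with negligible
    energy map to 0.
    """
    t = np.asarray(getattr(template, "samples", template), dtype=float)
    if t.size > frame.n_samples:
        raise ValueError("template longer than a line")
    tnorm = np.linalg.norm(t)
    out = np.zeros((frame.n_lines, frame.n_samples - t.size + 1))
    if tnorm == 0:
        return out
    window = np.ones(t.size)
    gmax = np.abs(frame.samples).max()
    floor = (1e-9 * max(gmax, 1e-300)) ** 2 * t.size
    for l in range(frame.n_lines):
        line = frame.samples[l]
        corr = np.correlate(line, t, mode="valid")
        energy = np.convolve(line**2, window, mode="valid")
        denom = tnorm * np.sqrt(np.maximum(energy, 0.0))
        np.divide(corr, denom, out=out[l], where=energy > floor)
    return out


@dataclass(frozen=True)
class MetricReport:
    """Spot-visibility metrics around the AE spot."""

    snr: float
    cnr: float
    spot_region: np.ndarray  # boolean mask over the image
    surrounding_window: tuple[slice, slice]
    window_size: int = 50


def compute_snr_cnr(
    frame_on: BModeImage | np.ndarray,
    frame_off: BModeImage | np.ndarray,
    spot_center: tuple[int, int],
    window: int = 50,
) -> MetricReport:
    """SNR and CNR of the AE spot from echo-on and echo-off images.

    ``DiffSignal = on - off``; the spot region is where DiffSignal reaches
    at least half its maximum; the background statistics come from the
    echo-off image over a ``window x window`` pixel area centered on the
    spot.  ``SNR = mean(DiffSignal over spot) / std(background over
    window)``; ``CNR = |mean(on over spot) - mean(background over window)|
    / std(background over window)``.
    """
    on = np.asarray(getattr(frame_on, "pixels", frame_on), dtype=float)
    off = np.asarray(getattr(frame_off, "pixels", frame_off), dtype=float)
    if on.shape != off.shape:
        raise ValueError("images must have the same shape")
    diff = on - off
    dmax = diff.max()
    if dmax <= 0:
        raise NoSignalError("no positive differential signal; spot undefined")
    spot = diff >= dmax / 2.0
    r0, c0 = spot_center
    half = window // 2
    rs = slice(max(0, r0 - half), min(on.shape[0], r0 - half + window))
    cs = slice(max(0, c0 - half), min(on.shape[1], c0 - half + window))
    if (rs.stop - rs.start) < window or (cs.stop - cs.start) < window:
        raise MetricError(f"{window}x{window} window does not fit at {spot_center}")
    bg = off[rs, cs]
    sigma = bg.std()
    if sigma == 0:
        raise MetricError("zero background standard deviation; metrics undefined")
    snr = float(diff[spot].mean() / sigma)
    cnr = float(abs(on[spot].mean() - bg.mean()) / sigma)
    return MetricReport(snr, cnr, spot, (rs, cs), window)


@dataclass(frozen=True)
class SweepResult:
    """Trigger counts and peak received amplitudes over an elevational
    sweep, with per-offset repeat statistics."""

    offsets_mm: np.ndarray
    trigger_counts: np.ndarray  # (n_offsets, repeats), integers
    peak_amplitudes: np.ndarray  # (n_offsets, repeats)
    repeats: int

    def __post_init__(self) -> None:
        if self.trigger_counts.shape != self.peak_amplitudes.shape:
            raise ValueError("counts and amplitudes must have matching shapes")
        if np.any(self.trigger_counts < 0):
            raise ValueError("trigger counts must be >= 0")

    @property
    def count_mean(self) -> np.ndarray:
        return self.trigger_counts.mean(axis=1)

    @property
    def count_std(self) -> np.ndarray:
        return self.trigger_counts.std(axis=1)

    @property
    def amp_mean(self) -> np.ndarray:
        return self.peak_amplitudes.mean(axis=1)

    @property
    def amp_std(self) -> np.ndarray:
        return self.peak_amplitudes.std(axis=1)

    @property
    def saturated(self) -> np.ndarray:
        """Offsets whose mean count exceeds the reliability ceiling."""
        return self.count_mean > TRIGGER_COUNT_CEILING

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_mm": self.offsets_mm,
                "count_mean": self.count_mean,
                "count_std": self.count_std,
                "amp_mean": self.amp_mean,
                "amp_std": self.amp_std,
                "saturated": self.saturated,
            }
        )


def midplane_sweep(
    probe: LinearProbe,
    scene: Scene,
    device: AEDevice,
    offsets_m,
    repeats: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Move the element across elevational offsets and record, per offset
    and repeat, the frame trigger count and the peak comparator amplitude.

    Noise (device or scene) is reseeded per repeat; noiseless sweeps are
    deterministic and their repeats identical.
    """
    offsets = np.sort(np.asarray(offsets_m, dtype=float))
    counts = np.zeros((offsets.size, repeats), dtype=int)
    amps = np.zeros((offsets.size, repeats))
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(offsets.size * repeats)
    x, _, z = device.position
    for i, off in enumerate(offsets):
        dev = device.at(position=(x, float(off), z))
        for r in range(repeats):
            rng = np.random.default_rng(seeds[i * repeats + r])
            _, log = acquire_frame(probe, scene, dev, rng=rng, rf=False)
            counts[i, r] = log.count
            amps[i, r] = log.peak_amplitude
    return SweepResult(offsets * 1e3, counts, amps, repeats)


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Vertex of the parabola through (x, y) at k-1, k, k+1; falls back to
    the grid point at the edges or for degenerate curvature."""
    if k == 0 or k == len(x) - 1:
        return float(x[k])
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom >= 0:  # not a maximum
        return float(x[k])
    dx = x[k + 1] - x[k]
    return float(x[k] + 0.5 * dx * (y[k - 1] - y[k + 1]) / denom)


def _threshold_half_width(x: np.ndarray, y: np.ndarray, q: float) -> tuple[float, float]:
    """Center and half-width of the region where y >= q * max(y), with
    linear interpolation of the two crossings."""
    level = q * y.max()
    above = y >= level
    if not above.any():
        raise MetricError("no samples above the threshold level")
    idx = np.nonzero(above)[0]
    lo, hi = idx[0], idx[-1]
    left = x[lo]
    if lo > 0:
        left = np.interp(level, [y[lo - 1], y[lo]], [x[lo - 1], x[lo]])
    right = x[hi]
    if hi < len(x) - 1:
        right = np.interp(level, [y[hi + 1], y[hi]], [x[hi + 1], x[hi]])
    return float((left + right) / 2.0), float((right - left) / 2.0)


def localize_midplane(
    sweep: SweepResult, method: str = "count"
) -> tuple[float, float]:
    """Mid-plane offset estimate (mm) and half-width (mm) from a sweep.

    ``count`` and ``amplitude`` return the parabolic-refined argmax of the
    mean curve (half-width at half maximum alongside).  ``amplitude-
    threshold@q`` (e.g. ``@0.9``) returns the center and half-width of the
    region where the mean amplitude stays above ``q`` of its maximum — the
    accuracy obtained by setting the trigger level to that fraction.
    Saturated offsets are excluded from count-based fits.
    """
    x = sweep.offsets_mm
    if method == "count":
        y = sweep.count_mean.astype(float).copy()
        y[sweep.saturated] = np.nan
        valid = ~np.isnan(y)
        x, y = x[valid], y[valid]
        q = 0.5
    elif method == "amplitude":
        y = sweep.amp_mean
        q = 0.5
    elif method.startswith("amplitude-threshold@"):
        q = float(method.split("@", 1)[1])
        y = sweep.amp_mean
        center, hw = _threshold_half_width(x, y, q)
        return center, hw
    else:
        raise ValueError(f"unknown localization method {method!r}")
    if y.size == 0 or np.ptp(y) == 0:
        raise MetricError("flat sweep; no maximum to localize")
    # integer counts plateau at the top; center on the tied maximum before
    # parabolic refinement so a symmetric sweep localizes to zero exactly
    ties = np.nonzero(y == y.max())[0]
    k = int(round(ties.mean()))
    est = _parabolic_vertex(x, y, k)
    _, hw = _threshold_half_width(x, y, q)
    return est, hw


def detectable_range(sweep: SweepResult) -> float:
    """Largest |offset| (mm) at which the element still triggers, linearly
    interpolated to the first zero-count offset on each side.

    If the counts never reach zero at the sweep extremes the range is
    undetermined; a warning is issued and the sweep extreme returned.
    """
    x = sweep.offsets_mm
    y = sweep.count_mean.astype(float)
    if not np.any(y > 0):
        return 0.0

    def _side(xs: np.ndarray, ys: np.ndarray) -> float:
        # xs ordered with |offset| increasing away from 0
        nz = np.nonzero(ys > 0)[0]
        last = nz[-1]
        if last == len(xs) - 1:
            warnings.warn(
                "trigger count nonzero at sweep extreme; range undetermined",
                stacklevel=3,
            )
            return abs(float(xs[-1]))
        # linear segment from (x_last, y_last) down to (x_next, 0) reaches
        # zero at x_next: the interpolated first-zero offset
        return abs(float(xs[last + 1]))

    pos = x >= 0
    neg = x <= 0
    ranges = []
    if np.any(y[pos] > 0):
        ranges.append(_side(x[pos], y[pos]))
    if np.any(y[neg] > 0):
        ranges.append(_side(x[neg][::-1], y[neg][::-1]))
    return max(ranges)


def parameter_grid(
    probe: LinearProbe,
    scene: Scene,
    device: AEDevice,
    grid: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Trigger count over a Cartesian grid of scanner/device settings.

    ``grid`` maps parameter names (probe fields ``tx_power``,
    ``tx_aperture``, ``focus_depth`` ... or device fields ``rx_gain_db``,
    ``threshold``) to value lists.  Counts above the reliability ceiling are
    flagged ``discarded``.
    """
    probe_fields = set(LinearProbe.__dataclass_fields__)
    device_fields = set(AEDevice.__dataclass_fields__)
    names = list(grid)
    rows = []
    rng = np.random.default_rng(seed)
    for values in itertools.product(*(grid[n] for n in names)):
        p, d = probe, device
        for name, val in zip(names, values):
            if name in probe_fields:
                p = p.at(**{name: val})
            elif name in device_fields:
                d = d.at(**{name: val})
            else:
                raise KeyError(f"unknown grid parameter {name!r}")
        _, log = acquire_frame(p, scene, d, rng=rng, rf=False)
        row = dict(zip(names, values))
        row["trigger_count"] = log.count
        row["discarded"] = log.count > TRIGGER_COUNT_CEILING
        rows.append(row)
    return pd.DataFrame(rows)
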