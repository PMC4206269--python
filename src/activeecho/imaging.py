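"""B-mode and M-mode image formation from RF frames.

Standard pipeline: per-line envelope detection (analytic-signal magnitude),
per-frame max normalization and log compression to an 8-bit dynamic range.
No scan conversion is needed for a linear array — the pixel grid is
(line, sample) and the axial pixel depth is ``assumed_c * t / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import ConfigError
from .scanner import RFFrame
from .scene import Medium

__all__ = [
    "BModeImage",
    "MModeImage",
    "envelope",
    "log_compress",
    "form_bmode",
    "extract_mmode",
]


@dataclass(frozen=True)
class BModeImage:
    """Log-compressed brightness image (lines x samples, values 0-255)."""

    pixels: np.ndarray
    dynamic_range_db: float
    axial_extent: float
    lateral_extent: float
    line_x: np.ndarray
    fs: float
    assumed_c: float

    @property
    def depths(self) -> np.ndarray:
        """Axial pixel depths in meters."""
        n = self.pixels.shape[1]
        return self.assumed_c * np.arange(n) / self.fs / 2.0

    def depth_to_sample(self, depth: float) -> int:
        return int(round(2.0 * depth / self.assumed_c * self.fs))


@dataclass(frozen=True)
class MModeImage:
    """One envelope line per frame at a fixed line index (samples x frames)."""

    columns: np.ndarray
    frame_times: np.ndarray
    line_index: int


def envelope(rf_line: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (non-negative, carrier removed)."""
    rf_line = np.asarray(rf_line, dtype=float)
    if not np.all(np.isfinite(rf_line)):
        raise ValueError("RF samples must be finite")
    if rf_line.ndim == 1:
        return np.abs(hilbert(rf_line))
    return np.abs(hilbert(rf_line, axis=-1))


def log_compress(env: np.ndarray, dynamic_range_db: float = 50.0) -> np.ndarray:
    """Envelope -> 0-255 pixels over a dB dynamic range.

    255 at the frame maximum, 0 at/below ``max * 10**(-DR/20)``, linear in
    dB in between; an all-zero frame maps to an all-zero image.
    """
    if dynamic_range_db <= 0:
        raise ConfigError("dynamic_range_db must be > 0")
    env = np.asarray(env, dtype=float)
    peak = env.max() if env.size else 0.0
    if peak <= 0:
        return np.zeros_like(env)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.where(env > 0, env / peak, np.finfo(float).tiny))
    return np.clip(255.0 * (1.0 + db / dynamic_range_db), 0.0, 255.0)


def form_bmode(
    frame: RFFrame, medium: Medium, dynamic_range_db: float = 50.0
) -> BModeImage:
    """Envelope-detect and log-compress a whole frame."""
    env = envelope(frame.samples)
    pix = log_compress(env, dynamic_range_db)
    axial = medium.assumed_c * frame.n_samples / frame.fs / 2.0
    lateral = float(frame.line_x[-1] - frame.line_x[0])
    return BModeImage(
        pixels=pix,
        dynamic_range_db=dynamic_range_db,
        axial_extent=axial,
        lateral_extent=lateral,
        line_x=frame.line_x,
        fs=frame.fs,
        assumed_c=medium.assumed_c,
    )


def extract_mmode(frames, line_index: int) -> MModeImage:
    """Stack one line's envelope across frames (motion display).

    A device blinking at a few Hz shows up as a dashed bright line.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if not (0 <= line_index < frames[0].n_lines):
        raise IndexError(
            f"line {line_index} out of range [0, {frames[0].n_lines})"
        )
    cols = np.stack(
        [envelope(fr.samples[line_index]) for fr in frames], axis=1
    )
    times = np.array([fr.frame_start for fr in frames])
    return MModeImage(columns=cols, frame_times=times, line_index=line_index)
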