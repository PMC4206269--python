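"""The catheter-mounted active-echo (AE) element and its front-end.

The element is a small piezo tube on the tool tip that both *receives* the
scanner's beacon pulses and *fires* its own pulses back.  The electronics are
modelled abstractly: variable-gain amplifier, analog band-pass, absolute-value
comparator with a per-line latch, and a pulser with a fixed electronic loop
delay between trigger and emission.

Timing convention
-----------------
``trigger_decision`` reports the first comparator crossing of the received
trace, which is what the hardware logs.  The *emission epoch* used by the
scanner, however, is referenced to the beacon envelope center: the measured
loop delay is defined between received and fired waveform features, so with
``loop_delay = 0`` the echoed spot coincides exactly with the element's true
image position.  See the methods note for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

from .errors import ConfigError

__all__ = [
    "AEDevice",
    "TriggerEvent",
    "Firing",
    "receive_voltage",
    "directivity_factor",
    "trigger_decision",
    "blink_gate",
    "make_firing",
    "frontend_filter",
]

MAX_DRIVE_V = 150.0  #: pulser hard limit, volts
MIN_PULSE_S = 12.5e-9  #: shortest pulse the pulser can produce, seconds
FRONTEND_BAND = (0.1e6, 20e6)  #: analog front-end band, Hz


@dataclass(frozen=True)
class AEDevice:
    """Active-echo element state and electronics settings.

    ``position`` is (x, e, z) in meters; ``orientation`` is the cylinder-axis
    unit vector (the element is most sensitive to beams perpendicular to its
    axis).  ``sensitivity`` converts beacon pressure amplitude to volts at
    0 dB gain; only ratios to ``threshold`` matter anywhere in the method.
    """

    position: tuple[float, float, float] = (0.0, 0.0, 0.04)
    orientation: tuple[float, float, float] = (0.0, 1.0, 0.0)
    rx_gain_db: float = 19.0
    threshold: float = 1.0
    loop_delay: float = 0.6e-6
    pulse_freq: float = 9.0e6
    pulse_cycles: int = 8
    drive_voltage: float = 58.0
    blink_enabled: bool = False
    blink_period: float = 0.5
    blink_duty: float = 0.5
    mode: str = "echo"  # off | echo | pattern
    sensitivity: float = 1.0
    noise_std: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.drive_voltage <= MAX_DRIVE_V):
            raise ConfigError(
                f"drive_voltage must be in (0, {MAX_DRIVE_V}] V, "
                f"got {self.drive_voltage}"
            )
        if self.pulse_duration < MIN_PULSE_S:
            raise ConfigError(
                f"pulse duration {self.pulse_duration:.3e} s below pulser "
                f"minimum {MIN_PULSE_S:.3e} s"
            )
        if not np.isfinite(self.rx_gain_db):
            raise ConfigError("rx_gain_db must be finite")
        if not (0.0 < self.blink_duty < 1.0):
            raise ConfigError("blink_duty must be in (0, 1)")
        if self.mode not in ("off", "echo", "pattern"):
            raise ConfigError(f"unknown device mode {self.mode!r}")
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")

    @property
    def pulse_duration(self) -> float:
        return self.pulse_cycles / self.pulse_freq

    def at(self, **kw) -> "AEDevice":
        """Copy with fields replaced (convenience for sweeps)."""
        return replace(self, **kw)


@dataclass(frozen=True)
class TriggerEvent:
    """A comparator crossing on one scan line.

    ``t_trigger`` is the first-crossing time within the line; ``t_beacon``
    the beacon envelope-center arrival time (the emission reference).
    """

    line_index: int
    t_trigger: float
    amplitude_v: float
    t_beacon: float = 0.0


@dataclass(frozen=True)
class Firing:
    """One AE emission: epoch within the line, waveform parameters, and an
    amplitude in the scanner's RF units."""

    fire_time: float
    freq: float
    cycles: int
    amplitude: float


def directivity_factor(incidence_angle_deg, device: AEDevice):
    """Angular sensitivity of the cylindrical element.

    0 degrees = beam perpendicular to the cylinder axis (maximum).  Smooth,
    even, and floored at 0.05 so the element works at every tested angle once
    the gain is adjusted.
    """
    ang = np.deg2rad(np.asarray(incidence_angle_deg, dtype=float))
    f = np.maximum(np.cos(ang) ** 2, 0.05)
    return f if f.ndim else float(f)


def receive_voltage(pressure_amplitude, device: AEDevice, incidence_angle_deg=0.0):
    """Beacon pressure -> comparator input voltage.

    ``pressure * sensitivity * 10**(gain_dB/20) * directivity``.
    """
    p = np.asarray(pressure_amplitude, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure amplitude must be >= 0")
    v = (
        p
        * device.sensitivity
        * 10.0 ** (device.rx_gain_db / 20.0)
        * directivity_factor(incidence_angle_deg, device)
    )
    return v if v.ndim else float(v)


def frontend_filter(trace: np.ndarray, fs: float) -> np.ndarray:
    """Analog front-end band-pass (0.1-20 MHz), zero-phase.

    The upper cutoff is clipped below Nyquist when the simulation sampling
    rate is too low to represent the full analog band.
    """
    lo, hi = FRONTEND_BAND
    hi = min(hi, 0.45 * fs)
    sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, trace)


def trigger_decision(
    voltage_trace: np.ndarray,
    threshold: float,
    fs: float,
    line_index: int = 0,
    t_beacon: float = 0.0,
    ref_norm: float | None = None,
) -> TriggerEvent | None:
    """First sample where ``|v| >= threshold``; the latch then blocks any
    further event until the next line (one event per line at most).

    Returns ``None`` when the trace never crosses the threshold.

    The event amplitude is the detected peak amplitude of the received
    packet, which the amplitude-based mid-plane method relies on.  With
    ``ref_norm`` (the l2 norm of the front-end-filtered, unit-peak beacon
    shape) it is computed from the packet energy in a short window around
    the envelope maximum — insensitive to the carrier phase at the
    sampling instants, which makes repeated amplitude readings stable to
    ~0.2%.  Without it the sub-sample-refined envelope peak is used.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    trace = np.asarray(voltage_trace, dtype=float)
    v = np.abs(trace)
    above = v >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if ref_norm is not None and ref_norm > 0:
        c = int(np.argmax(v))
        lo, hi = max(0, c - 48), min(v.size, c + 49)
        amp = float(np.sqrt(np.sum(trace[lo:hi] ** 2)) / ref_norm)
    else:
        amp = _envelope_peak(trace)
    return TriggerEvent(
        line_index=line_index,
        t_trigger=k / fs,
        amplitude_v=max(amp, float(v.max())),
        t_beacon=t_beacon,
    )


def _envelope_peak(trace: np.ndarray) -> float:
    """Detected peak amplitude of a trace.

    Analytic-signal envelope maximum with sub-sample refinement: the
    analytic signal is bandlimited, so local sinc interpolation around the
    coarse maximum recovers the true peak regardless of where it falls
    between samples (a raw sample maximum would beat against the carrier
    phase and jitter by several percent).
    """
    analytic = _sig.hilbert(np.asarray(trace, dtype=float))
    env = np.abs(analytic)
    k = int(np.argmax(env))
    w = 40
    lo, hi = max(0, k - w), min(env.size, k + w + 1)
    seg = analytic[lo:hi]
    j = np.arange(lo, hi)
    tau = k + np.linspace(-1.0, 1.0, 33)
    fine = np.abs(np.sinc(tau[:, None] - j[None, :]) @ seg)
    return float(max(env[k], fine.max()))


def blink_gate(t: float, device: AEDevice) -> bool:
    """Time-modulation gate: enabled iff the device is within the 'on' part
    of its blink cycle (always on when blinking is disabled)."""
    if not device.blink_enabled:
        return True
    if device.blink_period <= 0:
        raise ConfigError("blink_period must be > 0")
    return (t % device.blink_period) < device.blink_duty * device.blink_period


def make_firing(event: TriggerEvent, device: AEDevice) -> Firing:
    """Echo-mode response to a trigger: fire ``loop_delay`` after the
    beacon reference with the device's pulse settings.

    The emitted amplitude scales linearly with drive voltage (RF units are
    arbitrary; 150 V maps to 1.0).
    """
    if device.pulse_duration < MIN_PULSE_S:
        raise ConfigError("pulse duration below pulser minimum")
    ref = event.t_beacon if event.t_beacon > 0 else event.t_trigger
    return Firing(
        fire_time=ref + device.loop_delay,
        freq=device.pulse_freq,
        cycles=device.pulse_cycles,
        amplitude=device.drive_voltage / MAX_DRIVE_V,
    )
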